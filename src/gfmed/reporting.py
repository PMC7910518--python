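"""Publication-style tables from an analytic cohort and a fitted model.

The descriptive table mirrors the standard register-study layout: for every
category of the exposure, the mediators and the confounders it lists N,
column percent, the outcome prevalence within the category and the adjusted
odds ratio (with 95% CI) from the outcome model, reference rows marked
``ref.``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import (
    BIRTH_YEARS,
    EDUCATION_LEVELS,
    FAMILY_CATEGORIES,
    GPA,
    MEDIATORS,
    OUTCOME,
    PARENTAL_FLAGS,
)
from .models import (
    CONF_TERMS,
    INCOME_TERMS,
    MEDIATOR_TERMS,
    confounder_matrix,
    income_matrix,
    mediator_matrix,
)

_QUINTILE_LABELS = {5: "Highest", 4: "4th", 3: "3rd", 2: "2nd", 1: "Lowest"}
_QUARTILE_LABELS = {1: "Highest", 2: "3rd", 3: "2nd", 4: "Lowest"}


def fit_outcome_model_with_ci(records: pd.DataFrame, alpha: float = 0.05):
    """Outcome model refit through statsmodels to obtain Wald intervals."""
    ones = np.ones((len(records), 1))
    X = np.hstack([
        ones,
        confounder_matrix(records),
        income_matrix(records["income_quintile"].to_numpy()),
        mediator_matrix({**{m: records[m].to_numpy() for m in MEDIATORS},
                         GPA: records["gpa_quartile"].to_numpy()}),
    ])
    terms = ("const",) + CONF_TERMS + INCOME_TERMS + MEDIATOR_TERMS
    res = sm.GLM(records[OUTCOME].to_numpy(dtype=float), X,
                 family=sm.families.Binomial()).fit()
    ci = res.conf_int(alpha=alpha)
    return {t: (float(np.exp(res.params[i])),
                float(np.exp(ci[i, 0])), float(np.exp(ci[i, 1])))
            for i, t in enumerate(terms)}


def _rows_for(records, mask_by_level, block, term_by_level, ref_level, ors):
    n_total = len(records)
    y = records[OUTCOME].to_numpy()
    rows = []
    for level, mask in mask_by_level:
        n = int(mask.sum())
        prev = 100.0 * y[mask].mean() if n else np.nan
        term = term_by_level.get(level)
        if level == ref_level:
            or_, lo, hi, ref = np.nan, np.nan, np.nan, True
        elif term is not None and n > 0:
            or_, lo, hi = ors[term]
            ref = False
        else:
            or_, lo, hi, ref = np.nan, np.nan, np.nan, False
        rows.append({"block": block, "category": str(level), "n": n,
                     "percent": 100.0 * n / n_total,
                     "outcome_prevalence_pct": prev,
                     "odds_ratio": or_, "ci_low": lo, "ci_high": hi,
                     "reference": ref})
    return rows


def render_descriptive_table(records: pd.DataFrame,
                             ors: dict | None = None) -> pd.DataFrame:
    """One row per category: N, column %, outcome prevalence, adjusted OR."""
    if ors is None:
        ors = fit_outcome_model_with_ci(records)
    rows = []

    q = records["income_quintile"].to_numpy()
    rows += _rows_for(records,
                      [(_QUINTILE_LABELS[k], q == k) for k in (5, 4, 3, 2, 1)],
                      "childhood_income_quintile",
                      {_QUINTILE_LABELS[k]: f"income_q{k}" for k in (1, 2, 3, 4)},
                      "Highest", ors)

    for m in MEDIATORS:
        vals = records[m].to_numpy()
        rows += _rows_for(records, [("No", vals == 0), ("Yes", vals == 1)],
                          m, {"Yes": m}, "No", ors)

    g = records["gpa_quartile"].to_numpy()
    rows += _rows_for(records,
                      [(_QUARTILE_LABELS[k], g == k) for k in (1, 2, 3, 4)],
                      "gpa_quartile",
                      {_QUARTILE_LABELS[k]: f"gpa:{k}" for k in (2, 3, 4)},
                      "Highest", ors)

    for t in PARENTAL_FLAGS:
        vals = records[t].to_numpy()
        rows += _rows_for(records, [("No", vals == 0), ("Yes", vals == 1)],
                          t, {"Yes": t}, "No", ors)

    fam = records["family_stability"]
    rows += _rows_for(records, [(c, (fam == c).to_numpy()) for c in FAMILY_CATEGORIES],
                      "family_stability",
                      {c: f"family:{c}" for c in FAMILY_CATEGORIES[1:]},
                      FAMILY_CATEGORIES[0], ors)

    edu = records["parental_education"]
    rows += _rows_for(records, [(l, (edu == l).to_numpy()) for l in EDUCATION_LEVELS],
                      "parental_education",
                      {l: f"education:{l}" for l in EDUCATION_LEVELS[1:]},
                      EDUCATION_LEVELS[0], ors)

    sex = records["sex_female"].to_numpy()
    rows += _rows_for(records, [("male", sex == 0), ("female", sex == 1)],
                      "sex", {"female": "sex_female"}, "male", ors)

    year = records["birth_year"].to_numpy()
    rows += _rows_for(records, [(y, year == y) for y in BIRTH_YEARS],
                      "birth_year", {y: f"birth_year:{y}" for y in BIRTH_YEARS[1:]},
                      BIRTH_YEARS[0], ors)
    return pd.DataFrame(rows)


def descriptive_table_markdown(table: pd.DataFrame) -> str:
    lines = ["| Variable | Category | N | % | Self-harm % | OR | 95% CI |",
             "|---|---|---:|---:|---:|---|---|"]
    for _, r in table.iterrows():
        if r["reference"]:
            or_txt, ci_txt = "ref.", ""
        elif np.isnan(r["odds_ratio"]):
            or_txt, ci_txt = "", ""
        else:
            or_txt = f"{r['odds_ratio']:.2f}"
            ci_txt = f"{r['ci_low']:.2f}-{r['ci_high']:.2f}"
        lines.append(
            f"| {r['block']} | {r['category']} | {r['n']:,} | {r['percent']:.1f} "
            f"| {r['outcome_prevalence_pct']:.1f} | {or_txt} | {ci_txt} |")
    return "\n".join(lines)


def mediation_table_markdown(med_table: pd.DataFrame) -> str:
    lines = ["| Direct effect definition | % mediated | 95% CI (normal) |",
             "|---|---:|---|"]
    for _, r in med_table.iterrows():
        if r.get("undefined", False):
            lines.append(f"| {r['direct_effect']} | undefined | |")
        else:
            lines.append(f"| {r['direct_effect']} | {r['percent_mediated']:.0f} "
                         f"| {r['ci_normal_low']:.0f}-{r['ci_normal_high']:.0f} |")
    return "\n".join(lines)
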
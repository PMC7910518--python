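"""Synthetic registry cohort generator.

Emits raw, per-child register-style records: five annual equivalised family
incomes (ages 8-12), five annual family-structure states, parental adversity
flags, parental education, annual adolescent episode flags (ages 13-17), a
numeric school-leaving GPA with a missing fraction, the young-adult self-harm
outcome, and sequential exclusion flags.  The causal structure is the one the
downstream analysis assumes: confounders shift income downward, mediators
follow logistic models in confounders and income quintile, and the outcome
follows a logistic model in confounders, income quintile and all mediators.

Quintile membership used during generation is derived exactly as the cohort
builder derives it (empirical fifths of the mean annual income), so the
generated and rebuilt exposure agree record by record up to boundary noise
from the small annual income perturbations.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from . import calibration
from .config import (
    ADOLESCENT_AGES,
    EDUCATION_LEVELS,
    EXCLUSION_RULES,
    FAMILY_CATEGORIES,
    FAMILY_STATES,
    GPA,
    GPA_BANDS,
    GPA_UPPER_SPLIT_DAMPING,
    INCOME_COLUMNS,
    MEDIATORS,
    OUTCOME,
    GeneratorConfig,
)

__all__ = ["generate_cohort", "write_cohort_csv", "read_cohort_csv",
           "COLUMN_DICTIONARY"]

COLUMN_DICTIONARY = {
    "child_id": "integer child identifier, 0..n-1",
    "birth_year": "birth cohort, 1990-1995",
    "sex_female": "1 = female, 0 = male",
    "income_age_8..income_age_12": "annual equivalised disposable family income, EUR; may be empty",
    "family_state_age_8..family_state_age_12": "two_parent / single_parent / no_parents",
    "parental_psychiatric": "either parent ever treated for a psychiatric disorder during childhood",
    "parental_substance": "parental substance abuse ever during childhood",
    "parental_violent": "parental violent crime ever during childhood",
    "parental_education": "highest parental education: basic / secondary / tertiary",
    "<mediator>_age_13..17": "annual adolescent episode flags, one block per mediator",
    "gpa": "grade point average at end of compulsory school (4-10); empty if never applied",
    "y_self_harm": "hospital-presenting self-harm at ages 18-22",
    "excl_*": "sequential exclusion flags (census absence, unlinkable parents, missing income)",
}


def _draw_categorical(rng, shares: Mapping, n: int) -> tuple[np.ndarray, list]:
    cats = list(shares.keys())
    p = np.array([shares[c] for c in cats], dtype=float)
    codes = rng.choice(len(cats), size=n, p=p / p.sum())
    return codes, cats


def _term_lookup(or_map: Mapping[str, float], fam_codes, edu_codes,
                 flags: Mapping[str, np.ndarray]) -> np.ndarray:
    """Per-record confounder log-odds from an odds-ratio map."""
    fam_lut = np.array([math.log(or_map.get(f"family:{c}", 1.0))
                        for c in FAMILY_CATEGORIES])
    edu_lut = np.array([math.log(or_map.get(f"education:{lvl}", 1.0))
                        for lvl in EDUCATION_LEVELS])
    lp = fam_lut[fam_codes] + edu_lut[edu_codes]
    for t, v in flags.items():
        lp = lp + math.log(or_map.get(t, 1.0)) * v
    return lp


def _family_sequences(rng, fam_codes: np.ndarray) -> np.ndarray:
    """(n, 5) state codes consistent with each drawn stability category."""
    n = len(fam_codes)
    seq = np.zeros((n, 5), dtype=np.int64)
    cat = {c: i for i, c in enumerate(FAMILY_CATEGORIES)}
    years = np.arange(5)

    seq[fam_codes == cat["intact_single_parent"]] = 1

    for name, before, after in (("disrupted_two_parent", 0, 1),
                                ("repartnered_single_parent", 1, 0)):
        mask = fam_codes == cat[name]
        t = rng.integers(1, 5, size=int(mask.sum()))
        seq[mask] = np.where(years[None, :] < t[:, None], before, after)

    mask = fam_codes == cat["multiple_changes"]
    k = int(mask.sum())
    # two change points -> pattern A B A with exactly two transitions
    t1 = rng.integers(1, 4, size=k)
    t2 = t1 + rng.integers(1, 5 - t1)
    a = rng.integers(0, 2, size=k)
    block = np.where((years[None, :] >= t1[:, None]) & (years[None, :] < t2[:, None]),
                     1 - a[:, None], a[:, None])
    seq[mask] = block

    mask = fam_codes == cat["ever_without_family"]
    k = int(mask.sum())
    rows = np.zeros((k, 5), dtype=np.int64)
    rows[np.arange(k), rng.integers(0, 5, size=k)] = 2
    seq[mask] = rows
    return seq


def _generation_quintiles(mean_income: np.ndarray, child_id: np.ndarray,
                          usable: np.ndarray) -> np.ndarray:
    """Empirical fifths among usable records; others placed by cut values."""
    from .cohort import _ranked_groups

    q = np.empty(len(mean_income), dtype=np.int64)
    q[usable] = _ranked_groups(mean_income[usable], child_id[usable], 5)
    if (~usable).any():
        cuts = [np.max(mean_income[usable][q[usable] == j]) for j in range(1, 5)]
        q[~usable] = np.searchsorted(np.array(cuts), mean_income[~usable]) + 1
    return q


def generate_cohort(config: GeneratorConfig, seed: Optional[int] = None) -> pd.DataFrame:
    """Generate ``config.n_children`` raw child records.

    The RNG is fully determined by ``seed`` (default ``config.seed``);
    identical config and seed give byte-identical cohorts.  Intercepts are
    resolved by closed-form calibration when the config does not carry them.
    """
    config.validate()
    if not config.is_resolved():
        config = calibration.attach(config, calibration.resolve(config))
    params = calibration.detach(config)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_children

    # -- confounders ------------------------------------------------------
    cp = config.confounder_prevalences
    flags = {t: (rng.random(n) < cp[t]).astype(np.int64)
             for t in ("parental_psychiatric", "parental_substance", "parental_violent")}
    sex = (rng.random(n) < cp["sex_female"]).astype(np.int64)
    fam_codes, fam_cats = _draw_categorical(rng, config.family_stability_shares, n)
    edu_codes, edu_lvls = _draw_categorical(rng, config.parental_education_shares, n)
    year_codes, years = _draw_categorical(rng, config.birth_year_shares, n)
    birth_year = np.array(years)[year_codes]

    # -- income -----------------------------------------------------------
    w = config.income_adversity_weights
    fam_w = np.array([w.get(f"family:{c}", 0.0) for c in FAMILY_CATEGORIES])
    edu_w = np.array([w.get(f"education:{lvl}", 0.0) for lvl in EDUCATION_LEVELS])
    score = fam_w[fam_codes] + edu_w[edu_codes]
    for t, v in flags.items():
        score = score + w.get(t, 0.0) * v
    log_latent = (config.income_log_mean - config.income_adversity_scale * score
                  + config.income_log_sd * rng.standard_normal(n))
    annual = np.exp(log_latent[:, None]
                    + config.annual_income_log_sd * rng.standard_normal((n, 5)))

    # -- exclusion quotas (disjoint, assigned to a random permutation) ----
    excl = {rule: np.zeros(n, dtype=np.int64) for rule in EXCLUSION_RULES}
    quotas = [int(config.exclusion_counts.get(rule, 0)) for rule in EXCLUSION_RULES]
    if sum(quotas) > 0:
        perm = rng.permutation(n)
        start = 0
        for rule, k in zip(EXCLUSION_RULES, quotas):
            excl[rule][perm[start:start + k]] = 1
            start += k
        annual[excl["income_all_missing"] == 1] = np.nan

    child_id = np.arange(n, dtype=np.int64)
    has_income = ~np.isnan(annual).all(axis=1)
    mean_income = np.exp(log_latent)        # fallback for all-missing rows
    mean_income[has_income] = np.nanmean(annual[has_income], axis=1)
    usable = has_income & ~np.array(
        [excl[r] for r in EXCLUSION_RULES]).any(axis=0).astype(bool)
    if not usable.any():
        usable = np.ones(n, dtype=bool)
    quintile = _generation_quintiles(mean_income, child_id, usable)

    # -- mediators --------------------------------------------------------
    med_vals = {}
    for m in MEDIATORS:
        lp = (params.mediator_intercepts[m]
              + _term_lookup(config.mediator_confounder_odds_ratios[m],
                             fam_codes, edu_codes, flags)
              + config.income_gradients.get(m, 0.0) * (5.0 - quintile))
        med_vals[m] = (rng.random(n) < expit(lp)).astype(np.int64)

    # -- GPA: sequential splits from the lowest quartile upward -----------
    gor = config.mediator_confounder_odds_ratios[GPA]
    gpa_conf = _term_lookup(gor, fam_codes, edu_codes, flags)
    a1, a2, a3 = params.gpa_split_intercepts
    p_low = expit(a1 + gpa_conf + config.income_gradients.get(GPA, 0.0) * (5.0 - quintile))
    p3 = expit(a2 + GPA_UPPER_SPLIT_DAMPING * gpa_conf)
    p2 = expit(a3 + GPA_UPPER_SPLIT_DAMPING * gpa_conf)
    u1, u2, u3 = rng.random(n), rng.random(n), rng.random(n)
    cat = np.where(u1 < p_low, 4, np.where(u2 < p3, 3, np.where(u3 < p2, 2, 1)))
    band = np.array(GPA_BANDS)                       # highest quartile first
    lo, hi = band[cat - 1, 0], band[cat - 1, 1]
    gpa = lo + rng.random(n) * (hi - lo)
    gpa_missing = rng.random(n) < config.gpa_missing_rate
    gpa[gpa_missing] = np.nan
    built_gpa = np.where(gpa_missing, 4, cat)

    # -- outcome ----------------------------------------------------------
    oor = config.outcome_model_odds_ratios
    beta_q = np.array([math.log(oor[f"income_q{k}"]) for k in (1, 2, 3, 4)] + [0.0])
    gpa_lut = np.array([0.0] + [math.log(oor[f"gpa:{k}"]) for k in (2, 3, 4)])
    lp_y = (params.outcome_intercept
            + _term_lookup(oor, fam_codes, edu_codes, flags)
            + math.log(oor.get("sex_female", 1.0)) * sex
            + beta_q[quintile - 1]
            + gpa_lut[built_gpa - 1])
    for m in MEDIATORS:
        lp_y = lp_y + math.log(oor[m]) * med_vals[m]
    y = (rng.random(n) < expit(lp_y)).astype(np.int64)

    # -- annual episode flags ---------------------------------------------
    data = {
        "child_id": child_id,
        "birth_year": birth_year,
        "sex_female": sex,
        **{c: annual[:, j] for j, c in enumerate(INCOME_COLUMNS)},
    }
    states = _family_sequences(rng, fam_codes)
    labels = np.array(FAMILY_STATES, dtype=object)
    for j, a in enumerate(range(8, 13)):
        data[f"family_state_age_{a}"] = labels[states[:, j]]
    data.update(flags)
    data["parental_education"] = np.array(edu_lvls, dtype=object)[edu_codes]
    for m in MEDIATORS:
        ever = med_vals[m]
        yr = rng.integers(0, 5, size=n)
        block = np.zeros((n, 5), dtype=np.int64)
        block[np.arange(n), yr] = ever
        for j, a in enumerate(ADOLESCENT_AGES):
            data[f"{m}_age_{a}"] = block[:, j]
    data["gpa"] = gpa
    data[OUTCOME] = y
    for rule in EXCLUSION_RULES:
        data[f"excl_{rule}"] = excl[rule]
    return pd.DataFrame(data)


def write_cohort_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, float_format="%.2f")


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
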
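"""Raw registry records -> analytic sample.

Applies the sequential exclusion rules, averages childhood income and cuts
it into quintiles, classifies five-year family-structure sequences, derives
"ever during adolescence" mediator indicators and GPA quartiles (missing
grades folded into the lowest quartile).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .config import (
    ADOLESCENT_AGES,
    EXCLUSION_COLUMNS,
    EXCLUSION_RULES,
    FAMILY_STATE_COLUMNS,
    FAMILY_STATES,
    INCOME_COLUMNS,
    MEDIATORS,
    OUTCOME,
    PARENTAL_FLAGS,
)

_STATE_CODE = {s: i for i, s in enumerate(FAMILY_STATES)}

ANALYTIC_COLUMNS = (
    ("child_id", "sex_female", "birth_year", "income_quintile")
    + PARENTAL_FLAGS
    + ("family_stability", "parental_education")
    + MEDIATORS
    + ("gpa_quartile", OUTCOME)
)


@dataclass
class ExclusionReport:
    initial_count: int
    excluded: dict
    final_count: int

    @property
    def excluded_percent(self) -> float:
        return 100.0 * (self.initial_count - self.final_count) / self.initial_count

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["excluded_percent"] = self.excluded_percent
        return json.dumps(d, indent=2)

    def log_lines(self) -> list[str]:
        lines = [f"initial records: {self.initial_count:,}"]
        for rule in EXCLUSION_RULES:
            lines.append(f"  excluded ({rule.replace('_', ' ')}): {self.excluded[rule]:,}")
        lines.append(f"final sample: {self.final_count:,} "
                     f"({self.excluded_percent:.1f}% excluded)")
        return lines


def apply_exclusions(records: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop flagged children, attributing each to the first rule flagging it."""
    missing = [c for c in EXCLUSION_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"exclusion flags missing from records: {missing}")
    flags = records[list(EXCLUSION_COLUMNS)].to_numpy(dtype=bool)
    # first flagged rule per child; children with no flag get code len(rules)
    first = np.where(flags.any(axis=1), flags.argmax(axis=1), len(EXCLUSION_RULES))
    counts = {rule: int((first == i).sum()) for i, rule in enumerate(EXCLUSION_RULES)}
    kept = records.loc[first == len(EXCLUSION_RULES)].copy()
    report = ExclusionReport(initial_count=len(records), excluded=counts,
                             final_count=len(kept))
    return kept, report


def _ranked_groups(values: np.ndarray, ids: np.ndarray, k: int) -> np.ndarray:
    """Cut ``values`` into k ascending groups of near-equal size (1..k).

    Ties are broken by the stable secondary key ``ids`` so group sizes never
    differ by more than one and assignment is permutation-invariant.
    """
    n = len(values)
    order = np.lexsort((ids, values))
    group = np.empty(n, dtype=np.int64)
    group[order] = np.arange(n) * k // n + 1
    return group


def mean_childhood_income(records: pd.DataFrame) -> pd.Series:
    """Per-child mean of available annual equivalised incomes."""
    incomes = records[list(INCOME_COLUMNS)]
    means = incomes.mean(axis=1, skipna=True)
    if means.isna().any():
        raise ValueError(
            "children with all childhood incomes missing reached quintile "
            "derivation; exclusions must be applied first")
    return means


def derive_income_quintiles(records: pd.DataFrame) -> pd.DataFrame:
    """Attach ``income_quintile`` (1 = lowest fifth of mean childhood income)."""
    means = mean_childhood_income(records)
    out = records.copy()
    out["income_quintile"] = _ranked_groups(
        means.to_numpy(), records["child_id"].to_numpy(), 5)
    return out


def classify_family_stability(sequence: Sequence[str]) -> str:
    """Classify one five-year family-structure sequence.

    A year without parents dominates (institutional or foster care makes
    transition counting ambiguous); otherwise the number and direction of
    transitions decides the category.
    """
    if len(sequence) != 5:
        raise ValueError("family sequence must have exactly 5 annual states")
    try:
        codes = [_STATE_CODE[s] for s in sequence]
    except KeyError as err:
        raise ValueError(f"invalid family state token: {err.args[0]!r}") from None
    return _classify_codes(np.asarray(codes, dtype=np.int64)[None, :])[0]


def _classify_codes(codes: np.ndarray) -> np.ndarray:
    transitions = (codes[:, 1:] != codes[:, :-1]).sum(axis=1)
    ever_out = (codes == _STATE_CODE["no_parents"]).any(axis=1)
    start_two = codes[:, 0] == _STATE_CODE["two_parent"]
    result = np.select(
        [ever_out,
         transitions >= 2,
         (transitions == 1) & start_two,
         (transitions == 1) & ~start_two,
         start_two],
        np.array(["ever_without_family", "multiple_changes", "disrupted_two_parent",
                  "repartnered_single_parent", "intact_two_parent"], dtype=object),
        default="intact_single_parent",
    )
    return result.astype(object)


def derive_family_stability(records: pd.DataFrame) -> pd.DataFrame:
    cols = records[list(FAMILY_STATE_COLUMNS)]
    codes = np.empty(cols.shape, dtype=np.int64)
    for j, c in enumerate(FAMILY_STATE_COLUMNS):
        s = cols[c]
        bad = ~s.isin(FAMILY_STATES)
        if bad.any():
            raise ValueError(f"invalid family state token in {c}: "
                             f"{s[bad].iloc[0]!r}")
        codes[:, j] = s.map(_STATE_CODE).to_numpy()
    out = records.copy()
    out["family_stability"] = _classify_codes(codes)
    return out


def derive_gpa_quartiles(records: pd.DataFrame) -> pd.DataFrame:
    """Attach ``gpa_quartile`` (1 = highest GPA; missing -> lowest quartile 4).

    Cut points come from the empirical quartiles of non-missing grades; ties
    are broken by child_id so the assignment is deterministic.
    """
    gpa = records["gpa"].to_numpy(dtype=float)
    ids = records["child_id"].to_numpy()
    quart = np.full(len(records), 4, dtype=np.int64)
    nonmiss = ~np.isnan(gpa)
    if nonmiss.any():
        # rank descending: highest grades -> quartile 1
        quart[nonmiss] = _ranked_groups(-gpa[nonmiss], ids[nonmiss], 4)
    out = records.copy()
    out["gpa_quartile"] = quart
    return out


def derive_ever_indicator(flags: np.ndarray | pd.DataFrame) -> np.ndarray:
    """1 iff any of the annual episode flags is set."""
    arr = np.asarray(flags)
    if arr.ndim == 1:
        return np.asarray(arr.any(), dtype=np.int64)
    return arr.any(axis=1).astype(np.int64)


def derive_mediator_indicators(records: pd.DataFrame) -> pd.DataFrame:
    out = records.copy()
    for m in MEDIATORS:
        cols = [f"{m}_age_{a}" for a in ADOLESCENT_AGES]
        out[m] = derive_ever_indicator(records[cols].to_numpy())
    return out


def build_analytic(records: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Full construction: exclusions, exposure, confounders, mediators.

    Column assignments happen on the single post-exclusion copy; the
    individual ``derive_*`` functions share the same implementations.
    """
    kept, report = apply_exclusions(records)
    ids = kept["child_id"].to_numpy()
    kept["income_quintile"] = _ranked_groups(
        mean_childhood_income(kept).to_numpy(), ids, 5)
    codes = np.empty((len(kept), 5), dtype=np.int64)
    for j, c in enumerate(FAMILY_STATE_COLUMNS):
        s = kept[c]
        bad = ~s.isin(FAMILY_STATES)
        if bad.any():
            raise ValueError(f"invalid family state token in {c}: {s[bad].iloc[0]!r}")
        codes[:, j] = s.map(_STATE_CODE).to_numpy()
    kept["family_stability"] = _classify_codes(codes)
    gpa = kept["gpa"].to_numpy(dtype=float)
    quart = np.full(len(kept), 4, dtype=np.int64)
    nonmiss = ~np.isnan(gpa)
    if nonmiss.any():
        quart[nonmiss] = _ranked_groups(-gpa[nonmiss], ids[nonmiss], 4)
    kept["gpa_quartile"] = quart
    for m in MEDIATORS:
        cols = [f"{m}_age_{a}" for a in ADOLESCENT_AGES]
        kept[m] = derive_ever_indicator(kept[cols].to_numpy())
    analytic = kept[list(ANALYTIC_COLUMNS)].reset_index(drop=True)
    if analytic.isna().any().any():
        raise ValueError("analytic sample contains missing values")
    return analytic, report
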
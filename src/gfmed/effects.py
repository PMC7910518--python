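"""Effect decomposition from the iteration ledger.

Per bootstrap iteration the engine records scenario means; this module turns
them into total effects (TE), treated-group effects (ATT), total direct
effects (TDE) and natural indirect effects (NIE = TE - TDE), on the absolute
scale (difference in proportions) and the relative scale (percentage
reduction, 1 - counterfactual/natural-course).  The percentage mediated is
the ratio of across-iteration average NIE to average TE: with a rare outcome
the per-iteration TDE fluctuates around zero, so per-iteration ratios are
unstable while the ratio of averages is not.  Confidence intervals for
effects are percentile bootstrap intervals; for the mediated percentage both
a delta-method normal interval and a Fieller interval are provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import ALL_MEDIATORS
from .engine import CF, NC, TDE, per_mediator_name

#: |mean TE| below this floor makes ratio estimands undefined
TE_FLOOR = 1e-12

EFFECTS = ("TE", "TDE", "NIE")


def _pivot(ledger: pd.DataFrame, metric: str) -> pd.DataFrame:
    if metric not in ledger.columns:
        raise KeyError(f"metric {metric!r} not present in ledger")
    return ledger.pivot(index="iteration", columns="scenario", values=metric)


def iteration_effects(ledger: pd.DataFrame, metric: str = "outcome",
                      nc: str = NC, cf: str = CF,
                      tde: Optional[str] = TDE) -> pd.DataFrame:
    """Per-iteration effect table; the TE = TDE + NIE identity is exact."""
    wide = _pivot(ledger, metric)
    out = pd.DataFrame(index=wide.index)
    out["TE_abs"] = wide[cf] - wide[nc]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["TE_rel"] = np.where(wide[nc] > 0, 1.0 - wide[cf] / wide[nc], np.nan)
    if tde is not None and tde in wide.columns:
        out["TDE_abs"] = wide[tde] - wide[nc]
        with np.errstate(divide="ignore", invalid="ignore"):
            out["TDE_rel"] = np.where(wide[nc] > 0, 1.0 - wide[tde] / wide[nc], np.nan)
        out["NIE_abs"] = out["TE_abs"] - out["TDE_abs"]
        out["NIE_rel"] = out["TE_rel"] - out["TDE_rel"]
    return out


@dataclass
class EffectEstimates:
    """Point estimates (across-iteration means) with percentile intervals."""

    table: pd.DataFrame      # rows: effect x scale; columns: estimate, ci_low, ci_high
    per_iteration: pd.DataFrame

    def estimate(self, effect: str, scale: str = "rel") -> float:
        return float(self.table.loc[(effect, scale), "estimate"])

    def ci(self, effect: str, scale: str = "rel") -> tuple[float, float]:
        row = self.table.loc[(effect, scale)]
        return float(row["ci_low"]), float(row["ci_high"])


def compute_effects(ledger: pd.DataFrame, metric: str = "outcome",
                    alpha: float = 0.05) -> EffectEstimates:
    """TE/TDE/NIE with bootstrap percentile confidence intervals.

    When the natural-course mean is zero in some iteration the relative
    effects are undefined (NaN) there; absolute effects are always returned.
    """
    per_it = iteration_effects(ledger, metric)
    rows = []
    for col in per_it.columns:
        effect, scale = col.split("_")
        vals = per_it[col].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if len(finite) == 0:
            est = lo = hi = np.nan
        else:
            est = float(np.mean(finite))
            lo, hi = np.percentile(finite, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        rows.append({"effect": effect, "scale": scale, "estimate": est,
                     "ci_low": float(lo), "ci_high": float(hi),
                     "n_iterations": int(len(finite))})
    table = pd.DataFrame(rows).set_index(["effect", "scale"])
    return EffectEstimates(table, per_it)


# --------------------------------------------------------------------------
# percentage mediated
# --------------------------------------------------------------------------

@dataclass
class MediationRow:
    direct_effect: str            # "TDE" or "TDE + <mediator>"
    percent_mediated: float
    ci_normal: tuple
    ci_fieller: tuple
    n_iterations: int
    mean_nie: float
    mean_te: float
    undefined: bool = False
    note: str = ""


def _fieller_interval(num: float, den: float, v_num: float, v_den: float,
                      cov: float, z: float) -> tuple[float, float]:
    """Fieller bounds for num/den with (approximately) normal moments."""
    a = den * den - z * z * v_den
    b = num * den - z * z * cov
    c = num * num - z * z * v_num
    disc = b * b - a * c
    if a <= 0 or disc < 0:
        return (-np.inf, np.inf)
    root = math.sqrt(disc)
    return ((b - root) / a, (b + root) / a)


def percent_mediated(ledger: pd.DataFrame, absorbed: Optional[str] = None,
                     metric: str = "outcome", alpha: float = 0.05) -> MediationRow:
    """Mediated percentage as the ratio of average NIE to average TE.

    ``absorbed`` names a mediator whose pathway is folded into the direct
    effect (its single-mediator scenario replaces the TDE scenario); ``None``
    gives the all-mediator decomposition.  The normal interval uses the delta
    method with the empirical covariance of the two bootstrap means; the
    Fieller interval inverts the same moments exactly.
    """
    wide = _pivot(ledger, metric)
    direct_scen = TDE if absorbed is None else per_mediator_name(absorbed)
    label = "TDE" if absorbed is None else f"TDE + {absorbed}"
    if direct_scen not in wide.columns:
        raise KeyError(f"scenario {direct_scen!r} missing from ledger")
    te = (wide[CF] - wide[NC]).to_numpy(dtype=float)
    nie = (wide[CF] - wide[direct_scen]).to_numpy(dtype=float)
    b = len(te)
    mean_te, mean_nie = float(np.mean(te)), float(np.mean(nie))
    if abs(mean_te) < TE_FLOOR:
        return MediationRow(label, np.nan, (np.nan, np.nan), (np.nan, np.nan), b,
                            mean_nie, mean_te, undefined=True,
                            note=f"mean TE {mean_te:.3e} below numerical floor")
    ratio = mean_nie / mean_te
    if b > 1:
        cov = np.cov(np.vstack([nie, te]), ddof=1) / b   # covariance of the means
        v_n, v_t, c_nt = cov[0, 0], cov[1, 1], cov[0, 1]
    else:
        v_n = v_t = c_nt = 0.0
    z = norm.ppf(1 - alpha / 2)
    var_ratio = (v_n - 2 * ratio * c_nt + ratio * ratio * v_t) / (mean_te * mean_te)
    half = z * math.sqrt(max(var_ratio, 0.0))
    ci_norm = (100 * (ratio - half), 100 * (ratio + half))
    f_lo, f_hi = _fieller_interval(mean_nie, mean_te, v_n, v_t, c_nt, z)
    return MediationRow(label, 100 * ratio, ci_norm,
                        (100 * f_lo, 100 * f_hi), b, mean_nie, mean_te)


def mediation_table(ledger: pd.DataFrame, mediators: Sequence[str] = ALL_MEDIATORS,
                    metric: str = "outcome") -> pd.DataFrame:
    """Mediated percentage across direct-effect definitions."""
    rows = [percent_mediated(ledger, None, metric)]
    for m in mediators:
        if per_mediator_name(m) in set(ledger["scenario"]):
            rows.append(percent_mediated(ledger, m, metric))
    return pd.DataFrame([{
        "direct_effect": r.direct_effect,
        "percent_mediated": r.percent_mediated,
        "ci_normal_low": r.ci_normal[0], "ci_normal_high": r.ci_normal[1],
        "ci_fieller_low": r.ci_fieller[0], "ci_fieller_high": r.ci_fieller[1],
        "n_iterations": r.n_iterations, "undefined": r.undefined,
    } for r in rows])


# --------------------------------------------------------------------------
# subgroup contrasts
# --------------------------------------------------------------------------

def subgroup_effects(ledger: pd.DataFrame, variables: Sequence[str],
                     treated: bool = True, alpha: float = 0.05) -> pd.DataFrame:
    """ATT (or population) effects within strata of the listed confounders.

    Strata with no simulated members are skipped.  Returns a tidy frame
    (variable, level, effect, scale, estimate, ci_low, ci_high).
    """
    prefix = "sub_treated:" if treated else "sub:"
    rows = []
    for var in variables:
        metrics = [c for c in ledger.columns
                   if c.startswith(prefix + var + "=")]
        for metric in metrics:
            level = metric.split("=", 1)[1]
            if ledger[metric].isna().all():
                continue
            est = compute_effects(ledger, metric=metric, alpha=alpha)
            for (effect, scale), row in est.table.iterrows():
                rows.append({"variable": var, "level": level, "effect": effect,
                             "scale": scale, "estimate": row["estimate"],
                             "ci_low": row["ci_low"], "ci_high": row["ci_high"]})
    return pd.DataFrame(rows)


def subgroup_percent_mediated(ledger: pd.DataFrame, variables: Sequence[str],
                              treated: bool = False) -> pd.DataFrame:
    """Heat-map data: mediated percentage per subgroup and direct-effect row."""
    prefix = "sub_treated:" if treated else "sub:"
    rows = []
    for var in variables:
        for metric in [c for c in ledger.columns if c.startswith(prefix + var + "=")]:
            level = metric.split("=", 1)[1]
            if ledger[metric].isna().all():
                continue
            r = percent_mediated(ledger, None, metric)
            rows.append({"variable": var, "level": level,
                         "direct_effect": r.direct_effect,
                         "percent_mediated": r.percent_mediated,
                         "undefined": r.undefined})
    return pd.DataFrame(rows)
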
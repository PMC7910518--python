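"""Monte-Carlo g-formula engine.

Standardization by simulation: given a fitted :class:`~gfmed.models.ModelBundle`
and an analytic cohort, draw mediators and the outcome from their models under
the observed exposure (natural course, NC), under the income intervention
(counterfactual, CF), or in mixed scenarios where selected mediators respond
to the intervention while the rest keep their natural-course draws (direct
effect and per-mediator decomposition scenarios).

Scenario draws inside one inner repetition share uniform variates (common
random numbers), so an identity intervention reproduces NC draws exactly and
paired contrasts have minimal Monte-Carlo variance.  Inner repetitions are
averaged (``n_mc``) to stabilize scenario means; an outer bootstrap resamples
the cohort and refits the models to quantify estimation uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import ALL_MEDIATORS, GPA, MEDIATORS
from .models import BundlePredictor, ModelBundle, ModelFitError, fit_bundle

SIMULATE = "simulate_under_intervention"
COPY_NC = "copy_from_NC"

NC = "NC"
CF = "CF"
TDE = "TDE"


def per_mediator_name(mediator: str) -> str:
    return f"per_mediator:{mediator}"


@dataclass(frozen=True)
class InterventionSpec:
    """Income intervention: move one quintile to another (or do nothing)."""

    kind: str = "none"                      # "none" | "quintile_shift"
    from_quintile: Optional[int] = None
    to_quintile: Optional[int] = None

    def __post_init__(self):
        if self.kind not in ("none", "quintile_shift"):
            raise ValueError(f"unknown intervention kind {self.kind!r}")
        if self.kind == "quintile_shift":
            if self.from_quintile not in range(1, 6) or self.to_quintile not in range(1, 6):
                raise ValueError("quintiles must lie in 1..5")
            if self.from_quintile == self.to_quintile:
                raise ValueError("from_quintile and to_quintile must differ")

    def apply(self, quintile: np.ndarray) -> np.ndarray:
        if self.kind == "none":
            return quintile
        return np.where(quintile == self.from_quintile, self.to_quintile, quintile)


#: the study's intervention: lowest quintile raised to the second-lowest
RAISE_LOWEST = InterventionSpec("quintile_shift", from_quintile=1, to_quintile=2)


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    intervention: InterventionSpec
    mediator_source: Mapping[str, str] = field(
        default_factory=lambda: {m: SIMULATE for m in ALL_MEDIATORS})

    def __post_init__(self):
        if set(self.mediator_source) != set(ALL_MEDIATORS):
            raise ValueError("mediator_source must cover every mediator")
        for m, src in self.mediator_source.items():
            if src not in (SIMULATE, COPY_NC):
                raise ValueError(f"unknown mediator source {src!r} for {m}")


def natural_course() -> ScenarioSpec:
    return ScenarioSpec(NC, InterventionSpec("none"))


def counterfactual(intervention: InterventionSpec = RAISE_LOWEST) -> ScenarioSpec:
    return ScenarioSpec(CF, intervention)


def direct_effect(intervention: InterventionSpec = RAISE_LOWEST) -> ScenarioSpec:
    """All mediators held at natural-course values; exposure intervened."""
    return ScenarioSpec(TDE, intervention,
                        {m: COPY_NC for m in ALL_MEDIATORS})


def single_mediator(mediator: str,
                    intervention: InterventionSpec = RAISE_LOWEST) -> ScenarioSpec:
    """Only one mediator responds to the intervention (its pathway joins the
    direct effect in the decomposition)."""
    if mediator not in ALL_MEDIATORS:
        raise ValueError(f"unknown mediator {mediator!r}")
    src = {m: COPY_NC for m in ALL_MEDIATORS}
    src[mediator] = SIMULATE
    return ScenarioSpec(per_mediator_name(mediator), intervention, src)


def headline_scenarios(intervention: InterventionSpec = RAISE_LOWEST,
                       per_mediator: bool = False) -> list[ScenarioSpec]:
    specs = [natural_course(), counterfactual(intervention), direct_effect(intervention)]
    if per_mediator:
        specs += [single_mediator(m, intervention) for m in ALL_MEDIATORS]
    return specs


@dataclass
class ScenarioResult:
    """Simulated population means for one scenario."""

    scenario: str
    mean_outcome: float
    mean_outcome_treated: float
    mediator_means: dict                 # mediator -> proportion; GPA -> 4 shares
    subgroup_means: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {"scenario": self.scenario, "outcome": self.mean_outcome,
               "outcome_treated": self.mean_outcome_treated}
        for m, v in self.mediator_means.items():
            if m == GPA:
                for k in range(4):
                    row[f"med:gpa:{k + 1}"] = v[k]
            else:
                row[f"med:{m}"] = v
        row.update(self.subgroup_means)
        return row

    @staticmethod
    def average(results: Sequence["ScenarioResult"]) -> "ScenarioResult":
        first = results[0]
        med = {}
        for m in first.mediator_means:
            if m == GPA:
                med[m] = tuple(np.mean([r.mediator_means[m] for r in results], axis=0))
            else:
                med[m] = float(np.mean([r.mediator_means[m] for r in results]))
        sub = {k: float(np.mean([r.subgroup_means[k] for r in results]))
               for k in first.subgroup_means}
        return ScenarioResult(
            first.scenario,
            float(np.mean([r.mean_outcome for r in results])),
            float(np.mean([r.mean_outcome_treated for r in results])),
            med, sub)


class SimulationContext:
    """Precomputed probabilities shared by all inner repetitions."""

    def __init__(self, bundle: ModelBundle, records: pd.DataFrame,
                 intervention: InterventionSpec,
                 treated_quintile: Optional[int] = None,
                 subgroups: Sequence[str] = ()):
        self.n = len(records)
        pred = BundlePredictor(bundle, records)
        self.pred = pred
        q_obs = records["income_quintile"].to_numpy(dtype=int)
        q_int = intervention.apply(q_obs)
        if treated_quintile is None and intervention.kind == "quintile_shift":
            treated_quintile = intervention.from_quintile
        self.treated = (q_obs == treated_quintile if treated_quintile is not None
                        else np.zeros(self.n, dtype=bool))
        self.p_nat = {m: pred.mediator_p(m, q_obs) for m in MEDIATORS}
        self.p_int = {m: pred.mediator_p(m, q_int) for m in MEDIATORS}
        self.gpa_cum_nat = np.cumsum(pred.gpa_probs(q_obs), axis=1)
        self.gpa_cum_int = np.cumsum(pred.gpa_probs(q_int), axis=1)
        self.lp_y_nat = pred.outcome_lp_base(q_obs)
        self.lp_y_int = pred.outcome_lp_base(q_int)
        self.masks = {}
        for var in subgroups:
            col = records[var]
            for lvl in sorted(col.unique(), key=str):
                self.masks[f"{var}={lvl}"] = (col == lvl).to_numpy()

    def _means(self, values: np.ndarray) -> tuple[float, float, dict]:
        overall = float(values.mean())
        treated = float(values[self.treated].mean()) if self.treated.any() else np.nan
        sub = {}
        for key, mask in self.masks.items():
            sub[f"sub:{key}"] = float(values[mask].mean())
            both = mask & self.treated
            sub[f"sub_treated:{key}"] = float(values[both].mean()) if both.any() else np.nan
        return overall, treated, sub


def _simulate_once(ctx: SimulationContext, specs: Sequence[ScenarioSpec],
                   rng: np.random.Generator, draw_mode: str) -> dict:
    """One inner repetition for all scenarios under common random numbers."""
    if draw_mode not in ("binomial", "expectation"):
        raise ValueError(f"unknown draw mode {draw_mode!r}")
    n = ctx.n
    u_med = {m: rng.random(n) for m in MEDIATORS}
    u_gpa = rng.random(n)
    u_y = rng.random(n) if draw_mode == "binomial" else None

    m_nat = {m: (u_med[m] < ctx.p_nat[m]).astype(float) for m in MEDIATORS}
    m_int = {m: (u_med[m] < ctx.p_int[m]).astype(float) for m in MEDIATORS}
    gpa_nat = (u_gpa[:, None] >= ctx.gpa_cum_nat[:, :3]).sum(axis=1) + 1
    gpa_int = (u_gpa[:, None] >= ctx.gpa_cum_int[:, :3]).sum(axis=1) + 1

    out = {}
    for spec in specs:
        intervened = spec.intervention.kind != "none"
        med_vals = {}
        med_means = {}
        for m in MEDIATORS:
            use_int = intervened and spec.mediator_source[m] == SIMULATE
            med_vals[m] = m_int[m] if use_int else m_nat[m]
            if draw_mode == "expectation":
                med_means[m] = float((ctx.p_int[m] if use_int else ctx.p_nat[m]).mean())
            else:
                med_means[m] = float(med_vals[m].mean())
        use_int_gpa = intervened and spec.mediator_source[GPA] == SIMULATE
        gpa_vals = gpa_int if use_int_gpa else gpa_nat
        if draw_mode == "expectation":
            cum = ctx.gpa_cum_int if use_int_gpa else ctx.gpa_cum_nat
            shares = np.diff(np.hstack([np.zeros((n, 1)), cum]), axis=1).mean(axis=0)
            med_means[GPA] = tuple(float(s) for s in shares)
        else:
            med_means[GPA] = tuple(float((gpa_vals == k).mean()) for k in (1, 2, 3, 4))

        lp_base = ctx.lp_y_int if intervened else ctx.lp_y_nat
        p_y = ctx.pred.outcome_p(lp_base, med_vals, gpa_vals)
        y = p_y if draw_mode == "expectation" else (u_y < p_y).astype(float)
        overall, treated, sub = ctx._means(y)
        out[spec.name] = ScenarioResult(spec.name, overall, treated, med_means, sub)
    return out


def simulate_scenario(bundle: ModelBundle, records: pd.DataFrame, spec: ScenarioSpec,
                      rng: np.random.Generator, draw_mode: str = "binomial",
                      treated_quintile: Optional[int] = None) -> ScenarioResult:
    """Single simulation pass for one scenario (NC draws are generated
    alongside whenever the scenario copies natural-course mediators)."""
    ctx = SimulationContext(bundle, records, spec.intervention, treated_quintile)
    return _simulate_once(ctx, [spec], rng, draw_mode)[spec.name]


def run_mc_stabilized(bundle: ModelBundle, records: pd.DataFrame,
                      specs: Sequence[ScenarioSpec] | ScenarioSpec,
                      n_mc: int, rng: np.random.Generator,
                      draw_mode: str = "binomial",
                      treated_quintile: Optional[int] = None,
                      subgroups: Sequence[str] = ()) -> dict:
    """Average scenario means over ``n_mc`` inner Monte-Carlo repetitions."""
    if isinstance(specs, ScenarioSpec):
        specs = [specs]
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    ivs = {s.intervention for s in specs if s.intervention.kind != "none"}
    if len(ivs) > 1:
        raise ValueError("scenarios in one run must share a single intervention")
    iv = ivs.pop() if ivs else specs[0].intervention
    ctx = SimulationContext(bundle, records, iv, treated_quintile, subgroups)
    reps = [_simulate_once(ctx, specs, rng, draw_mode) for _ in range(n_mc)]
    return {s.name: ScenarioResult.average([r[s.name] for r in reps]) for s in specs}


def _bootstrap_iteration(records: pd.DataFrame, specs, n_mc, seed_seq, resample,
                         draw_mode, treated_quintile, subgroups):
    rng = np.random.default_rng(seed_seq)
    if resample:
        idx = rng.integers(len(records), size=len(records))
        sample = records.iloc[idx].reset_index(drop=True)
    else:
        sample = records
    bundle = fit_bundle(sample)
    return run_mc_stabilized(bundle, records, specs, n_mc, rng, draw_mode,
                             treated_quintile, subgroups)


def run_bootstrap(records: pd.DataFrame, specs: Sequence[ScenarioSpec],
                  n_boot: int, n_mc: int, seed: int,
                  resample: bool = True, draw_mode: str = "binomial",
                  treated_quintile: Optional[int] = None,
                  subgroups: Sequence[str] = (),
                  n_jobs: int = 1,
                  max_failure_rate: float = 0.05) -> tuple[pd.DataFrame, list]:
    """Outer bootstrap: resample, refit, simulate all scenarios.

    Returns the iteration ledger (one row per iteration x scenario) and a
    list of ``(iteration, message)`` fitting failures.  Iterations are seeded
    independently from the master seed, so results are identical for any
    ``n_jobs``.  Simulation is always performed on the original cohort
    (standardization to the observed confounder distribution); resampling
    only perturbs the fitted models.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    seeds = np.random.SeedSequence(seed).spawn(n_boot)

    def one(i):
        try:
            return i, _bootstrap_iteration(records, specs, n_mc, seeds[i], resample,
                                           draw_mode, treated_quintile, subgroups), None
        except ModelFitError as err:
            return i, None, str(err)

    if n_jobs == 1:
        outputs = [one(i) for i in range(n_boot)]
    else:
        from joblib import Parallel, delayed
        outputs = Parallel(n_jobs=n_jobs)(delayed(one)(i) for i in range(n_boot))

    rows = []
    failures = []
    for i, result, err in sorted(outputs, key=lambda t: t[0]):
        if err is not None:
            failures.append((i, err))
            continue
        for name, sr in result.items():
            rows.append({"iteration": i, **sr.to_row()})
    if len(failures) > max_failure_rate * n_boot:
        raise RuntimeError(
            f"{len(failures)}/{n_boot} bootstrap iterations failed to fit: "
            f"{failures[:3]}")
    return pd.DataFrame(rows), failures
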
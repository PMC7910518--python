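"""End-to-end orchestration: config -> cohort -> g-formula -> report files."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__, calibration, effects, engine, reporting
from .cohort import build_analytic
from .config import ALL_MEDIATORS, ConfigError, GeneratorConfig
from .synthetic import generate_cohort, read_cohort_csv, write_cohort_csv

DEFAULT_SUBGROUPS = ("parental_psychiatric", "parental_substance",
                     "parental_violent", "family_stability")


@dataclass
class RunConfig:
    """A full g-formula run; defaults reproduce the study configuration
    (n_boot 250, n_mc 100, lowest -> second-lowest quintile, binomial draws)."""

    generator_config: Optional[str] = None     # YAML path; None -> calibrated default
    cohort_csv: Optional[str] = None           # raw cohort CSV; overrides generation
    output_dir: str = "gfmed_output"
    n_children: Optional[int] = None
    from_quintile: int = 1
    to_quintile: int = 2
    per_mediator: bool = True
    n_boot: int = 250
    n_mc: int = 100
    seed: int = 0
    draw_mode: str = "binomial"
    subgroups: Sequence[str] = field(default_factory=lambda: list(DEFAULT_SUBGROUPS))
    n_jobs: int = 1

    def validate(self) -> None:
        problems = []
        if self.n_boot < 1:
            problems.append("n_boot must be >= 1")
        if self.n_mc < 1:
            problems.append("n_mc must be >= 1")
        if self.draw_mode not in ("binomial", "expectation"):
            problems.append(f"unknown draw_mode {self.draw_mode!r}")
        if not (1 <= self.from_quintile <= 5 and 1 <= self.to_quintile <= 5):
            problems.append("intervention quintiles must lie in 1..5")
        if self.from_quintile == self.to_quintile:
            problems.append("intervention must move between two distinct quintiles")
        if self.generator_config and not Path(self.generator_config).exists():
            problems.append(f"generator config not found: {self.generator_config}")
        if self.cohort_csv and not Path(self.cohort_csv).exists():
            problems.append(f"cohort CSV not found: {self.cohort_csv}")
        if problems:
            raise ConfigError("; ".join(problems))


def _config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str)
                          .encode()).hexdigest()[:16]


def run_pipeline(rc: RunConfig) -> dict:
    """Execute the configured run and write all outputs; returns file paths."""
    rc.validate()
    out = Path(rc.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()

    if rc.cohort_csv:
        raw = read_cohort_csv(rc.cohort_csv)
        gen_cfg = None
    else:
        if rc.generator_config:
            gen_cfg = GeneratorConfig.from_yaml(rc.generator_config)
        else:
            gen_cfg = calibration.calibrate_cohort_config()
        if rc.n_children:
            gen_cfg = gen_cfg.replace(n_children=rc.n_children)
        gen_cfg = gen_cfg.replace(seed=rc.seed)
        raw = generate_cohort(gen_cfg)
        gen_cfg.to_yaml(out / "generator_config.yaml")

    analytic, report = build_analytic(raw)
    (out / "exclusion_report.json").write_text(report.to_json())
    write_cohort_csv(analytic, out / "analytic_cohort.csv")

    desc = reporting.render_descriptive_table(analytic)
    desc.to_csv(out / "descriptive_table.csv", index=False)
    (out / "descriptive_table.md").write_text(
        reporting.descriptive_table_markdown(desc))

    intervention = engine.InterventionSpec("quintile_shift", rc.from_quintile,
                                           rc.to_quintile)
    specs = engine.headline_scenarios(intervention, per_mediator=rc.per_mediator)
    ledger, failures = engine.run_bootstrap(
        analytic, specs, rc.n_boot, rc.n_mc, rc.seed,
        draw_mode=rc.draw_mode, treated_quintile=rc.from_quintile,
        subgroups=rc.subgroups, n_jobs=rc.n_jobs)
    ledger.to_csv(out / "iteration_ledger.csv", index=False)

    eff_frames = []
    dist_frames = []
    for metric, label in (("outcome", "population"), ("outcome_treated", "treated")):
        est = effects.compute_effects(ledger, metric=metric)
        t = est.table.reset_index()
        t.insert(0, "target", label)
        eff_frames.append(t)
        d = est.per_iteration.reset_index()
        d.insert(0, "target", label)
        dist_frames.append(d)
    pd.concat(eff_frames).to_csv(out / "effects.csv", index=False)
    # per-iteration effect distributions (density-plot data)
    pd.concat(dist_frames).to_csv(out / "effect_distributions.csv", index=False)

    med = effects.mediation_table(ledger, ALL_MEDIATORS if rc.per_mediator else ())
    med.to_csv(out / "mediation_table.csv", index=False)
    (out / "mediation_table.md").write_text(reporting.mediation_table_markdown(med))

    if rc.subgroups:
        effects.subgroup_effects(ledger, rc.subgroups).to_csv(
            out / "subgroup_effects.csv", index=False)
        effects.subgroup_percent_mediated(ledger, rc.subgroups).to_csv(
            out / "subgroup_percent_mediated.csv", index=False)

    manifest = {
        "gfmed_version": __version__,
        "seed": rc.seed,
        "run_config": dataclasses.asdict(rc),
        "generator_config_hash": _config_hash(gen_cfg.to_dict()) if gen_cfg else None,
        "n_records_raw": int(len(raw)),
        "n_records_analytic": int(len(analytic)),
        "bootstrap_failures": [{"iteration": i, "error": e} for i, e in failures],
        "complete": True,
        "runtime_seconds": round(time.time() - t_start, 1),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {p.name: str(p) for p in sorted(out.iterdir())}
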
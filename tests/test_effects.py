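"""Effect decomposition, percentage mediated, Fieller interval, subgroups."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from gfmed import effects
from gfmed.engine import CF, NC, TDE, per_mediator_name


def _ledger(nc, cf, tde=None, per_med=None, **extra_cols):
    """Wide iteration ledger from per-scenario value lists."""
    rows = []
    for i in range(len(nc)):
        entries = [(NC, nc[i]), (CF, cf[i])]
        if tde is not None:
            entries.append((TDE, tde[i]))
        if per_med:
            for m, vals in per_med.items():
                entries.append((per_mediator_name(m), vals[i]))
        for scen, v in entries:
            row = {"iteration": i, "scenario": scen, "outcome": v,
                   "outcome_treated": v * 1.5}
            for c, vals2 in extra_cols.items():
                row[c] = vals2[i]
            rows.append(row)
    return pd.DataFrame(rows)


class TestComputeEffects:
    def test_hand_audited_toy_ledger(self):
        """Five iterations re-computed by an independent spreadsheet-style
        pass (plain python loops) match exactly."""
        nc = [0.0100, 0.0102, 0.0098, 0.0101, 0.0099]
        cf = [0.0097, 0.0099, 0.0096, 0.0098, 0.0097]
        tde = [0.0099, 0.0101, 0.0098, 0.0100, 0.0098]
        led = _ledger(nc, cf, tde)
        est = effects.compute_effects(led)
        te_abs = [c - n for c, n in zip(cf, nc)]
        te_rel = [1 - c / n for c, n in zip(cf, nc)]
        nie_abs = [(c - n) - (t - n) for c, n, t in zip(cf, nc, tde)]
        assert est.estimate("TE", "abs") == pytest.approx(sum(te_abs) / 5, abs=1e-15)
        assert est.estimate("TE", "rel") == pytest.approx(sum(te_rel) / 5, abs=1e-15)
        assert est.estimate("NIE", "abs") == pytest.approx(sum(nie_abs) / 5, abs=1e-15)
        lo, hi = est.ci("TE", "abs")
        assert lo == pytest.approx(np.percentile(te_abs, 2.5), abs=1e-15)
        assert hi == pytest.approx(np.percentile(te_abs, 97.5), abs=1e-15)

    def test_decomposition_identity_exact(self, rng):
        nc = 0.01 + 0.001 * rng.random(40)
        cf = nc - 0.0004 * rng.random(40)
        tde = nc - 0.0002 * rng.random(40)
        est = effects.compute_effects(_ledger(nc, cf, tde))
        per = est.per_iteration
        assert np.abs(per["TE_abs"] - (per["TDE_abs"] + per["NIE_abs"])).max() < 1e-15
        assert (est.estimate("TE", "abs")
                == pytest.approx(est.estimate("TDE", "abs")
                                 + est.estimate("NIE", "abs"), abs=1e-15))

    def test_null_contrast_zero_effects_zero_width_ci(self):
        nc = [0.01, 0.011, 0.012]
        est = effects.compute_effects(_ledger(nc, nc, nc))
        for effect in ("TE", "TDE", "NIE"):
            for scale in ("abs", "rel"):
                assert est.estimate(effect, scale) == 0.0
                assert est.ci(effect, scale) == (0.0, 0.0)

    def test_zero_nc_relative_undefined_absolute_kept(self):
        led = _ledger([0.0, 0.01], [0.001, 0.009], [0.0, 0.0095])
        est = effects.compute_effects(led)
        assert math.isnan(est.per_iteration.loc[0, "TE_rel"])
        assert est.per_iteration.loc[0, "TE_abs"] == pytest.approx(0.001)
        assert est.table.loc[("TE", "rel"), "n_iterations"] == 1

    def test_sign_convention_reduction_positive(self, rng):
        nc = 0.01 + 0.002 * rng.random(30)
        cf = nc - 0.0005 - 0.0001 * rng.random(30)
        per = effects.compute_effects(_ledger(nc, cf)).per_iteration
        assert ((per["TE_abs"] < 0) == (per["TE_rel"] > 0)).all()


class TestPercentMediated:
    def test_fully_mediated_when_tde_scenario_equals_nc(self):
        nc = [0.0100, 0.0101, 0.0099]
        cf = [0.0095, 0.0096, 0.0094]
        row = effects.percent_mediated(_ledger(nc, cf, tde=nc))
        assert row.percent_mediated == pytest.approx(100.0)

    def test_ratio_arithmetic_matches_reported_convention(self):
        """Relative TE 7.0% with relative TDE 2.31% leaves 67% mediated."""
        nc = [0.0140] * 4
        cf = [0.0140 * (1 - 0.070)] * 4
        tde = [0.0140 * (1 - 0.0231)] * 4
        row = effects.percent_mediated(_ledger(nc, cf, tde))
        assert row.percent_mediated == pytest.approx(100 * (1 - 0.0231 / 0.070),
                                                     abs=1e-9)
        assert round(row.percent_mediated) == 67

    def test_zero_variance_intervals_collapse_to_point(self):
        nc, cf, tde = [0.010] * 6, [0.0095] * 6, [0.0099] * 6
        row = effects.percent_mediated(_ledger(nc, cf, tde))
        assert row.ci_normal[0] == pytest.approx(row.percent_mediated)
        assert row.ci_normal[1] == pytest.approx(row.percent_mediated)
        assert row.ci_fieller[0] == pytest.approx(row.percent_mediated)
        assert row.ci_fieller[1] == pytest.approx(row.percent_mediated)

    def test_te_below_floor_reported_undefined(self):
        nc = [0.01, 0.01]
        row = effects.percent_mediated(_ledger(nc, nc, tde=nc))
        assert row.undefined
        assert math.isnan(row.percent_mediated)
        assert "floor" in row.note

    def test_absorbed_mediator_uses_its_scenario(self):
        nc = [0.0100] * 3
        cf = [0.0093] * 3
        tde = [0.00977] * 3
        s_gpa = [0.00965] * 3
        led = _ledger(nc, cf, tde, per_med={"gpa": s_gpa})
        row = effects.percent_mediated(led, absorbed="gpa")
        assert row.direct_effect == "TDE + gpa"
        assert row.percent_mediated == pytest.approx(
            100 * (0.0093 - 0.00965) / (0.0093 - 0.0100), abs=1e-9)
        table = effects.mediation_table(led, ("gpa",))
        assert list(table.direct_effect) == ["TDE", "TDE + gpa"]

    def test_ratio_of_averages_close_to_median_of_ratios(self, rng):
        """On a well-behaved ledger (TE bounded away from zero) the two
        stabilizations agree within a few points."""
        b = 300
        nc = np.full(b, 0.014)
        te = -0.00098 + 0.0002 * rng.standard_normal(b)
        nie = 0.67 * te + 0.00005 * rng.standard_normal(b)
        cf = nc + te
        tde = cf - nie
        row = effects.percent_mediated(_ledger(nc, cf, tde))
        med_of_ratios = 100 * np.median(nie / te)
        assert abs(row.percent_mediated - med_of_ratios) < 3.0

    def test_fieller_interval_coverage_against_simulation(self):
        """Fieller intervals built from sample moments cover the true ratio
        at close to nominal rate over 1,000 simulated ledgers."""
        rng = np.random.default_rng(77)
        mu_n, mu_t = 6.7e-4, 1.0e-3
        sd_n, sd_t, rho = 1.2e-4, 2.0e-4, 0.5
        cov = rho * sd_n * sd_t
        true_ratio = 100 * mu_n / mu_t
        z = norm.ppf(0.975)
        b = 40
        hits = 0
        for _ in range(1000):
            draws = rng.multivariate_normal(
                [mu_n, mu_t], [[sd_n ** 2, cov], [cov, sd_t ** 2]], size=b)
            n_bar, t_bar = draws.mean(axis=0)
            c = np.cov(draws.T, ddof=1) / b
            lo, hi = effects._fieller_interval(n_bar, t_bar, c[0, 0], c[1, 1],
                                               c[0, 1], z)
            if 100 * lo <= true_ratio <= 100 * hi:
                hits += 1
        assert abs(hits / 1000 - 0.95) < 0.02


class TestSubgroups:
    def test_exchangeable_strata_agree(self):
        nc = [0.0100, 0.0102, 0.0098]
        cf = [0.0096, 0.0097, 0.0095]
        led = _ledger(nc, cf, tde=None,
                      **{"sub_treated:parental_psychiatric=0": [0.01] * 6,
                         "sub_treated:parental_psychiatric=1": [0.01] * 6})
        # identical stratum columns -> identical estimates
        out = effects.subgroup_effects(led, ["parental_psychiatric"])
        te = out[(out.effect == "TE") & (out.scale == "abs")]
        assert te.estimate.nunique() == 1

    def test_covers_requested_modifiers_and_levels(self, small_cohort):
        from gfmed import engine
        analytic = small_cohort[1]
        specs = engine.headline_scenarios()
        led, _ = engine.run_bootstrap(
            analytic, specs, 2, 1, seed=3, draw_mode="expectation",
            treated_quintile=1,
            subgroups=("parental_psychiatric", "parental_substance",
                       "parental_violent", "family_stability"))
        out = effects.subgroup_effects(led, ("parental_psychiatric",
                                             "parental_substance",
                                             "parental_violent",
                                             "family_stability"))
        assert set(out.variable) == {"parental_psychiatric", "parental_substance",
                                     "parental_violent", "family_stability"}
        fam_levels = set(out[out.variable == "family_stability"].level)
        assert len(fam_levels) == 6
        heat = effects.subgroup_percent_mediated(led, ("parental_psychiatric",))
        assert set(heat.level) == {"0", "1"}
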
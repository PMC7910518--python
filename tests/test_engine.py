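"""g-formula engine: pairing, stabilization, bootstrap, standardization oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from gfmed import engine
from gfmed.config import GPA, MEDIATORS, OUTCOME
from gfmed.models import CONF_TERMS, INCOME_TERMS, MEDIATOR_TERMS, FittedLogit, ModelBundle


def test_scenario_spec_invariants():
    with pytest.raises(ValueError):
        engine.InterventionSpec("quintile_shift", 2, 2)
    with pytest.raises(ValueError):
        engine.InterventionSpec("quintile_shift", 0, 2)
    with pytest.raises(ValueError):
        engine.ScenarioSpec("bad", engine.RAISE_LOWEST, {"neet": "simulate_under_intervention"})
    tde = engine.direct_effect()
    assert all(v == engine.COPY_NC for v in tde.mediator_source.values())
    pm = engine.single_mediator("neet")
    assert pm.mediator_source["neet"] == engine.SIMULATE
    assert pm.mediator_source["gpa"] == engine.COPY_NC


def test_identity_intervention_reproduces_nc_exactly(small_cohort, small_bundle):
    """Under shared draw streams an intervention that changes nothing yields
    draws identical to the natural course: TE is exactly zero."""
    analytic = small_cohort[1]
    null_cf = engine.ScenarioSpec("CF", engine.InterventionSpec("none"))
    res = engine.run_mc_stabilized(
        small_bundle, analytic, [engine.natural_course(), null_cf],
        n_mc=3, rng=np.random.default_rng(0), draw_mode="binomial",
        treated_quintile=1)
    assert res["CF"].mean_outcome == res["NC"].mean_outcome
    assert res["CF"].mean_outcome_treated == res["NC"].mean_outcome_treated
    for m in MEDIATORS:
        assert res["CF"].mediator_means[m] == res["NC"].mediator_means[m]


def test_natural_course_reproduces_observed_data(small_cohort, small_bundle):
    """NC stabilized means sit within Monte-Carlo error of the sample
    prevalences for the outcome and every mediator."""
    analytic = small_cohort[1]
    n = len(analytic)
    res = engine.run_mc_stabilized(
        small_bundle, analytic, engine.natural_course(), n_mc=20,
        rng=np.random.default_rng(1), draw_mode="expectation", treated_quintile=1)
    nc = res["NC"]
    p = analytic[OUTCOME].mean()
    assert abs(nc.mean_outcome - p) < 3 * math.sqrt(p * (1 - p) / n)
    for m in MEDIATORS:
        pm = analytic[m].mean()
        assert nc.mediator_means[m] == pytest.approx(pm, abs=1e-9)  # expectation mode
    q1 = analytic[analytic.income_quintile == 1]
    p1 = q1[OUTCOME].mean()
    assert abs(nc.mean_outcome_treated - p1) < 3 * math.sqrt(p1 * (1 - p1) / len(q1))


def _toy_bundle_and_cohort(n=30_000, seed=0):
    """Hand-constructed coefficients; one binary confounder, mediators off a
    single stratum, so scenario means have a closed form by enumeration."""
    rng = np.random.default_rng(seed)
    conf = (rng.random(n) < 0.4).astype(int)
    quintile = rng.integers(1, 6, size=n)
    frame = pd.DataFrame({
        "child_id": np.arange(n), "sex_female": 0, "birth_year": 1990,
        "income_quintile": quintile, "parental_psychiatric": conf,
        "parental_substance": 0, "parental_violent": 0,
        "family_stability": "intact_two_parent", "parental_education": "tertiary",
        **{m: 0 for m in MEDIATORS}, "gpa_quartile": 1, OUTCOME: 0,
    })
    terms_med = ("const",) + CONF_TERMS + INCOME_TERMS
    terms_out = terms_med + MEDIATOR_TERMS

    def coefs(terms, values):
        c = np.zeros(len(terms))
        for t, v in values.items():
            c[terms.index(t)] = v
        return c

    models = {}
    for m in MEDIATORS:
        models[m] = FittedLogit(terms_med, coefs(terms_med, {
            "const": -3.0, "parental_psychiatric": 0.8, "income_q1": 0.9,
            "income_q2": 0.5, "income_q3": 0.3, "income_q4": 0.1}))
    models["gpa_lowest"] = FittedLogit(terms_med, coefs(terms_med, {
        "const": -1.1, "parental_psychiatric": 0.4, "income_q1": 0.6}))
    models["gpa_3rd"] = FittedLogit(terms_med, coefs(terms_med, {"const": -0.7}))
    models["gpa_2nd"] = FittedLogit(terms_med, coefs(terms_med, {"const": 0.0}))
    models["outcome"] = FittedLogit(terms_out, coefs(terms_out, {
        "const": -4.6, "parental_psychiatric": 0.3, "income_q1": 0.25,
        "income_q2": 0.2, "income_q3": 0.1, "income_q4": 0.05,
        "adolescent_self_harm": 1.5, "psychiatric_disorder": 1.2,
        "substance_abuse": 0.6, "violent_victimization": 0.3,
        "violent_crime": 0.6, "out_of_home_placement": 0.8, "neet": 0.3,
        "gpa:2": 0.3, "gpa:3": 0.6, "gpa:4": 0.8}))
    return ModelBundle(models), frame


def _enumerate_scenario_mean(bundle, frame, intervened_exposure, responding):
    """Test-local exact standardization: sum over strata x quintile cells and
    all 2^7 x 4 mediator combinations."""
    coef = {name: dict(zip(f.terms, f.coef)) for name, f in bundle.models.items()}
    total = 0.0
    n = len(frame)
    for c in (0, 1):
        for q in (1, 2, 3, 4, 5):
            w = ((frame.parental_psychiatric == c)
                 & (frame.income_quintile == q)).sum() / n
            if w == 0:
                continue
            q_out = 2 if (q == 1 and intervened_exposure) else q

            def med_p(name, member_q):
                cc = coef[name]
                return expit(cc["const"] + cc["parental_psychiatric"] * c
                             + cc.get(f"income_q{member_q}", 0.0))

            probs = {}
            for m in MEDIATORS:
                q_m = 2 if (q == 1 and m in responding) else q
                probs[m] = med_p(m, q_m)
            q_g = 2 if (q == 1 and GPA in responding) else q
            p_low = med_p("gpa_lowest", q_g)
            p3 = med_p("gpa_3rd", q_g)
            p2 = med_p("gpa_2nd", q_g)
            gpa_p = [(1 - p_low) * (1 - p3) * (1 - p2),
                     (1 - p_low) * (1 - p3) * p2,
                     (1 - p_low) * p3, p_low]
            cell = 0.0
            oc = coef["outcome"]
            for combo in range(128):
                bits = [(combo >> j) & 1 for j in range(7)]
                w_combo = 1.0
                lp_m = 0.0
                for j, m in enumerate(MEDIATORS):
                    w_combo *= probs[m] if bits[j] else (1 - probs[m])
                    lp_m += oc[m] * bits[j]
                for g in range(4):
                    lp = (oc["const"] + oc["parental_psychiatric"] * c
                          + oc.get(f"income_q{q_out}", 0.0) + lp_m
                          + (oc[f"gpa:{g + 1}"] if g else 0.0))
                    cell += w_combo * gpa_p[g] * expit(lp)
            total += w * cell
    return total


def test_scenario_means_match_closed_form_standardization():
    """Simulated NC/CF/TDE means agree with the exact standardization
    (enumeration over strata and mediator combinations) within three
    Monte-Carlo standard errors."""
    bundle, frame = _toy_bundle_and_cohort()
    specs = engine.headline_scenarios()
    per_rep = {s.name: [] for s in specs}
    rng = np.random.default_rng(3)
    for _ in range(15):
        res = engine.run_mc_stabilized(bundle, frame, specs, 1, rng,
                                       "expectation", treated_quintile=1)
        for name, sr in res.items():
            per_rep[name].append(sr.mean_outcome)
    expected = {
        "NC": _enumerate_scenario_mean(bundle, frame, False, set()),
        "CF": _enumerate_scenario_mean(bundle, frame, True,
                                       set(MEDIATORS) | {GPA}),
        "TDE": _enumerate_scenario_mean(bundle, frame, True, set()),
    }
    for name, vals in per_rep.items():
        mean = np.mean(vals)
        se = np.std(vals, ddof=1) / math.sqrt(len(vals)) + 1e-9
        assert abs(mean - expected[name]) < max(3 * se, 2e-4), name


def test_n_mc_one_equals_single_simulation(small_cohort, small_bundle):
    analytic = small_cohort[1]
    spec = engine.direct_effect()
    a = engine.run_mc_stabilized(small_bundle, analytic, spec, 1,
                                 np.random.default_rng(42), "binomial",
                                 treated_quintile=1)[engine.TDE]
    b = engine.simulate_scenario(small_bundle, analytic, spec,
                                 np.random.default_rng(42), "binomial",
                                 treated_quintile=1)
    assert a.mean_outcome == b.mean_outcome
    assert a.mediator_means == b.mediator_means


def test_mc_variance_scales_inversely_with_n_mc(small_cohort, small_bundle):
    """log-variance of the stabilized mean falls with slope -1 in log n_mc."""
    analytic = small_cohort[1].head(1500).reset_index(drop=True)
    rng = np.random.default_rng(7)
    variances = []
    for n_mc in (1, 8):
        means = [engine.run_mc_stabilized(small_bundle, analytic,
                                          engine.natural_course(), n_mc, rng,
                                          "binomial")["NC"].mean_outcome
                 for _ in range(200)]
        variances.append(np.var(means, ddof=1))
    slope = (math.log(variances[1]) - math.log(variances[0])) / math.log(8)
    assert slope == pytest.approx(-1.0, abs=0.2)


def test_bootstrap_no_resample_equals_direct_run(small_cohort, small_bundle):
    analytic = small_cohort[1]
    specs = engine.headline_scenarios()
    ledger, failures = engine.run_bootstrap(
        analytic, specs, n_boot=1, n_mc=2, seed=9, resample=False,
        draw_mode="expectation", treated_quintile=1)
    assert failures == []
    rng = np.random.default_rng(np.random.SeedSequence(9).spawn(1)[0])
    direct = engine.run_mc_stabilized(small_bundle, analytic, specs, 2, rng,
                                      "expectation", treated_quintile=1)
    row = ledger[ledger.scenario == engine.NC].iloc[0]
    assert row["outcome"] == pytest.approx(direct[engine.NC].mean_outcome, abs=1e-12)


def test_bootstrap_concentrates_on_point_estimate(small_cohort):
    """Bootstrap means sit within three bootstrap SEs of the no-resample
    estimate (consistency of the resampling loop)."""
    analytic = small_cohort[1]
    specs = [engine.natural_course(), engine.counterfactual()]
    point, _ = engine.run_bootstrap(analytic, specs, 1, 2, seed=1,
                                    resample=False, draw_mode="expectation",
                                    treated_quintile=1)
    boot, failures = engine.run_bootstrap(analytic, specs, 25, 2, seed=2,
                                          draw_mode="expectation",
                                          treated_quintile=1)
    assert len(failures) <= 1          # rare-cell resamples may fail to fit
    for scen in (engine.NC, engine.CF):
        vals = boot.loc[boot.scenario == scen, "outcome"]
        ref = point.loc[point.scenario == scen, "outcome"].iloc[0]
        se = vals.std(ddof=1) / math.sqrt(len(vals))
        assert abs(vals.mean() - ref) < 3 * se


def test_bootstrap_deterministic_across_worker_counts(small_cohort):
    analytic = small_cohort[1]
    specs = [engine.natural_course(), engine.counterfactual()]
    led1, fail1 = engine.run_bootstrap(analytic, specs, 4, 2, seed=5,
                                       draw_mode="expectation", treated_quintile=1,
                                       n_jobs=1, max_failure_rate=0.5)
    led2, fail2 = engine.run_bootstrap(analytic, specs, 4, 2, seed=5,
                                       draw_mode="expectation", treated_quintile=1,
                                       n_jobs=2, max_failure_rate=0.5)
    pd.testing.assert_frame_equal(led1, led2)
    assert fail1 == fail2


def test_bootstrap_failure_policy(small_cohort):
    analytic = small_cohort[1].head(2000).copy().reset_index(drop=True)
    analytic["substance_abuse"] = 0          # empty stratum -> every fit fails
    with pytest.raises(RuntimeError, match="failed to fit"):
        engine.run_bootstrap(analytic, [engine.natural_course()], 4, 1, seed=0)


def test_subgroup_means_recorded(small_cohort, small_bundle):
    analytic = small_cohort[1]
    res = engine.run_mc_stabilized(
        small_bundle, analytic, engine.headline_scenarios(), 2,
        np.random.default_rng(0), "expectation", treated_quintile=1,
        subgroups=("parental_psychiatric", "family_stability"))
    keys = res[engine.NC].subgroup_means.keys()
    assert "sub:parental_psychiatric=1" in keys
    assert "sub_treated:family_stability=intact_two_parent" in keys
    # subgroup means average to the population mean with observed weights
    nc = res[engine.NC]
    w1 = analytic["parental_psychiatric"].mean()
    combined = (nc.subgroup_means["sub:parental_psychiatric=1"] * w1
                + nc.subgroup_means["sub:parental_psychiatric=0"] * (1 - w1))
    assert combined == pytest.approx(nc.mean_outcome, abs=1e-12)
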
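"""Closed-form standardization and calibration of the cohort generator.

The generator draws mediators and the outcome from logistic models given a
confounder stratum and an income quintile, with conditional independence of
the mediators.  Because the confounders are discrete (288 strata: 3 parental
flags x 6 family categories x 3 education levels x 2 sexes) and the latent
income is a normal mixture on the log scale, every marginal and every
counterfactual scenario mean has a closed form obtained by enumerating
strata x quintiles x mediator combinations.  This module implements that
enumeration and uses it to solve, by one-dimensional root-finding, for

* mediator intercepts   -> configured marginal prevalences,
* income slopes         -> configured treated-group (ATT) responses to the
                           quintile-1 -> quintile-2 income shift,
* GPA income slope      -> configured mediated share left when the GPA
                           pathway is absorbed into the direct effect,
* outcome intercept     -> configured overall outcome prevalence,
* adversity->income scale -> configured crude outcome prevalence in the
                           lowest income quintile.

The same enumeration doubles as an independent oracle for the Monte-Carlo
g-formula engine in the test-suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from .config import (
    ALL_MEDIATORS,
    BIRTH_YEARS,
    DEFAULT_ATT_TARGETS,
    DEFAULT_GPA_MEDIATED_SHARE,
    DEFAULT_Q1_OUTCOME_PREVALENCE,
    EDUCATION_LEVELS,
    FAMILY_CATEGORIES,
    GPA,
    GPA_UPPER_SPLIT_DAMPING,
    MEDIATORS,
    CalibrationError,
    ConfigError,
    GeneratorConfig,
)

_N_MED = len(MEDIATORS)
#: all 2^7 binary mediator combinations, one row per combination
_COMBOS = ((np.arange(1 << _N_MED)[:, None] >> np.arange(_N_MED)[None, :]) & 1).astype(float)


def _lookup(or_map: Mapping[str, float], term: str) -> float:
    return math.log(or_map.get(term, 1.0))


@dataclass
class Strata:
    """Discrete confounder strata with quintile membership probabilities."""

    prob: np.ndarray              # (S,) stratum probability
    score: np.ndarray             # (S,) adversity score for the income shift
    med_lp: dict                  # mediator -> (S,) confounder log-odds
    gpa_lp: np.ndarray            # (S, 3) split log-odds (lowest, 3rd, 2nd)
    out_lp: np.ndarray            # (S,) outcome confounder log-odds (incl. sex)
    pq: np.ndarray                # (S, 5) P(quintile | stratum), col j = quintile j+1
    cutpoints: np.ndarray         # (4,) log-income quintile cut points


def build_strata(config: GeneratorConfig, scale: Optional[float] = None) -> Strata:
    """Enumerate confounder strata and their income-quintile distribution."""
    if scale is None:
        scale = config.income_adversity_scale
    cp = config.confounder_prevalences
    flags = [(0, 1)] * 3
    cells = list(itertools.product(*flags, FAMILY_CATEGORIES, EDUCATION_LEVELS, (0, 1)))
    S = len(cells)

    prob = np.empty(S)
    score = np.empty(S)
    out_lp = np.empty(S)
    gpa_lp = np.empty((S, 3))
    med_lp = {m: np.empty(S) for m in MEDIATORS}

    weights = config.income_adversity_weights
    oor = config.outcome_model_odds_ratios
    mco = config.mediator_confounder_odds_ratios

    fam_share = config.family_stability_shares
    edu_share = config.parental_education_shares
    p_flags = [cp["parental_psychiatric"], cp["parental_substance"], cp["parental_violent"]]
    flag_terms = ("parental_psychiatric", "parental_substance", "parental_violent")
    p_female = cp["sex_female"]

    for i, (fp, fs, fv, fam, edu, sex) in enumerate(cells):
        f = (fp, fs, fv)
        prob[i] = (
            math.prod(p if on else 1 - p for on, p in zip(f, p_flags))
            * fam_share[fam] * edu_share[edu]
            * (p_female if sex else 1 - p_female)
        )
        terms = [t for on, t in zip(f, flag_terms) if on]
        terms.append(f"family:{fam}")
        terms.append(f"education:{edu}")
        score[i] = sum(weights.get(t, 0.0) for t in terms)
        out_lp[i] = sum(_lookup(oor, t) for t in terms) + (sex * _lookup(oor, "sex_female"))
        for m in MEDIATORS:
            med_lp[m][i] = sum(_lookup(mco[m], t) for t in terms)
        g = sum(_lookup(mco[GPA], t) for t in terms)
        gpa_lp[i] = (g, GPA_UPPER_SPLIT_DAMPING * g, GPA_UPPER_SPLIT_DAMPING * g)

    # latent per-child mean log income ~ N(mu - scale*score, sd_tot^2)
    sd_tot = math.sqrt(config.income_log_sd ** 2
                       + config.annual_income_log_sd ** 2 / 5.0)
    mu = config.income_log_mean - scale * score

    def mix_cdf(x):
        return float(prob @ norm.cdf((x - mu) / sd_tot))

    lo, hi = mu.min() - 8 * sd_tot, mu.max() + 8 * sd_tot
    cut = np.array([brentq(lambda x, f=k: mix_cdf(x) - f / 5.0, lo, hi, xtol=1e-10)
                    for k in (1, 2, 3, 4)])
    edges = np.concatenate(([-np.inf], cut, [np.inf]))
    cdf = norm.cdf((edges[None, :] - mu[:, None]) / sd_tot)
    pq = np.diff(cdf, axis=1)
    return Strata(prob=prob, score=score, med_lp=med_lp, gpa_lp=gpa_lp,
                  out_lp=out_lp, pq=pq, cutpoints=cut)


# --------------------------------------------------------------------------
# mediator marginals and treated-group responses
# --------------------------------------------------------------------------

def _grad_term(gradient: float, quintile) -> float:
    """Linear-in-quintile slope: quintile 5 (highest) is the reference."""
    return gradient * (5.0 - np.asarray(quintile, dtype=float))


def mediator_marginal(strata: Strata, lp_conf: np.ndarray, intercept: float,
                      gradient: float) -> float:
    q = np.arange(1, 6, dtype=float)
    p = expit(intercept + lp_conf[:, None] + _grad_term(gradient, q)[None, :])
    return float((strata.prob[:, None] * strata.pq * p).sum())


def solve_mediator_intercept(strata: Strata, lp_conf: np.ndarray, gradient: float,
                             target: float) -> float:
    return brentq(lambda a: mediator_marginal(strata, lp_conf, a, gradient) - target,
                  -25.0, 10.0, xtol=1e-10)


def att_reduction(strata: Strata, lp_conf: np.ndarray, intercept: float,
                  gradient: float) -> float:
    """Relative fall in a mediator's quintile-1 prevalence under the q1->q2 shift."""
    w = strata.prob * strata.pq[:, 0]
    p1 = expit(intercept + lp_conf + 4.0 * gradient)
    p2 = expit(intercept + lp_conf + 3.0 * gradient)
    return float(1.0 - (w @ p2) / (w @ p1))


def solve_income_gradient(strata: Strata, lp_conf: np.ndarray, prevalence: float,
                          target: float, hi: float = 3.0) -> tuple[float, float]:
    """Return (gradient, intercept) hitting an ATT reduction target."""
    if not 0.0 <= target < 1.0:
        raise ConfigError(f"ATT target {target!r} must lie in [0, 1)")
    if target == 0.0:
        return 0.0, solve_mediator_intercept(strata, lp_conf, 0.0, prevalence)

    def f(g):
        a = solve_mediator_intercept(strata, lp_conf, g, prevalence)
        return att_reduction(strata, lp_conf, a, g) - target

    f_hi = f(hi)
    if f_hi < 0:
        raise CalibrationError(
            f"ATT target {target:.3f} unattainable: slope {hi} achieves only "
            f"{f_hi + target:.3f}")
    g = brentq(f, 0.0, hi, xtol=1e-6)
    return g, solve_mediator_intercept(strata, lp_conf, g, prevalence)


# --------------------------------------------------------------------------
# GPA sequential splits
# --------------------------------------------------------------------------

def gpa_category_probs(strata: Strata, intercepts: Sequence[float], gradient: float,
                       quintile: np.ndarray) -> np.ndarray:
    """(S, 4) probabilities of the underlying quartile category, highest first.

    The income slope acts on the lowest-quartile split only; the conditional
    splits within the upper three quartiles carry confounder effects alone.
    """
    a1, a2, a3 = intercepts
    p_low = expit(a1 + strata.gpa_lp[:, 0] + _grad_term(gradient, quintile))
    p3 = expit(a2 + strata.gpa_lp[:, 1])
    p2 = expit(a3 + strata.gpa_lp[:, 2])
    cat4 = p_low
    cat3 = (1 - p_low) * p3
    cat2 = (1 - p_low) * (1 - p3) * p2
    cat1 = (1 - p_low) * (1 - p3) * (1 - p2)
    return np.stack([cat1, cat2, cat3, cat4], axis=1)


def built_gpa_probs(config: GeneratorConfig, cat_probs: np.ndarray) -> np.ndarray:
    """Fold the missing-GPA fraction into the lowest quartile."""
    miss = config.gpa_missing_rate
    out = (1 - miss) * cat_probs
    out[..., 3] += miss
    return out


def solve_gpa_intercepts(config: GeneratorConfig, strata: Strata,
                         gradient: float) -> tuple[float, float, float]:
    """Sequential-split intercepts hitting the configured quartile shares."""
    miss = config.gpa_missing_rate
    shares = config.gpa_quartile_shares
    t_low = (shares[3] - miss) / (1 - miss)
    t_3 = shares[2] / (1 - miss)
    t_2 = shares[1] / (1 - miss)
    if t_low <= 0:
        raise ConfigError("lowest GPA share must exceed the missing rate")
    w = strata.prob[:, None] * strata.pq
    q = np.arange(1, 6, dtype=float)

    def marg_low(a1):
        p = expit(a1 + strata.gpa_lp[:, 0][:, None] + _grad_term(gradient, q)[None, :])
        return float((w * p).sum())

    a1 = brentq(lambda a: marg_low(a) - t_low, -25.0, 10.0, xtol=1e-10)
    p_low = expit(a1 + strata.gpa_lp[:, 0][:, None] + _grad_term(gradient, q)[None, :])
    w_rest = (w * (1 - p_low)).sum(axis=1)          # (S,) weight of "not lowest"

    def marg_3(a2):
        return float(w_rest @ expit(a2 + strata.gpa_lp[:, 1]))

    a2 = brentq(lambda a: marg_3(a) - t_3, -25.0, 10.0, xtol=1e-10)
    w_rest2 = w_rest * (1 - expit(a2 + strata.gpa_lp[:, 1]))

    def marg_2(a3):
        return float(w_rest2 @ expit(a3 + strata.gpa_lp[:, 2]))

    a3 = brentq(lambda a: marg_2(a) - t_2, -25.0, 10.0, xtol=1e-10)
    return (a1, a2, a3)


# --------------------------------------------------------------------------
# outcome standardization
# --------------------------------------------------------------------------

@dataclass
class ResolvedParams:
    """Numeric generator parameters after intercept calibration."""

    mediator_intercepts: dict
    gpa_split_intercepts: tuple
    outcome_intercept: float


def _outcome_cells(config: GeneratorConfig, strata: Strata, params: ResolvedParams,
                   q_outcome: np.ndarray, q_med: Mapping[str, np.ndarray],
                   subset: Optional[np.ndarray] = None) -> np.ndarray:
    """E[Y | stratum] for one quintile column under per-mediator exposure.

    ``q_outcome`` (S,) is the quintile used in the outcome model,
    ``q_med[m]`` the quintile each mediator responds to; mediators are
    integrated out by enumerating all 2^7 x 4 combinations.
    """
    oor = config.outcome_model_odds_ratios
    beta_med = np.array([_lookup(oor, m) for m in MEDIATORS])
    beta_gpa = np.array([0.0] + [_lookup(oor, f"gpa:{k}") for k in (2, 3, 4)])
    beta_q = np.array([_lookup(oor, f"income_q{k}") for k in (1, 2, 3, 4)] + [0.0])

    med_p = np.stack([
        expit(params.mediator_intercepts[m] + strata.med_lp[m]
              + _grad_term(config.income_gradients.get(m, 0.0), q_med[m]))
        for m in MEDIATORS], axis=1)                               # (S, 7)
    gpa_p = built_gpa_probs(config, gpa_category_probs(
        strata, params.gpa_split_intercepts,
        config.income_gradients.get(GPA, 0.0), q_med[GPA]))        # (S, 4)
    lp0 = (params.outcome_intercept + strata.out_lp
           + beta_q[(np.asarray(q_outcome) - 1).astype(int)])      # (S,)

    if subset is not None:
        med_p, gpa_p, lp0 = med_p[subset], gpa_p[subset], lp0[subset]

    logit_m = np.log(med_p) - np.log1p(-med_p)
    log_none = np.log1p(-med_p).sum(axis=1)
    w = np.exp(_COMBOS @ logit_m.T + log_none[None, :])            # (128, S)
    off = _COMBOS @ beta_med                                       # (128,)
    lp = lp0[None, :, None] + off[:, None, None] + beta_gpa[None, None, :]
    ey = np.einsum("js,sg,jsg->s", w, gpa_p, expit(lp))
    return ey


def scenario_outcome_means(config: GeneratorConfig, strata: Strata,
                           params: ResolvedParams, intervene_exposure: bool = False,
                           responding: Iterable[str] = ()) -> tuple[float, float]:
    """(overall, quintile-1) outcome means for one g-formula scenario.

    The intervention moves quintile-1 children to quintile 2; ``responding``
    lists the mediators that see the intervened income, all others stay at
    their natural-course distribution.
    """
    responding = set(responding)
    S = strata.prob.shape[0]
    total = 0.0
    q1_mean = 0.0
    for q in (1, 2, 3, 4, 5):
        qcol = np.full(S, float(q))
        if q == 1:
            q_out = np.full(S, 2.0) if intervene_exposure else qcol
            q_med = {m: (np.full(S, 2.0) if m in responding else qcol)
                     for m in ALL_MEDIATORS}
        else:
            q_out = qcol
            q_med = {m: qcol for m in ALL_MEDIATORS}
        ey = _outcome_cells(config, strata, params, q_out, q_med)
        w = strata.prob * strata.pq[:, q - 1]
        total += float(w @ ey)
        if q == 1:
            q1_mean = float(w @ ey) / float(w.sum())
    return total, q1_mean


def mediated_share(config: GeneratorConfig, strata: Strata, params: ResolvedParams,
                   absorbed: Optional[str] = None) -> float:
    """NIE/TE when ``absorbed`` (or none) is folded into the direct effect."""
    nc, _ = scenario_outcome_means(config, strata, params)
    cf, _ = scenario_outcome_means(config, strata, params, True, ALL_MEDIATORS)
    resp = () if absorbed is None else (absorbed,)
    s, _ = scenario_outcome_means(config, strata, params, True, resp)
    te = cf - nc
    if te == 0.0:
        raise CalibrationError("total effect is zero; mediated share undefined")
    return (cf - s) / te


def solve_outcome_intercept(config: GeneratorConfig, strata: Strata,
                            params: ResolvedParams) -> float:
    def f(b0):
        p = ResolvedParams(params.mediator_intercepts, params.gpa_split_intercepts, b0)
        total, _ = scenario_outcome_means(config, strata, p)
        return total - config.outcome_base_rate

    return brentq(f, -25.0, 5.0, xtol=1e-9)


# --------------------------------------------------------------------------
# top-level calibration operations
# --------------------------------------------------------------------------

def resolve(config: GeneratorConfig, strata: Optional[Strata] = None) -> ResolvedParams:
    """Calibrate every intercept for the config's current slopes and scale."""
    config.validate()
    if strata is None:
        strata = build_strata(config)
    med_int = {
        m: solve_mediator_intercept(strata, strata.med_lp[m],
                                    config.income_gradients.get(m, 0.0),
                                    config.mediator_base_prevalences[m])
        for m in MEDIATORS}
    gpa_int = solve_gpa_intercepts(config, strata, config.income_gradients.get(GPA, 0.0))
    params = ResolvedParams(med_int, gpa_int, 0.0)
    params.outcome_intercept = solve_outcome_intercept(config, strata, params)
    return params


def attach(config: GeneratorConfig, params: ResolvedParams) -> GeneratorConfig:
    return config.replace(mediator_intercepts=dict(params.mediator_intercepts),
                          gpa_split_intercepts=tuple(params.gpa_split_intercepts),
                          outcome_intercept=params.outcome_intercept)


def detach(config: GeneratorConfig) -> ResolvedParams:
    if not config.is_resolved():
        raise ConfigError("config has unresolved intercepts")
    return ResolvedParams(dict(config.mediator_intercepts),
                          tuple(config.gpa_split_intercepts),
                          float(config.outcome_intercept))


def calibrate_income_gradients(config: GeneratorConfig,
                               att_targets: Mapping[str, float],
                               strata: Optional[Strata] = None) -> GeneratorConfig:
    """Tune per-quintile income slopes to treated-group mediator responses.

    Each target is the relative reduction in the mediator's prevalence among
    quintile-1 children when they are moved to quintile 2, evaluated by
    closed-form standardization over the confounder strata.
    """
    config.validate()
    if strata is None:
        strata = build_strata(config)
    grads = dict(config.income_gradients)
    for m, target in att_targets.items():
        if m not in MEDIATORS:
            raise ConfigError(f"unknown mediator {m!r} in ATT targets")
        g, _ = solve_income_gradient(strata, strata.med_lp[m],
                                     config.mediator_base_prevalences[m], target)
        grads[m] = g
    return config.replace(income_gradients=grads,
                          mediator_intercepts=None, outcome_intercept=None,
                          gpa_split_intercepts=None)


def calibrate_gpa_gradient(config: GeneratorConfig,
                           mediated_share_target: float = DEFAULT_GPA_MEDIATED_SHARE,
                           strata: Optional[Strata] = None,
                           hi: float = 2.0) -> GeneratorConfig:
    """Tune the GPA income slope so that absorbing the GPA pathway into the
    direct effect leaves the requested mediated share."""
    config.validate()
    if strata is None:
        strata = build_strata(config)

    def f(g):
        cfg = config.replace(income_gradients={**config.income_gradients, GPA: g})
        params = resolve(cfg, strata)
        return mediated_share(cfg, strata, params, absorbed=GPA) - mediated_share_target

    f0 = f(0.0)
    if f0 < 0:
        raise CalibrationError(
            f"mediated-share target {mediated_share_target:.2f} already exceeded "
            f"with a null GPA slope ({f0 + mediated_share_target:.3f})")
    fh = f(hi)
    if fh > 0:
        raise CalibrationError(
            f"mediated-share target {mediated_share_target:.2f} unattainable: "
            f"slope {hi} leaves {fh + mediated_share_target:.3f}")
    g = brentq(f, 0.0, hi, xtol=2e-3)
    return config.replace(income_gradients={**config.income_gradients, GPA: g},
                          mediator_intercepts=None, outcome_intercept=None,
                          gpa_split_intercepts=None)


def calibrate_cohort_config(
        config: Optional[GeneratorConfig] = None,
        att_targets: Mapping[str, float] = DEFAULT_ATT_TARGETS,
        gpa_mediated_share: float = DEFAULT_GPA_MEDIATED_SHARE,
        q1_outcome_prevalence: Optional[float] = DEFAULT_Q1_OUTCOME_PREVALENCE,
        scale_bracket: tuple[float, float] = (0.05, 1.2),
) -> GeneratorConfig:
    """Full calibration chain; returns a config with resolved intercepts.

    The outer loop tunes the adversity->income scale to the crude outcome
    prevalence in the lowest quintile; the mediator slopes, GPA slope and all
    intercepts are re-solved at every trial scale because quintile membership
    probabilities move with it.  Pass ``q1_outcome_prevalence=None`` to skip
    the outer loop and calibrate at the config's own scale.
    """
    if config is None:
        config = GeneratorConfig()
    config.validate()

    def inner(scale: float) -> tuple[GeneratorConfig, ResolvedParams, Strata]:
        cfg = config.replace(income_adversity_scale=scale)
        strata = build_strata(cfg)
        cfg = calibrate_income_gradients(cfg, att_targets, strata)
        cfg = calibrate_gpa_gradient(cfg, gpa_mediated_share, strata)
        params = resolve(cfg, strata)
        return cfg, params, strata

    if q1_outcome_prevalence is None:
        cfg, params, _ = inner(config.income_adversity_scale)
        return attach(cfg, params)

    def f(scale: float) -> float:
        cfg, params, strata = inner(scale)
        _, q1 = scenario_outcome_means(cfg, strata, params)
        return q1 - q1_outcome_prevalence

    lo, hi = scale_bracket
    f_lo, f_hi = f(lo), f(hi)
    if f_lo * f_hi > 0:
        raise CalibrationError(
            f"lowest-quintile prevalence target {q1_outcome_prevalence:.4f} not "
            f"bracketed by scales {scale_bracket}: achieved "
            f"[{f_lo + q1_outcome_prevalence:.4f}, {f_hi + q1_outcome_prevalence:.4f}]")
    scale = brentq(f, lo, hi, xtol=1e-3)
    cfg, params, _ = inner(scale)
    return attach(cfg, params)


# --------------------------------------------------------------------------
# generator-truth coefficients (for parameter-recovery testing and audits)
# --------------------------------------------------------------------------

def true_coefficients(config: GeneratorConfig) -> dict:
    """Per-model term -> log-odds maps implied by the generator.

    Covers the seven binary mediator models and the outcome model (the
    rebuilt GPA variable is a missingness mixture, so its sequential splits
    have no exact logistic form).  Terms follow the fitted models' naming.
    """
    params = detach(config)
    out: dict = {}
    for m in MEDIATORS:
        terms = {"const": params.mediator_intercepts[m]}
        _fill_confounder_terms(terms, config.mediator_confounder_odds_ratios[m])
        g = config.income_gradients.get(m, 0.0)
        for q in (1, 2, 3, 4):
            terms[f"income_q{q}"] = g * (5 - q)
        out[m] = terms
    terms = {"const": params.outcome_intercept}
    oor = config.outcome_model_odds_ratios
    _fill_confounder_terms(terms, oor)
    terms["sex_female"] = _lookup(oor, "sex_female")
    for q in (1, 2, 3, 4):
        terms[f"income_q{q}"] = _lookup(oor, f"income_q{q}")
    for m in MEDIATORS:
        terms[m] = _lookup(oor, m)
    for k in (2, 3, 4):
        terms[f"gpa:{k}"] = _lookup(oor, f"gpa:{k}")
    out["outcome"] = terms
    return out


def _fill_confounder_terms(terms: dict, or_map: Mapping[str, float]) -> None:
    for t in ("parental_psychiatric", "parental_substance", "parental_violent"):
        terms[t] = _lookup(or_map, t)
    for c in FAMILY_CATEGORIES[1:]:
        terms[f"family:{c}"] = _lookup(or_map, f"family:{c}")
    for lvl in EDUCATION_LEVELS[1:]:
        terms[f"education:{lvl}"] = _lookup(or_map, f"education:{lvl}")
    for y in BIRTH_YEARS[1:]:
        terms[f"birth_year:{y}"] = 0.0
    terms.setdefault("sex_female", 0.0)
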
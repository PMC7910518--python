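"""Logistic model layer for the g-formula.

One maximum-likelihood logistic regression per binary mediator (confounders,
sex, birth year, income quintile), a sequential series of three logistic
models for the four-level GPA quartile (lowest vs rest, then 3rd, then 2nd),
and the outcome model which additionally includes every mediator.  Reference
categories: highest income quintile, highest GPA quartile, intact two-parent
family, tertiary parental education, male, first birth cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import (
    BIRTH_YEARS,
    EDUCATION_LEVELS,
    FAMILY_CATEGORIES,
    GPA,
    MEDIATORS,
    OUTCOME,
    PARENTAL_FLAGS,
)

CONF_TERMS = (
    PARENTAL_FLAGS
    + tuple(f"family:{c}" for c in FAMILY_CATEGORIES[1:])
    + tuple(f"education:{lvl}" for lvl in EDUCATION_LEVELS[1:])
    + ("sex_female",)
    + tuple(f"birth_year:{y}" for y in BIRTH_YEARS[1:])
)
INCOME_TERMS = ("income_q1", "income_q2", "income_q3", "income_q4")
MEDIATOR_TERMS = MEDIATORS + ("gpa:2", "gpa:3", "gpa:4")

GPA_MODELS = ("gpa_lowest", "gpa_3rd", "gpa_2nd")

#: divergent coefficients on the logit scale signal (quasi-)separation
_SEPARATION_LIMIT = 15.0


class ModelFitError(RuntimeError):
    def __init__(self, model: str, reason: str):
        super().__init__(f"model {model!r}: {reason}")
        self.model = model
        self.reason = reason


@dataclass
class FittedLogit:
    terms: tuple
    coef: np.ndarray

    def to_dict(self) -> dict:
        return {"terms": list(self.terms), "coef": [float(c) for c in self.coef]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "FittedLogit":
        return cls(tuple(d["terms"]), np.asarray(d["coef"], dtype=float))


@dataclass
class ModelBundle:
    """Fitted coefficient sets for all mediator models and the outcome model."""

    models: dict     # name -> FittedLogit

    @property
    def term_dictionary(self) -> dict:
        return {name: fit.terms for name, fit in self.models.items()}

    def to_json(self) -> str:
        return json.dumps({k: v.to_dict() for k, v in self.models.items()}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelBundle":
        return cls({k: FittedLogit.from_dict(v) for k, v in json.loads(text).items()})


# --------------------------------------------------------------------------
# design matrices
# --------------------------------------------------------------------------

def confounder_matrix(records: pd.DataFrame) -> np.ndarray:
    """(n, len(CONF_TERMS)) dummy matrix; category levels are validated."""
    n = len(records)
    X = np.zeros((n, len(CONF_TERMS)))
    col = 0
    for t in PARENTAL_FLAGS:
        X[:, col] = records[t].to_numpy(dtype=float)
        col += 1
    fam = records["family_stability"]
    bad = ~fam.isin(FAMILY_CATEGORIES)
    if bad.any():
        raise ValueError(f"unknown family_stability level {fam[bad].iloc[0]!r}")
    for c in FAMILY_CATEGORIES[1:]:
        X[:, col] = (fam == c).to_numpy(dtype=float)
        col += 1
    edu = records["parental_education"]
    bad = ~edu.isin(EDUCATION_LEVELS)
    if bad.any():
        raise ValueError(f"unknown parental_education level {edu[bad].iloc[0]!r}")
    for lvl in EDUCATION_LEVELS[1:]:
        X[:, col] = (edu == lvl).to_numpy(dtype=float)
        col += 1
    X[:, col] = records["sex_female"].to_numpy(dtype=float)
    col += 1
    year = records["birth_year"]
    bad = ~year.isin(BIRTH_YEARS)
    if bad.any():
        raise ValueError(f"unknown birth_year level {year[bad].iloc[0]!r}")
    for y in BIRTH_YEARS[1:]:
        X[:, col] = (year == y).to_numpy(dtype=float)
        col += 1
    return X


def income_matrix(quintile: np.ndarray) -> np.ndarray:
    quintile = np.asarray(quintile)
    if not np.isin(quintile, [1, 2, 3, 4, 5]).all():
        raise ValueError("income quintiles must lie in 1..5")
    X = np.zeros((len(quintile), 4))
    for j, q in enumerate((1, 2, 3, 4)):
        X[:, j] = quintile == q
    return X


def mediator_matrix(values: Mapping[str, np.ndarray]) -> np.ndarray:
    n = len(np.asarray(values[MEDIATORS[0]]))
    X = np.zeros((n, len(MEDIATOR_TERMS)))
    for j, m in enumerate(MEDIATORS):
        X[:, j] = np.asarray(values[m], dtype=float)
    gpa = np.asarray(values[GPA])
    if not np.isin(gpa, [1, 2, 3, 4]).all():
        raise ValueError("gpa quartiles must lie in 1..4")
    for j, k in enumerate((2, 3, 4)):
        X[:, len(MEDIATORS) + j] = gpa == k
    return X


def _fit_logit(X: np.ndarray, y: np.ndarray, terms: tuple, name: str,
               tol: float = 1e-8, max_iter: int = 60,
               start: Optional[np.ndarray] = None) -> FittedLogit:
    """Maximum-likelihood logistic fit by Newton-Raphson with step halving.

    Converges on the score (gradient of the log-likelihood, absolute
    tolerance ``tol``); agrees with statsmodels' IRLS to machine precision
    but avoids its per-iteration SVD, which dominates runtime at registry
    sample sizes.
    """
    y = np.asarray(y, dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ModelFitError(name, "response stratum is empty (all 0 or all 1)")
    if start is not None and len(start) == X.shape[1]:
        beta = np.asarray(start, dtype=float).copy()
    else:
        beta = np.zeros(X.shape[1])
        beta[0] = float(np.log(y.mean() / (1 - y.mean())))   # intercept-only start
    loglik = -np.inf
    for _ in range(max_iter):
        p = expit(X @ beta)
        score = X.T @ (y - p)
        w = p * (1 - p)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, score)
        except np.linalg.LinAlgError:
            raise ModelFitError(name, "singular information matrix") from None
        new = beta + step
        for _ in range(20):                      # step halving on deviance increase
            eta = X @ new
            ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
            if ll >= loglik - 1e-10 or not np.isfinite(loglik):
                break
            step = step / 2.0
            new = beta + step
        beta, loglik = new, ll
        if np.abs(beta).max() > 40.0:        # runaway long before convergence
            raise ModelFitError(name, "divergent coefficients (perfect separation?)")
        if np.abs(score).max() < tol and np.abs(step).max() < 1e-10:
            if np.abs(beta).max() > _SEPARATION_LIMIT:
                raise ModelFitError(name,
                                    "divergent coefficients (perfect separation?)")
            return FittedLogit(terms, beta)
    raise ModelFitError(name, f"no convergence in {max_iter} Newton iterations")


def fit_bundle(records: pd.DataFrame,
               warm_start: Optional[ModelBundle] = None) -> ModelBundle:
    """Fit all mediator models, the GPA series and the outcome model.

    ``warm_start`` supplies Newton starting values from a previous fit on a
    comparable cohort; the converged maximum-likelihood solution does not
    depend on it.
    """
    Xc = confounder_matrix(records)
    Xq = income_matrix(records["income_quintile"].to_numpy())
    ones = np.ones((len(records), 1))
    X_med = np.hstack([ones, Xc, Xq])
    terms_med = ("const",) + CONF_TERMS + INCOME_TERMS

    def start_for(name):
        if warm_start is not None and name in warm_start.models:
            return warm_start.models[name].coef
        return None

    models = {}
    for m in MEDIATORS:
        models[m] = _fit_logit(X_med, records[m].to_numpy(), terms_med, m,
                               start=start_for(m))

    gpa = records["gpa_quartile"].to_numpy()
    models["gpa_lowest"] = _fit_logit(X_med, gpa == 4, terms_med, "gpa_lowest",
                                      start=start_for("gpa_lowest"))
    rest = gpa < 4
    models["gpa_3rd"] = _fit_logit(X_med[rest], gpa[rest] == 3, terms_med, "gpa_3rd",
                                   start=start_for("gpa_3rd"))
    rest2 = gpa < 3
    models["gpa_2nd"] = _fit_logit(X_med[rest2], gpa[rest2] == 2, terms_med, "gpa_2nd",
                                   start=start_for("gpa_2nd"))

    Xm = mediator_matrix({**{m: records[m].to_numpy() for m in MEDIATORS},
                          GPA: gpa})
    X_out = np.hstack([ones, Xc, Xq, Xm])
    models["outcome"] = _fit_logit(
        X_out, records[OUTCOME].to_numpy(),
        ("const",) + CONF_TERMS + INCOME_TERMS + MEDIATOR_TERMS, "outcome",
        start=start_for("outcome"))
    return ModelBundle(models)


# --------------------------------------------------------------------------
# prediction
# --------------------------------------------------------------------------

def _split_coef(fit: FittedLogit) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """(const, conf, income, mediator) coefficient blocks by term name."""
    idx = {t: i for i, t in enumerate(fit.terms)}
    const = fit.coef[idx["const"]]
    conf = np.array([fit.coef[idx[t]] for t in CONF_TERMS])
    income = np.array([fit.coef[idx[t]] for t in INCOME_TERMS])
    med = (np.array([fit.coef[idx[t]] for t in MEDIATOR_TERMS])
           if MEDIATOR_TERMS[0] in idx else np.zeros(0))
    return const, conf, income, med


class BundlePredictor:
    """Caches confounder linear predictors for fast repeated scenario work."""

    def __init__(self, bundle: ModelBundle, records: pd.DataFrame):
        self.bundle = bundle
        self.n = len(records)
        Xc = confounder_matrix(records)
        self.base = {}
        self.beta_q = {}
        for name, fit in bundle.models.items():
            const, conf, income, med = _split_coef(fit)
            self.base[name] = const + Xc @ conf
            self.beta_q[name] = np.append(income, 0.0)   # index by quintile-1
        out = bundle.models["outcome"]
        idx = {t: i for i, t in enumerate(out.terms)}
        self.beta_med = np.array([out.coef[idx[m]] for m in MEDIATORS])
        self.beta_gpa = np.array([0.0] + [out.coef[idx[f"gpa:{k}"]] for k in (2, 3, 4)])

    @staticmethod
    def _check_quintile(quintile: np.ndarray) -> np.ndarray:
        q = np.asarray(quintile, dtype=int)
        if q.size and (q.min() < 1 or q.max() > 5):
            raise ValueError("income quintiles must lie in 1..5")
        return q

    def mediator_p(self, m: str, quintile: np.ndarray) -> np.ndarray:
        q = self._check_quintile(quintile)
        return expit(self.base[m] + self.beta_q[m][q - 1])

    def gpa_probs(self, quintile: np.ndarray) -> np.ndarray:
        """(n, 4) quartile probabilities, highest first; rows sum to one."""
        q = self._check_quintile(quintile)
        p_low = expit(self.base["gpa_lowest"] + self.beta_q["gpa_lowest"][q - 1])
        p3 = expit(self.base["gpa_3rd"] + self.beta_q["gpa_3rd"][q - 1])
        p2 = expit(self.base["gpa_2nd"] + self.beta_q["gpa_2nd"][q - 1])
        rest = 1.0 - p_low
        cat3 = rest * p3
        cat2 = rest * (1 - p3) * p2
        cat1 = rest * (1 - p3) * (1 - p2)
        return np.stack([cat1, cat2, cat3, p_low], axis=1)

    def outcome_lp_base(self, quintile: np.ndarray) -> np.ndarray:
        q = self._check_quintile(quintile)
        return self.base["outcome"] + self.beta_q["outcome"][q - 1]

    def outcome_p(self, lp_base: np.ndarray, med_values: Mapping[str, np.ndarray],
                  gpa_quartile: np.ndarray) -> np.ndarray:
        lp = lp_base + self.beta_gpa[np.asarray(gpa_quartile, dtype=int) - 1]
        for j, m in enumerate(MEDIATORS):
            lp = lp + self.beta_med[j] * np.asarray(med_values[m], dtype=float)
        return expit(lp)


def predict_mediator(bundle: ModelBundle, records: pd.DataFrame, mediator: str,
                     exposure_override: Optional[int] = None) -> np.ndarray:
    """Per-record mediator probabilities; (n, 4) category probabilities for GPA.

    ``exposure_override`` replaces every record's income quintile (used by
    intervention scenarios); otherwise the observed quintile is used.
    """
    pred = BundlePredictor(bundle, records)
    q = (np.full(len(records), exposure_override)
         if exposure_override is not None
         else records["income_quintile"].to_numpy())
    if mediator == GPA:
        return pred.gpa_probs(q)
    if mediator not in MEDIATORS:
        raise ValueError(f"unknown mediator {mediator!r}")
    return pred.mediator_p(mediator, q)


def predict_outcome(bundle: ModelBundle, records: pd.DataFrame,
                    exposure_override: Optional[int] = None,
                    mediator_values: Optional[Mapping[str, np.ndarray]] = None
                    ) -> np.ndarray:
    """Per-record outcome probabilities given mediator values.

    Mediator values default to the observed columns; pass simulated values to
    evaluate counterfactual scenarios.
    """
    pred = BundlePredictor(bundle, records)
    q = (np.full(len(records), exposure_override)
         if exposure_override is not None
         else records["income_quintile"].to_numpy())
    if mediator_values is None:
        mediator_values = {m: records[m].to_numpy() for m in MEDIATORS}
        gpa = records["gpa_quartile"].to_numpy()
    else:
        gpa = np.asarray(mediator_values[GPA])
    return pred.outcome_p(pred.outcome_lp_base(q), mediator_values, gpa)
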
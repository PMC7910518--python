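"""Cohort vocabulary and generator configuration.

The synthetic registry emulates a Finnish birth-cohort register extract:
children born 1990-1995, childhood (age 8-12) family income and confounders,
adolescent (age 13-17) mediators, and hospital-presenting self-harm in young
adulthood (age 18-22).  Default parameter values reproduce the marginal
category shares, mediator prevalences and adjusted outcome odds ratios
observed for that population; quantities that no register publication pins
down (mediator-confounder associations, the income distribution itself) carry
realism defaults documented in docs/methods.md.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import yaml

# --------------------------------------------------------------------------
# Vocabulary
# --------------------------------------------------------------------------

#: Binary adolescent mediators ("ever during ages 13-17" indicators).
MEDIATORS = (
    "adolescent_self_harm",
    "psychiatric_disorder",
    "substance_abuse",
    "violent_victimization",
    "violent_crime",
    "out_of_home_placement",
    "neet",
)

#: The categorical school-performance mediator (GPA quartile, 1 = highest).
GPA = "gpa"

ALL_MEDIATORS = MEDIATORS + (GPA,)

PARENTAL_FLAGS = ("parental_psychiatric", "parental_substance", "parental_violent")

FAMILY_CATEGORIES = (
    "intact_two_parent",
    "intact_single_parent",
    "multiple_changes",
    "ever_without_family",
    "disrupted_two_parent",
    "repartnered_single_parent",
)

EDUCATION_LEVELS = ("tertiary", "secondary", "basic")

#: Annual household states used to build the family-stability classifier input.
FAMILY_STATES = ("two_parent", "single_parent", "no_parents")

BIRTH_YEARS = (1990, 1991, 1992, 1993, 1994, 1995)

#: Sequential exclusion rules, in the order children are attributed to them.
EXCLUSION_RULES = (
    "absent_census_8_17",
    "absent_young_adulthood",
    "unlinkable_parents",
    "income_all_missing",
)

CHILDHOOD_AGES = (8, 9, 10, 11, 12)
ADOLESCENT_AGES = (13, 14, 15, 16, 17)

INCOME_COLUMNS = tuple(f"income_age_{a}" for a in CHILDHOOD_AGES)
FAMILY_STATE_COLUMNS = tuple(f"family_state_age_{a}" for a in CHILDHOOD_AGES)
EXCLUSION_COLUMNS = tuple(f"excl_{r}" for r in EXCLUSION_RULES)

OUTCOME = "y_self_harm"

# Composite term keys used in odds-ratio maps (reference categories:
# highest income quintile, highest GPA quartile, intact two-parent family,
# tertiary education, male).
FAMILY_TERMS = tuple(f"family:{c}" for c in FAMILY_CATEGORIES[1:])
EDUCATION_TERMS = tuple(f"education:{lvl}" for lvl in EDUCATION_LEVELS[1:])
INCOME_TERMS = ("income_q1", "income_q2", "income_q3", "income_q4")
GPA_TERMS = ("gpa:2", "gpa:3", "gpa:4")

#: Attenuation applied to GPA confounder log-odds in the conditional splits
#: above the lowest quartile (adversity mostly separates the bottom of the
#: grade distribution from the rest).
GPA_UPPER_SPLIT_DAMPING = 0.5

#: Uniform score bands used to emit a numeric GPA (4.0-10.0 scale) for each
#: generated quartile category, highest quartile first.
GPA_BANDS = ((9.0, 10.0), (8.0, 9.0), (7.0, 8.0), (4.0, 7.0))


class ConfigError(ValueError):
    """Raised when a generator configuration fails validation."""


class CalibrationError(RuntimeError):
    """Raised when a calibration target cannot be bracketed or attained."""


# --------------------------------------------------------------------------
# Defaults (registry-calibrated study conditions)
# --------------------------------------------------------------------------

DEFAULT_CONFOUNDER_PREVALENCES: Mapping[str, float] = {
    "parental_psychiatric": 0.082,
    "parental_substance": 0.060,
    "parental_violent": 0.044,
    "sex_female": 0.49,
}

DEFAULT_FAMILY_STABILITY_SHARES: Mapping[str, float] = {
    "intact_two_parent": 0.735,
    "intact_single_parent": 0.109,
    "multiple_changes": 0.030,
    "ever_without_family": 0.011,
    "disrupted_two_parent": 0.073,
    "repartnered_single_parent": 0.042,
}

DEFAULT_EDUCATION_SHARES: Mapping[str, float] = {
    "tertiary": 0.532,
    "secondary": 0.410,
    "basic": 0.058,
}

DEFAULT_BIRTH_YEAR_SHARES: Mapping[int, float] = {y: 1.0 / 6.0 for y in BIRTH_YEARS}

DEFAULT_MEDIATOR_PREVALENCES: Mapping[str, float] = {
    "adolescent_self_harm": 1034 / 384121,
    "psychiatric_disorder": 33609 / 384121,
    "substance_abuse": 5015 / 384121,
    "violent_victimization": 1015 / 384121,
    "violent_crime": 9475 / 384121,
    "out_of_home_placement": 10890 / 384121,
    "neet": 28901 / 384121,
}

#: Rebuilt GPA quartile shares (missing folded into the lowest quartile).
#: Continuous generated grades cut at empirical quartiles give exact quarters
#: of the non-missing 97%, hence 0.2425 / 0.2425 / 0.2425 / 0.2725.
DEFAULT_GPA_SHARES = (0.2425, 0.2425, 0.2425, 0.2725)
DEFAULT_GPA_MISSING_RATE = 0.03

#: Adjusted odds ratios of the young-adult self-harm outcome model.
DEFAULT_OUTCOME_ODDS_RATIOS: Mapping[str, float] = {
    # income quintiles, reference = highest (q5); q1 = lowest
    "income_q1": 1.24,
    "income_q2": 1.21,
    "income_q3": 1.17,
    "income_q4": 1.10,
    # adolescent mediators
    "adolescent_self_harm": 4.64,
    "psychiatric_disorder": 3.41,
    "substance_abuse": 1.74,
    "violent_victimization": 1.29,
    "violent_crime": 1.81,
    "out_of_home_placement": 2.28,
    "neet": 1.36,
    # GPA quartiles, reference = highest (1)
    "gpa:2": 1.39,
    "gpa:3": 1.83,
    "gpa:4": 2.20,
    # childhood confounders
    "parental_psychiatric": 1.26,
    "parental_substance": 1.21,
    "parental_violent": 1.06,
    "family:intact_single_parent": 1.26,
    "family:multiple_changes": 1.38,
    "family:ever_without_family": 1.15,
    "family:disrupted_two_parent": 1.21,
    "family:repartnered_single_parent": 1.20,
    "education:secondary": 1.04,
    "education:basic": 1.04,
    # demographic terms (no published value; realism default)
    "sex_female": 1.50,
}

#: Mediator-model odds ratios for the childhood confounders.  These are not
#: published for the source registry; values are realism defaults (adversity
#: raises every adolescent risk, most strongly out-of-home placement).
DEFAULT_MEDIATOR_CONFOUNDER_ODDS_RATIOS: Mapping[str, Mapping[str, float]] = {
    "adolescent_self_harm": {
        "parental_psychiatric": 2.0, "parental_substance": 1.6, "parental_violent": 1.4,
        "family:intact_single_parent": 1.5, "family:multiple_changes": 1.9,
        "family:ever_without_family": 2.5, "family:disrupted_two_parent": 1.5,
        "family:repartnered_single_parent": 1.6,
        "education:secondary": 1.3, "education:basic": 1.7,
    },
    "psychiatric_disorder": {
        "parental_psychiatric": 2.5, "parental_substance": 1.5, "parental_violent": 1.3,
        "family:intact_single_parent": 1.5, "family:multiple_changes": 1.8,
        "family:ever_without_family": 2.5, "family:disrupted_two_parent": 1.5,
        "family:repartnered_single_parent": 1.5,
        "education:secondary": 1.3, "education:basic": 1.6,
    },
    "substance_abuse": {
        "parental_psychiatric": 1.8, "parental_substance": 2.5, "parental_violent": 1.6,
        "family:intact_single_parent": 1.6, "family:multiple_changes": 2.2,
        "family:ever_without_family": 3.0, "family:disrupted_two_parent": 1.7,
        "family:repartnered_single_parent": 1.8,
        "education:secondary": 1.4, "education:basic": 2.0,
    },
    "violent_victimization": {
        "parental_psychiatric": 1.5, "parental_substance": 1.8, "parental_violent": 2.0,
        "family:intact_single_parent": 1.6, "family:multiple_changes": 2.0,
        "family:ever_without_family": 2.8, "family:disrupted_two_parent": 1.6,
        "family:repartnered_single_parent": 1.7,
        "education:secondary": 1.4, "education:basic": 2.0,
    },
    "violent_crime": {
        "parental_psychiatric": 1.5, "parental_substance": 1.8, "parental_violent": 2.2,
        "family:intact_single_parent": 1.7, "family:multiple_changes": 2.2,
        "family:ever_without_family": 2.8, "family:disrupted_two_parent": 1.7,
        "family:repartnered_single_parent": 1.8,
        "education:secondary": 1.6, "education:basic": 2.4,
    },
    "out_of_home_placement": {
        "parental_psychiatric": 2.2, "parental_substance": 2.5, "parental_violent": 2.0,
        "family:intact_single_parent": 2.0, "family:multiple_changes": 3.5,
        "family:ever_without_family": 6.0, "family:disrupted_two_parent": 2.0,
        "family:repartnered_single_parent": 2.2,
        "education:secondary": 1.8, "education:basic": 3.0,
    },
    "neet": {
        "parental_psychiatric": 1.6, "parental_substance": 1.6, "parental_violent": 1.5,
        "family:intact_single_parent": 1.5, "family:multiple_changes": 1.9,
        "family:ever_without_family": 2.5, "family:disrupted_two_parent": 1.5,
        "family:repartnered_single_parent": 1.6,
        "education:secondary": 1.8, "education:basic": 2.8,
    },
    # applies to the lowest-quartile split; upper splits use damped log-odds
    "gpa": {
        "parental_psychiatric": 1.4, "parental_substance": 1.5, "parental_violent": 1.6,
        "family:intact_single_parent": 1.5, "family:multiple_changes": 1.8,
        "family:ever_without_family": 2.2, "family:disrupted_two_parent": 1.5,
        "family:repartnered_single_parent": 1.6,
        "education:secondary": 2.0, "education:basic": 3.5,
    },
}

#: Additive adversity score feeding the income location shift (consumption-
#: unit equivalised income is lower in single-parent, low-education and
#: adversity-burdened households).
DEFAULT_INCOME_ADVERSITY_WEIGHTS: Mapping[str, float] = {
    "parental_psychiatric": 0.5,
    "parental_substance": 0.6,
    "parental_violent": 0.5,
    "family:intact_single_parent": 1.0,
    "family:multiple_changes": 1.0,
    "family:ever_without_family": 1.2,
    "family:disrupted_two_parent": 0.6,
    "family:repartnered_single_parent": 0.5,
    "education:secondary": 0.5,
    "education:basic": 1.0,
}

#: Relative reductions in mediator prevalence among lowest-quintile children
#: when the intervention moves them to the second-lowest quintile (ATT scale).
DEFAULT_ATT_TARGETS: Mapping[str, float] = {
    "adolescent_self_harm": 0.0,
    "psychiatric_disorder": 0.0,
    "substance_abuse": 0.07,
    "violent_victimization": 0.21,
    "violent_crime": 0.17,
    "out_of_home_placement": 0.21,
    "neet": 0.20,
}

#: Mediated share left when the GPA pathway is absorbed into the direct
#: effect; used to calibrate the GPA income gradient.
DEFAULT_GPA_MEDIATED_SHARE = 0.50

DEFAULT_OUTCOME_PREVALENCE = 0.009
DEFAULT_Q1_OUTCOME_PREVALENCE = 0.014


# --------------------------------------------------------------------------
# GeneratorConfig
# --------------------------------------------------------------------------

def _copy_map(m: Mapping) -> dict:
    return {k: (dict(v) if isinstance(v, Mapping) else v) for k, v in m.items()}


@dataclass(frozen=True)
class GeneratorConfig:
    """All prevalences, odds ratios and gradients that define a cohort.

    Structural fields (shares, odds ratios, gradients) define the data
    generating process; ``*_intercept*`` fields are derived quantities filled
    in by :mod:`gfmed.calibration` so that marginal prevalences hit their
    configured targets.  ``generate_cohort`` resolves them on the fly when
    they are ``None``.
    """

    n_children: int = 200_000
    seed: int = 0

    confounder_prevalences: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONFOUNDER_PREVALENCES))
    family_stability_shares: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_STABILITY_SHARES))
    parental_education_shares: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EDUCATION_SHARES))
    birth_year_shares: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_BIRTH_YEAR_SHARES))

    mediator_base_prevalences: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MEDIATOR_PREVALENCES))
    gpa_quartile_shares: tuple = DEFAULT_GPA_SHARES
    gpa_missing_rate: float = DEFAULT_GPA_MISSING_RATE

    outcome_base_rate: float = DEFAULT_OUTCOME_PREVALENCE
    outcome_model_odds_ratios: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_ODDS_RATIOS))
    mediator_confounder_odds_ratios: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: _copy_map(DEFAULT_MEDIATOR_CONFOUNDER_ODDS_RATIOS))

    #: per-quintile-step log-odds slope; a child in quintile q gets
    #: slope * (5 - q) added to the mediator's linear predictor.
    income_gradients: Mapping[str, float] = field(
        default_factory=lambda: {m: 0.0 for m in ALL_MEDIATORS})

    income_log_mean: float = math.log(25_000.0)
    income_log_sd: float = 0.40
    annual_income_log_sd: float = 0.05
    income_adversity_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INCOME_ADVERSITY_WEIGHTS))
    income_adversity_scale: float = 0.35

    exclusion_counts: Mapping[str, int] = field(
        default_factory=lambda: {r: 0 for r in EXCLUSION_RULES})

    # derived (calibrated) parameters
    mediator_intercepts: Optional[Mapping[str, float]] = None
    gpa_split_intercepts: Optional[tuple] = None
    outcome_intercept: Optional[float] = None

    # ---------------------------------------------------------------- utils

    def replace(self, **changes) -> "GeneratorConfig":
        return dataclasses.replace(self, **changes)

    def validate(self) -> None:
        if self.n_children < 1:
            raise ConfigError("n_children must be >= 1")
        for name, share_map, cats in (
            ("family_stability_shares", self.family_stability_shares, FAMILY_CATEGORIES),
            ("parental_education_shares", self.parental_education_shares, EDUCATION_LEVELS),
            ("birth_year_shares", self.birth_year_shares, BIRTH_YEARS),
        ):
            if set(share_map) != set(cats):
                raise ConfigError(f"{name} must have exactly the categories {cats}")
            total = sum(share_map.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1 (got {total!r})")
            for k, v in share_map.items():
                if not 0.0 <= v <= 1.0:
                    raise ConfigError(f"{name}[{k}] = {v!r} outside [0, 1]")
        if abs(sum(self.gpa_quartile_shares) - 1.0) > 1e-9 or len(self.gpa_quartile_shares) != 4:
            raise ConfigError("gpa_quartile_shares must be 4 proportions summing to 1")
        for m_name, p in {**self.confounder_prevalences,
                          **self.mediator_base_prevalences,
                          "gpa_missing_rate": self.gpa_missing_rate,
                          "outcome_base_rate": self.outcome_base_rate}.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"proportion {m_name} = {p!r} outside [0, 1]")
        for term, orr in self.outcome_model_odds_ratios.items():
            if orr <= 0.0:
                raise ConfigError(f"outcome odds ratio {term} = {orr!r} must be positive")
        for med, terms in self.mediator_confounder_odds_ratios.items():
            for term, orr in terms.items():
                if orr <= 0.0:
                    raise ConfigError(
                        f"mediator odds ratio ({med}, {term}) = {orr!r} must be positive")
        for med, g in self.income_gradients.items():
            if med not in ALL_MEDIATORS:
                raise ConfigError(f"unknown mediator in income_gradients: {med!r}")
        for rule, cnt in self.exclusion_counts.items():
            if rule not in EXCLUSION_RULES:
                raise ConfigError(f"unknown exclusion rule {rule!r}")
            if cnt < 0:
                raise ConfigError("exclusion counts must be non-negative")
        if sum(self.exclusion_counts.values()) > self.n_children:
            raise ConfigError("exclusion quotas exceed n_children")
        if self.income_log_sd <= 0:
            raise ConfigError("income_log_sd must be positive")

    # ------------------------------------------------------------------ io

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["birth_year_shares"] = {int(k): v for k, v in d["birth_year_shares"].items()}
        d["gpa_quartile_shares"] = list(d["gpa_quartile_shares"])
        if d["gpa_split_intercepts"] is not None:
            d["gpa_split_intercepts"] = list(d["gpa_split_intercepts"])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        if "birth_year_shares" in d:
            d["birth_year_shares"] = {int(k): v for k, v in d["birth_year_shares"].items()}
        if "gpa_quartile_shares" in d:
            d["gpa_quartile_shares"] = tuple(d["gpa_quartile_shares"])
        if d.get("gpa_split_intercepts") is not None:
            d["gpa_split_intercepts"] = tuple(d["gpa_split_intercepts"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def is_resolved(self) -> bool:
        return (self.mediator_intercepts is not None
                and self.gpa_split_intercepts is not None
                and self.outcome_intercept is not None)
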
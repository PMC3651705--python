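"""Per-tissue damage caps: baseline weights plus route/patient modifiers.

The cap for a healthy tissue is produced by a multiplicative pipeline:
gender masking, route baseline lookup (inhalant reuses the local baseline
with lung as an additional target organ), local-delivery adjustment
(target organ heavily protected, everything else relaxed by 20%),
treatment aggressiveness (conservative 75%, aggressive 150%), optional
per-tissue extra protection, and a final clamp to [0, 1].

The shipped default baselines are ILLUSTRATIVE: the underlying ordering
(vital organs and drug-clearing organs get smaller caps; gut tissues are
extra-protected under oral delivery) is principled, the exact numbers are
not, and every value can be overridden by a user config file.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator

from .profiles import ExpressionTable, IsotypeProfile

logger = logging.getLogger(__name__)


class Route(str, enum.Enum):
    IV = "iv"
    LOCAL = "local"
    ORAL = "oral"
    INHALANT = "inhalant"


class Gender(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Aggressiveness(str, enum.Enum):
    CONSERVATIVE = "conservative"
    NORMAL = "normal"
    AGGRESSIVE = "aggressive"


class GenderSpecificity(str, enum.Enum):
    BOTH = "both"
    MALE_ONLY = "male_only"
    FEMALE_ONLY = "female_only"


#: Sentinel: the tissue imposes no constraint in this context.
ABSENT = None


@dataclass(frozen=True)
class PatientCharacteristics:
    gender: Gender
    aggressiveness: Aggressiveness = Aggressiveness.NORMAL
    extra_protection: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "gender", Gender(self.gender))
        object.__setattr__(self, "aggressiveness", Aggressiveness(self.aggressiveness))
        object.__setattr__(self, "extra_protection", frozenset(self.extra_protection))


@dataclass(frozen=True)
class CancerContext:
    """One optimization context: cancer label, delivery route, patient."""

    cancer: str
    route: Route
    patient: PatientCharacteristics
    target_organ: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "route", Route(self.route))
        if self.route in (Route.LOCAL, Route.INHALANT) and not self.target_organ:
            raise ValueError(
                f"route {self.route.value!r} requires a target_organ"
            )


class Modifiers(BaseModel):
    """Multiplicative factors applied on top of the baseline caps."""

    conservative_factor: float = 0.75
    aggressive_factor: float = 1.5
    local_relaxation_factor: float = 1.2
    target_protection_factor: float = 0.25
    extra_protection_factor: float = 0.5

    @field_validator("*")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("modifier factors must be >= 0")
        return v


class WeightConfig(BaseModel):
    """Baseline caps per (tissue, route) plus gender metadata and modifiers."""

    baseline: dict[str, dict[str, float]]
    gender: dict[str, GenderSpecificity] = Field(default_factory=dict)
    modifiers: Modifiers = Field(default_factory=Modifiers)

    @field_validator("baseline")
    @classmethod
    def _caps_valid(cls, v):
        for tissue, routes in v.items():
            for route, cap in routes.items():
                Route(route)  # raises on unknown route names
                if not 0.0 <= cap <= 1.0:
                    raise ValueError(
                        f"baseline cap for {tissue}/{route} must be in [0, 1]"
                    )
        return v

    def tissues(self) -> list[str]:
        return list(self.baseline)

    def gender_specificity(self, tissue: str) -> GenderSpecificity:
        return self.gender.get(tissue, GenderSpecificity.BOTH)

    def baseline_cap(self, tissue: str, route: Route) -> float:
        if tissue not in self.baseline:
            raise KeyError(f"unknown tissue {tissue!r} (not in weight config)")
        routes = self.baseline[tissue]
        key = route.value
        if key == Route.INHALANT.value and key not in routes:
            key = Route.LOCAL.value  # inhalant falls back to the local baseline
        if key not in routes:
            raise KeyError(f"no baseline cap for tissue {tissue!r}, route {key!r}")
        return float(routes[key])


def weight_for(tissue: str, ctx: CancerContext, cfg: WeightConfig
               ) -> Optional[float]:
    """Damage cap for one tissue in one context, or ABSENT (None).

    ABSENT means the tissue is excluded from the constrained optimization
    (gender-specific organ of the other gender).
    """
    spec = cfg.gender_specificity(tissue)
    if (spec is GenderSpecificity.MALE_ONLY and ctx.patient.gender is not Gender.MALE) or (
        spec is GenderSpecificity.FEMALE_ONLY and ctx.patient.gender is not Gender.FEMALE
    ):
        return ABSENT

    cap = cfg.baseline_cap(tissue, ctx.route)
    m = cfg.modifiers

    if ctx.route in (Route.LOCAL, Route.INHALANT):
        targets = {ctx.target_organ}
        if ctx.route is Route.INHALANT:
            targets.add("lung")
        if tissue in targets:
            cap *= m.target_protection_factor
        else:
            cap *= m.local_relaxation_factor

    if ctx.patient.aggressiveness is Aggressiveness.CONSERVATIVE:
        cap *= m.conservative_factor
    elif ctx.patient.aggressiveness is Aggressiveness.AGGRESSIVE:
        cap *= m.aggressive_factor

    if tissue in ctx.patient.extra_protection:
        cap *= m.extra_protection_factor

    return min(max(cap, 0.0), 1.0)


@dataclass(frozen=True)
class TissueConstraint:
    """A healthy-tissue damage cap paired with that tissue's profile."""

    tissue: str
    profile: IsotypeProfile
    cap: float


def build_constraint_set(healthy: ExpressionTable, ctx: CancerContext,
                         cfg: WeightConfig) -> list[TissueConstraint]:
    """One constraint per healthy tissue with a non-ABSENT cap.

    Order follows the input table; skipped (gender-masked) tissues are
    logged.
    """
    if len(healthy) == 0:
        raise ValueError("healthy expression table is empty")
    constraints = []
    for label, profile in healthy.profiles.items():
        cap = weight_for(label, ctx, cfg)
        if cap is ABSENT:
            logger.info("tissue %r skipped (gender-masked for %s patient)",
                        label, ctx.patient.gender.value)
            continue
        constraints.append(TissueConstraint(label, profile, cap))
    return constraints


def load_weight_config(path: str | Path) -> WeightConfig:
    """Load and schema-validate a YAML or JSON weight config."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return WeightConfig.model_validate(data)


def default_weight_config() -> WeightConfig:
    """The illustrative config shipped with the package."""
    ref = resources.files("tubopt").joinpath("data/default_weights.yaml")
    return WeightConfig.model_validate(yaml.safe_load(ref.read_text()))
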
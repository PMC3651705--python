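"""Deterministic synthetic fixtures: profiles, demo panel, drug energies.

Everything here is test/demo scaffolding. The demo panel is ILLUSTRATIVE
— hand-written toy numbers, not measured expression data. The shipped
drug energy table (PELA = peloruside A, LAU = laulimalide) reproduces
published per-isotype binding energy differences and is the only
real-data fixture in the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .damage import BindingEnergyVector, read_energy_table
from .isotypes import N_ISOTYPES
from .profiles import ExpressionTable, normalize
from .weights import WeightConfig, default_weight_config

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters for the Dirichlet profile generator."""

    seed: int = 0
    n_cancer: int = 3
    n_healthy: int = 12
    concentration: tuple[float, ...] = (2.0,) * N_ISOTYPES
    sparsity: float = 0.0

    def __post_init__(self) -> None:
        conc = tuple(float(c) for c in self.concentration)
        if len(conc) != N_ISOTYPES or any(c <= 0 for c in conc):
            raise ValueError("concentration must be 8 positive values")
        if not 0.0 <= self.sparsity <= 0.75:
            raise ValueError("sparsity must be in [0, 0.75]")
        if self.n_cancer < 0 or self.n_healthy < 0:
            raise ValueError("profile counts must be non-negative")
        object.__setattr__(self, "concentration", conc)


def sample_profiles(spec: GeneratorSpec, kind: str = "healthy") -> ExpressionTable:
    """Dirichlet-distributed profiles, optionally sparsified, seed-deterministic.

    Each profile independently zeroes every isotype with probability
    ``spec.sparsity`` and renormalizes; a draw that zeroes everything is
    regenerated (up to 100 attempts).
    """
    if kind not in ("cancer", "healthy"):
        raise ValueError("kind must be 'cancer' or 'healthy'")
    n = spec.n_cancer if kind == "cancer" else spec.n_healthy
    rng = np.random.default_rng(spec.seed if kind == "healthy" else spec.seed + 1)
    table = ExpressionTable(source_kind=kind)
    for j in range(n):
        for attempt in range(100):
            raw = rng.dirichlet(spec.concentration)
            if spec.sparsity > 0:
                keep = rng.random(N_ISOTYPES) >= spec.sparsity
                raw = raw * keep
            if raw.sum() > 0:
                break
            logger.info("all-zero draw for %s_%d (attempt %d), regenerating",
                        kind, j + 1, attempt + 1)
        else:
            raise RuntimeError("failed to draw a non-zero profile in 100 attempts")
        table.add(normalize(raw, f"{kind}_{j + 1}"))
    return table


# Hand-written toy panel. Healthy tissues share low betaIII expression so
# a betaIII-leaning drug can stay under every cap; the cancers overexpress
# betaIII. gut_mucosa has a zero cap under oral delivery, making every
# oral context infeasible by construction (its profile is strictly
# positive, so no simplex point has zero damage to it).
_DEMO_HEALTHY: dict[str, tuple[float, ...]] = {
    "tonsil":          (0.30, 0.20, 0.10, 0.02, 0.08, 0.15, 0.10, 0.05),
    "lymph_node":      (0.25, 0.15, 0.15, 0.03, 0.10, 0.17, 0.10, 0.05),
    "testis":          (0.20, 0.10, 0.10, 0.05, 0.15, 0.20, 0.10, 0.10),
    "prostate":        (0.30, 0.15, 0.10, 0.02, 0.10, 0.18, 0.10, 0.05),
    "breast":          (0.28, 0.12, 0.12, 0.03, 0.10, 0.20, 0.10, 0.05),
    "ovary":           (0.25, 0.15, 0.10, 0.04, 0.12, 0.19, 0.10, 0.05),
    "placenta":        (0.30, 0.10, 0.10, 0.05, 0.10, 0.20, 0.10, 0.05),
    "liver":           (0.40, 0.15, 0.10, 0.01, 0.09, 0.15, 0.05, 0.05),
    "kidney":          (0.35, 0.20, 0.10, 0.01, 0.09, 0.15, 0.05, 0.05),
    "heart":           (0.30, 0.20, 0.15, 0.02, 0.08, 0.15, 0.05, 0.05),
    "brain":           (0.15, 0.25, 0.20, 0.05, 0.15, 0.10, 0.05, 0.05),
    "colon":           (0.30, 0.15, 0.10, 0.03, 0.12, 0.15, 0.10, 0.05),
    "small_intestine": (0.32, 0.14, 0.10, 0.03, 0.11, 0.15, 0.10, 0.05),
    "lung":            (0.28, 0.18, 0.12, 0.04, 0.08, 0.15, 0.10, 0.05),
    "gut_mucosa":      (0.25, 0.15, 0.15, 0.05, 0.10, 0.15, 0.10, 0.05),
}

_DEMO_CANCER: dict[str, tuple[float, ...]] = {
    "demo_carcinoma":   (0.10, 0.15, 0.05, 0.45, 0.05, 0.05, 0.10, 0.05),
    "demo_sarcoma":     (0.05, 0.10, 0.10, 0.30, 0.10, 0.05, 0.25, 0.05),
    "demo_lung_tumor":  (0.08, 0.20, 0.07, 0.35, 0.05, 0.05, 0.15, 0.05),
}


def demo_panel() -> tuple[ExpressionTable, ExpressionTable, WeightConfig]:
    """Fixed illustrative panel: cancers, healthy tissues, weight config.

    The config extends the package default with the ``gut_mucosa``
    tissue, whose oral cap of 0 makes oral contexts infeasible — an
    intentional worked example of constraint-system emptiness.
    """
    cancer = ExpressionTable(source_kind="cancer")
    for label, vals in _DEMO_CANCER.items():
        cancer.add(normalize(np.array(vals), label))
    healthy = ExpressionTable(source_kind="healthy")
    for label, vals in _DEMO_HEALTHY.items():
        healthy.add(normalize(np.array(vals), label))

    cfg = default_weight_config().model_copy(deep=True)
    cfg.baseline["gut_mucosa"] = {"iv": 0.40, "local": 0.40, "oral": 0.0}
    for tissue in _DEMO_HEALTHY:
        if tissue not in cfg.baseline:  # pragma: no cover - panel matches default
            cfg.baseline[tissue] = {"iv": 0.40, "local": 0.40, "oral": 0.40}
    return cancer, healthy, cfg


def pela_lau_energies() -> list[BindingEnergyVector]:
    """The shipped per-isotype binding-energy rows for PELA and LAU.

    Values are energy *differences* with a per-row zero reference cell;
    the source does not state the unit or reference state, so the unit is
    recorded as "unspecified" and must be declared explicitly before
    Boltzmann conversion.
    """
    ref = resources.files("tubopt").joinpath("data/pela_lau_energies.tsv")
    with resources.as_file(ref) as path:
        return read_energy_table(path)
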
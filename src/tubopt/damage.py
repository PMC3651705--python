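"""Damage and affinity mathematics.

Covers the dot-product damage score, the negative-KL damage variant, the
linear per-isotype binding-energy score, the Boltzmann conversion of
binding free energies to an affinity profile, and convex combination of
drug profiles (drug cocktails).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .isotypes import ISOTYPE_NAMES, N_ISOTYPES, parse_isotype
from .profiles import IsotypeProfile, ProfileError

#: Gas constant, J/(mol K).
GAS_CONSTANT = 8.31

#: Joules per mole for each supported energy unit; "kT" means energies are
#: already expressed in units of RT (beta = 1).
ENERGY_UNITS = {"kJ/mol": 1000.0, "kcal/mol": 4184.0, "kT": None}


@dataclass(frozen=True)
class DamageScore:
    """Scalar damage of a drug profile ``r`` on a cell profile ``q``."""

    value: float
    model: str  # "dot" or "kl"

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class BindingEnergyVector:
    """Per-isotype binding free energies for one drug.

    More negative means stronger binding. ``+inf`` marks an isotype the
    drug cannot bind at all (excluded from Boltzmann profiles); ``-inf``
    and NaN are rejected. The unit is carried as metadata and only
    interpreted when converting to an affinity profile.
    """

    energies: np.ndarray
    drug_label: str = ""
    unit: str = "unspecified"

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        if e.shape != (N_ISOTYPES,):
            raise ValueError(
                f"energy vector {self.drug_label!r}: expected {N_ISOTYPES} values"
            )
        if np.any(np.isnan(e)) or np.any(np.isneginf(e)):
            raise ValueError(
                f"energy vector {self.drug_label!r}: NaN or -inf entries not allowed"
            )
        e.setflags(write=False)
        object.__setattr__(self, "energies", e)

    def shifted(self, delta: float) -> "BindingEnergyVector":
        return BindingEnergyVector(self.energies + delta, self.drug_label, self.unit)


@dataclass(frozen=True)
class ThermodynamicContext:
    """Temperature and unit convention for energy-to-affinity conversion."""

    temperature: float = 310.0  # Kelvin
    energy_unit: str = "kJ/mol"

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (Kelvin)")
        if self.energy_unit not in ENERGY_UNITS:
            raise ValueError(
                f"energy_unit must be one of {sorted(ENERGY_UNITS)}, "
                f"got {self.energy_unit!r}"
            )

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/(RT) in the declared unit's reciprocal."""
        scale = ENERGY_UNITS[self.energy_unit]
        if scale is None:  # energies already in units of RT
            return 1.0
        return scale / (GAS_CONSTANT * self.temperature)


def dot_damage(r: IsotypeProfile, q: IsotypeProfile) -> DamageScore:
    """Dot-product damage: sum_i r_i * q_i.

    Symmetric in its arguments; bounded by [min_i q_i, max_i q_i].
    """
    return DamageScore(float(np.dot(r.values, q.values)), "dot")


def kl_damage(r: IsotypeProfile, q: IsotypeProfile,
              on_unsupported: str = "flag") -> DamageScore:
    """Negative Kullback-Leibler damage: -sum_i r_i ln(r_i / q_i).

    Always <= 0, and 0 exactly when r == q. Uses natural log and the
    convention 0 ln 0 = 0. If r puts mass where q has none the score is
    -inf; ``on_unsupported="error"`` raises instead.
    """
    if on_unsupported not in ("flag", "error"):
        raise ValueError("on_unsupported must be 'flag' or 'error'")
    rv, qv = r.values, q.values
    mask = rv > 0
    if np.any(qv[mask] == 0):
        if on_unsupported == "error":
            raise ProfileError(
                f"unsupported-target: drug {r.label!r} binds isotypes absent "
                f"from cell {q.label!r}"
            )
        return DamageScore(-math.inf, "kl")
    val = -float(np.sum(rv[mask] * (np.log(rv[mask]) - np.log(qv[mask]))))
    # KL >= 0 analytically; clip tiny positive roundoff (and -0.0) to exact 0
    return DamageScore(val if val < 0.0 else 0.0, "kl")


def predicted_binding_energy(q: IsotypeProfile, dg: BindingEnergyVector) -> float:
    """Expected binding energy of a drug against a cell: sum_i q_i * dG_i.

    Proportional to -(1/RT) log IC50 for the cell line; lower (more
    negative) values mean a more cytotoxic drug. Only the linear score and
    its ordering are meaningful — no absolute IC50 calibration is applied.
    """
    e = dg.energies
    if np.any(np.isinf(e)):
        # +inf marks non-binding isotypes; they contribute only if expressed
        contrib = np.where((q.values > 0) & np.isposinf(e), math.inf, 0.0)
        if np.any(contrib == math.inf):
            return math.inf
        e = np.where(np.isposinf(e), 0.0, e)
    return float(np.dot(q.values, e))


def binding_profile_from_energies(dg: BindingEnergyVector,
                                  ctx: ThermodynamicContext | None = None
                                  ) -> IsotypeProfile:
    """Boltzmann affinity profile: r_i proportional to exp(-beta * dG_i).

    Invariant under a uniform shift of all energies; computed with
    max-subtraction so it never overflows. ``+inf`` energies get weight 0.
    """
    if ctx is None:
        ctx = ThermodynamicContext()
    e = dg.energies
    excluded = np.isposinf(e)
    if np.all(excluded):
        raise ValueError(f"drug {dg.drug_label!r}: all isotypes excluded")
    x = np.where(excluded, -math.inf, -ctx.beta * np.where(excluded, 0.0, e))
    x = x - np.max(x)
    w = np.exp(x)
    return IsotypeProfile(w / w.sum(), dg.drug_label)


@dataclass(frozen=True)
class MixtureSpec:
    """A drug cocktail: profiles with convex mixing coefficients."""

    components: Sequence[tuple[IsotypeProfile, float]] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        if not comps:
            raise ValueError("mixture needs at least one component")
        coeffs = np.array([a for _, a in comps], dtype=float)
        if np.any(coeffs < 0) or np.any(coeffs > 1):
            raise ValueError("mixture coefficients must lie in [0, 1]")
        if abs(coeffs.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"mixture coefficients sum to {coeffs.sum():.12g}, not 1"
            )
        object.__setattr__(self, "components", comps)


def combine_profiles(mix: MixtureSpec, label: str = "") -> IsotypeProfile:
    """Cumulative profile of a cocktail: sum_k alpha_k * r(d_k).

    Dot damage is linear, so the combination's damage on any cell equals
    the same convex combination of the component damages.
    """
    out = np.zeros(N_ISOTYPES)
    for profile, alpha in mix.components:
        out += alpha * profile.values
    if not label:
        label = "+".join(p.label for p, _ in mix.components if p.label)
    return IsotypeProfile(out / out.sum(), label)


def read_energy_table(path: str | Path, delimiter: str | None = None
                      ) -> list[BindingEnergyVector]:
    """Read a drug energy table: first column ``drug``, 8 isotype columns.

    An optional ``unit`` column carries the energy unit per row.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=delimiter)
    iso_cols: dict[int, str] = {}
    unit_col = None
    drug_col = None
    for orig in df.columns:
        low = str(orig).strip().casefold()
        if low == "drug":
            drug_col = orig
        elif low == "unit":
            unit_col = orig
        else:
            iso_cols[int(parse_isotype(str(orig)))] = orig
    if drug_col is None:
        raise ValueError(f"{path}: missing 'drug' column")
    if len(iso_cols) != N_ISOTYPES:
        missing = [n for i, n in enumerate(ISOTYPE_NAMES) if i not in iso_cols]
        raise ValueError(f"{path}: missing isotype columns: {missing}")
    out = []
    for _, row in df.iterrows():
        e = np.array([float(row[iso_cols[i]]) for i in range(N_ISOTYPES)])
        unit = str(row[unit_col]) if unit_col else "unspecified"
        out.append(BindingEnergyVector(e, str(row[drug_col]), unit))
    return out
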
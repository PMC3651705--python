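"""Isotype expression/affinity profiles: data model, validation and file I/O.

A profile is a probability 8-tuple over the canonical isotype order. The
same type represents cell expression distributions and drug binding
preference distributions; both are always renormalized on construction.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .isotypes import ISOTYPE_NAMES, N_ISOTYPES, Isotype, parse_isotype

logger = logging.getLogger(__name__)

SUM_TOL = 1e-9


class ProfileError(ValueError):
    """Raised when raw values cannot form a valid profile."""


class TableParseError(ValueError):
    """Raised when an expression-table file is malformed."""


@dataclass(frozen=True)
class IsotypeProfile:
    """A normalized distribution over the 8 beta-tubulin isotypes.

    ``values`` must be non-negative and sum to 1 within ``SUM_TOL``;
    use :func:`normalize` to build a profile from raw measurements.
    """

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_ISOTYPES,):
            raise ProfileError(
                f"profile {self.label!r}: expected {N_ISOTYPES} values, got shape {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise ProfileError(f"profile {self.label!r}: non-finite entries")
        if np.any(v < 0):
            raise ProfileError(f"profile {self.label!r}: negative entries")
        if abs(v.sum() - 1.0) > SUM_TOL:
            raise ProfileError(
                f"profile {self.label!r}: entries sum to {v.sum():.12g}, not 1"
            )
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    def __getitem__(self, iso: Isotype | int) -> float:
        return float(self.values[int(iso)])

    def argmax(self) -> Isotype:
        """Isotype with the largest fraction; ties go to the earliest index."""
        return Isotype(int(np.argmax(self.values)))

    def relabel(self, label: str) -> "IsotypeProfile":
        return IsotypeProfile(self.values.copy(), label)

    def allclose(self, other: "IsotypeProfile", atol: float = 1e-9) -> bool:
        return bool(np.allclose(self.values, other.values, atol=atol, rtol=0.0))

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "values": {name: float(x) for name, x in zip(ISOTYPE_NAMES, self.values)},
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: Mapping) -> "IsotypeProfile":
        vals = np.zeros(N_ISOTYPES)
        for name, x in d["values"].items():
            vals[parse_isotype(name)] = float(x)
        return cls(vals, d.get("label", ""))


def normalize(raw: Iterable[float], label: str = "") -> IsotypeProfile:
    """Scale non-negative raw expression values to a probability profile.

    Idempotent; rejects all-zero or negative input.
    """
    v = np.asarray(list(raw) if not isinstance(raw, np.ndarray) else raw, dtype=float)
    if v.shape != (N_ISOTYPES,):
        raise ProfileError(f"expected {N_ISOTYPES} raw values, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ProfileError(f"profile {label!r}: non-finite raw values")
    if np.any(v < 0):
        raise ProfileError(f"profile {label!r}: negative raw values")
    total = v.sum()
    if total <= 0:
        raise ProfileError(f"profile {label!r}: all raw values are zero")
    return IsotypeProfile(v / total, label)


def argmax_isotype(q: IsotypeProfile) -> Isotype:
    """Convenience wrapper for :meth:`IsotypeProfile.argmax`."""
    return q.argmax()


@dataclass
class ExpressionTable:
    """A labeled collection of profiles of one kind (cancer, healthy or drug)."""

    profiles: dict[str, IsotypeProfile] = field(default_factory=dict)
    source_kind: str = "healthy"

    _KINDS = ("cancer", "healthy", "drug")

    def __post_init__(self) -> None:
        if self.source_kind not in self._KINDS:
            raise ValueError(f"source_kind must be one of {self._KINDS}")

    def __len__(self) -> int:
        return len(self.profiles)

    def __contains__(self, label: str) -> bool:
        return label in self.profiles

    def __getitem__(self, label: str) -> IsotypeProfile:
        return self.profiles[label]

    def labels(self) -> list[str]:
        return list(self.profiles)

    def add(self, profile: IsotypeProfile) -> None:
        if profile.label in self.profiles:
            raise ValueError(f"duplicate profile label {profile.label!r}")
        self.profiles[profile.label] = profile

    def to_frame(self) -> pd.DataFrame:
        data = {label: p.values for label, p in self.profiles.items()}
        return pd.DataFrame(data, index=list(ISOTYPE_NAMES))


def _sniff_delimiter(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_table(
    path: str | Path,
    delimiter: str | None = None,
    source_kind: str = "healthy",
) -> ExpressionTable:
    """Read a TSV/CSV table: first column isotype names, one column per sample.

    Rows may appear in any order and use any recognized isotype spelling;
    missing isotypes are imputed as 0 (with a warning). Raw values are
    renormalized per column. All-zero or negative columns are rejected.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if df.shape[1] == 0:
        raise TableParseError(f"{path}: no sample columns found")

    try:
        rows = [parse_isotype(str(name)) for name in df.index]
    except ValueError as exc:
        raise TableParseError(f"{path}: {exc}") from exc
    if len(set(rows)) != len(rows):
        raise TableParseError(f"{path}: duplicate isotype rows")

    raw = np.zeros((N_ISOTYPES, df.shape[1]))
    raw[[int(i) for i in rows], :] = df.to_numpy(dtype=float)

    missing = sorted(set(Isotype) - set(rows))
    if missing:
        names = ", ".join(ISOTYPE_NAMES[int(i)] for i in missing)
        msg = f"{path}: isotype rows missing, imputed as 0: {names}"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)

    table = ExpressionTable(source_kind=source_kind)
    for j, label in enumerate(df.columns):
        col = raw[:, j]
        if np.any(col < 0):
            raise TableParseError(f"{path}: column {label!r} has negative values")
        if col.sum() <= 0:
            raise TableParseError(f"{path}: column {label!r} is all zeros")
        table.add(normalize(col, str(label)))
    return table


def write_expression_table(table: ExpressionTable, path: str | Path,
                           delimiter: str | None = None) -> None:
    """Write profiles as a TSV/CSV with canonical row order."""
    path = Path(path)
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    df = table.to_frame()
    df.index.name = "isotype"
    df.to_csv(path, sep=delimiter, float_format="%.12g")
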
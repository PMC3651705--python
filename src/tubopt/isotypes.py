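"""Canonical identity of the eight human beta-tubulin isotypes.

The ordered set is fixed; the order is the tie-breaking order used
throughout the package (argmax ties resolve to the earliest index).
"""

from __future__ import annotations

import enum


class Isotype(enum.IntEnum):
    """The eight canonical human beta-tubulin isotypes, in fixed order."""

    BETA_I = 0
    BETA_IIA = 1
    BETA_IIB = 2
    BETA_III = 3
    BETA_IVA = 4
    BETA_IVB = 5
    BETA_V = 6
    BETA_VI = 7

    @property
    def display_name(self) -> str:
        return ISOTYPE_NAMES[self.value]

    @property
    def gene_symbol(self) -> str:
        return GENE_SYMBOLS[self.value]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.display_name


#: Display names, positionally paired with :data:`GENE_SYMBOLS`.
ISOTYPE_NAMES: tuple[str, ...] = (
    "betaI",
    "betaIIa",
    "betaIIb",
    "betaIII",
    "betaIVa",
    "betaIVb",
    "betaV",
    "betaVI",
)

GENE_SYMBOLS: tuple[str, ...] = (
    "TUBB",
    "TUBB2A",
    "TUBB2B",
    "TUBB3",
    "TUBB4A",
    "TUBB4B",
    "TUBB6",
    "TUBB1",
)

N_ISOTYPES = 8


def _alias_table() -> dict[str, Isotype]:
    table: dict[str, Isotype] = {}
    roman = ("i", "iia", "iib", "iii", "iva", "ivb", "v", "vi")
    for iso in Isotype:
        variants = {
            ISOTYPE_NAMES[iso.value],
            GENE_SYMBOLS[iso.value],
            "beta" + roman[iso.value],
            "β" + roman[iso.value],  # βI, βIIa, ...
            "b" + roman[iso.value],
        }
        for v in variants:
            table[v.casefold()] = iso
    return table


_ALIASES = _alias_table()


def parse_isotype(name: str) -> Isotype:
    """Resolve a user-supplied isotype name (``βIIa``, ``betaIIa``, ``TUBB2A``...).

    Raises ``ValueError`` for names outside the canonical set.
    """
    key = name.strip().casefold()
    try:
        return _ALIASES[key]
    except KeyError:
        raise ValueError(
            f"unknown beta-tubulin isotype name: {name!r} "
            f"(expected one of {', '.join(ISOTYPE_NAMES)} or a TUBB gene symbol)"
        ) from None
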
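"""Per-residue charge assignment used by the complementarity score.

The default table carries formal side-chain charges at physiological pH:
lysine and arginine +1, aspartate and glutamate -1, histidine +0.5
(partially protonated), every other standard residue 0.  Alternative
tables (e.g. fully protonated His, or pH-shifted charges) can be supplied
anywhere a ``ChargeTable`` is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .exceptions import AlphabetError, ValidationError

STANDARD_AA: str = "ACDEFGHIKLMNPQRSTVWY"

_DEFAULT_CHARGES: dict[str, float] = {aa: 0.0 for aa in STANDARD_AA}
_DEFAULT_CHARGES.update({"K": 1.0, "R": 1.0, "H": 0.5, "D": -1.0, "E": -1.0})


@dataclass(frozen=True)
class ChargeTable:
    """Mapping from the 20 standard one-letter codes to charges in [-1, +1]."""

    charges: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CHARGES)
    )

    def __post_init__(self) -> None:
        missing = [aa for aa in STANDARD_AA if aa not in self.charges]
        if missing:
            raise ValidationError(
                f"charge table missing standard residues: {''.join(missing)}"
            )
        for aa, q in self.charges.items():
            if not -1.0 <= q <= 1.0:
                raise ValidationError(
                    f"charge for {aa!r} is {q}, outside [-1, +1]"
                )

    @classmethod
    def default(cls) -> "ChargeTable":
        return cls()

    @classmethod
    def with_overrides(cls, **overrides: float) -> "ChargeTable":
        """Default table with selected residues overridden, e.g. ``H=1.0``."""
        charges = dict(_DEFAULT_CHARGES)
        charges.update(overrides)
        return cls(charges)

    def __getitem__(self, aa: str) -> float:
        return self.charges[aa]

    def __contains__(self, aa: str) -> bool:
        return aa in self.charges


DEFAULT_TABLE = ChargeTable.default()


def residue_charge(aa: str, table: ChargeTable = DEFAULT_TABLE) -> float:
    """Charge of a single residue under ``table``.

    Raises :class:`AlphabetError` for any letter outside the table, including
    ambiguity codes (B, J, O, U, X, Z) and the stop character ``*`` —
    nonstandard letters are rejected rather than silently zero-charged.
    """
    if aa not in table:
        raise AlphabetError(aa, 0)
    return table[aa]


def sequence_charges(sequence: str, table: ChargeTable = DEFAULT_TABLE,
                     context: str = "") -> list[float]:
    """Charges of every residue; rejects the first nonstandard letter found."""
    out = []
    for i, aa in enumerate(sequence):
        if aa not in table:
            raise AlphabetError(aa, i, context or sequence)
        out.append(table[aa])
    return out
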
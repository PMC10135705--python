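"""Electrostatic complementarity scoring of CDR3 peptides against antigen windows.

The score slides the shorter peptide along the longer and, at each register,
sums charge products between each CDR3 residue and the antigen residue
directly across from it plus its two immediate neighbours:

    S(offset) = sum_i [ w_d * phi(q_c(i), q_a(offset+i))
                        + w_a * (phi(q_c(i), q_a(offset+i-1))
                                 + phi(q_c(i), q_a(offset+i+1))) ]

with ``phi(x, y) = -x*y``, so a positive charge directly across from a
negative one adds to the score while like charges subtract; a charge pair
that is adjacent rather than directly aligned contributes with the reduced
weight ``w_a``.  Positions sliding off either end of the antigen contribute
nothing.  The pair score is the maximum of ``S`` over all registers: the
most complementary pose dominates, as it would for a binding interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .charges import ChargeTable, DEFAULT_TABLE, sequence_charges
from .exceptions import ValidationError

CHAINS = ("TRA", "TRB")
MIN_CDR3_LENGTH = 5


@dataclass(frozen=True)
class CDR3Peptide:
    """One receptor CDR3 amino-acid sequence with its sample id and chain."""

    case_id: str
    chain: str
    sequence: str

    def __post_init__(self) -> None:
        if self.chain not in CHAINS:
            raise ValidationError(
                f"chain must be one of {CHAINS}, got {self.chain!r}"
            )
        if len(self.sequence) < MIN_CDR3_LENGTH:
            raise ValidationError(
                f"CDR3 {self.sequence!r} shorter than {MIN_CDR3_LENGTH} residues"
            )
        sequence_charges(self.sequence, context=f"CDR3 of case {self.case_id}")

    @property
    def label(self) -> str:
        return f"{self.case_id}:{self.chain}:{self.sequence}"


@dataclass(frozen=True)
class AntigenFragment:
    """A named contiguous peptide slice of a candidate antigen.

    ``fragment_index`` is 1-based; index 0 denotes the whole protein.
    """

    antigen_name: str
    fragment_index: int
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError("antigen fragment sequence is empty")
        if self.fragment_index < 0:
            raise ValidationError("fragment_index must be >= 0")
        sequence_charges(self.sequence, context=f"antigen {self.antigen_name}")

    @property
    def label(self) -> str:
        return f"{self.antigen_name}:{self.fragment_index}"


@dataclass(frozen=True)
class ScoreWeights:
    """Weights of the direct and adjacent alignment terms.

    Proximity without direct alignment is a reduced contribution, hence
    ``w_adjacent <= w_direct``.
    """

    w_direct: float = 1.0
    w_adjacent: float = 0.5

    def __post_init__(self) -> None:
        if self.w_direct < 0 or self.w_adjacent < 0:
            raise ValidationError("score weights must be nonnegative")
        if self.w_adjacent > self.w_direct:
            raise ValidationError(
                "w_adjacent must not exceed w_direct "
                f"({self.w_adjacent} > {self.w_direct})"
            )


DEFAULT_WEIGHTS = ScoreWeights()


def _as_seq(obj) -> str:
    return obj.sequence if hasattr(obj, "sequence") else str(obj)


def alignment_score(cdr3, fragment, offset: int,
                    weights: ScoreWeights = DEFAULT_WEIGHTS,
                    table: ChargeTable = DEFAULT_TABLE) -> float:
    """Complementarity score at one fixed register (see module docstring).

    ``cdr3`` slides along ``fragment``; ``offset`` is the antigen position
    facing the first CDR3 residue.  The CDR3 must not be longer than the
    fragment — for the general case use :func:`pair_score`, which swaps
    roles so the shorter sequence slides.
    """
    cseq, aseq = _as_seq(cdr3), _as_seq(fragment)
    if len(cseq) > len(aseq):
        raise ValidationError(
            "CDR3 longer than fragment at a fixed offset; "
            "use pair_score, which slides the shorter sequence"
        )
    if not 0 <= offset <= len(aseq) - len(cseq):
        raise ValidationError(
            f"offset {offset} outside [0, {len(aseq) - len(cseq)}]"
        )
    qc = sequence_charges(cseq, table)
    qa = sequence_charges(aseq, table)
    total = 0.0
    for i, q in enumerate(qc):
        j = offset + i
        total += -weights.w_direct * q * qa[j]
        if j - 1 >= 0:
            total += -weights.w_adjacent * q * qa[j - 1]
        if j + 1 < len(qa):
            total += -weights.w_adjacent * q * qa[j + 1]
    return total


def _offset_scores(slider: list[float], template: list[float],
                   weights: ScoreWeights) -> np.ndarray:
    """Scores at every register of ``slider`` along ``template`` (vectorised).

    Folding the adjacent weight into the template gives
    ``v[j] = w_d*t[j] + w_a*(t[j-1] + t[j+1])`` and
    ``S(o) = -sum_i s[i] * v[o+i]``, a plain cross-correlation.
    """
    s = np.asarray(slider)
    t = np.asarray(template)
    v = weights.w_direct * t
    v[1:] += weights.w_adjacent * t[:-1]
    v[:-1] += weights.w_adjacent * t[1:]
    return -np.correlate(v, s, mode="valid")


def pair_score(cdr3, fragment,
               weights: ScoreWeights = DEFAULT_WEIGHTS,
               table: ChargeTable = DEFAULT_TABLE,
               normalize: bool = False) -> float:
    """Maximum complementarity score over all registers of the sliding pair.

    The shorter sequence slides along the longer, so the score is symmetric
    in its two arguments.  With ``normalize=True`` the score is divided by
    the slider length (per-residue score); off by default.
    """
    a, b = _as_seq(cdr3), _as_seq(fragment)
    if not a or not b:
        raise ValidationError("cannot score an empty sequence")
    slider, template = (a, b) if len(a) <= len(b) else (b, a)
    qs = sequence_charges(slider, table)
    qt = sequence_charges(template, table)
    best = float(np.max(_offset_scores(qs, qt, weights))) + 0.0  # avoid -0.0
    if normalize:
        best /= len(slider)
    return best


def score_matrix(cdr3s, fragments,
                 weights: ScoreWeights = DEFAULT_WEIGHTS,
                 table: ChargeTable = DEFAULT_TABLE,
                 normalize: bool = False) -> pd.DataFrame:
    """Pair scores for every CDR3 (rows) against every fragment (columns).

    Row labels are ``case_id:chain:sequence``; column labels
    ``antigen:fragment_index``.
    """
    if not cdr3s or not fragments:
        raise ValidationError("score_matrix requires nonempty inputs")
    rows = [c.label for c in cdr3s]
    cols = [f.label for f in fragments]
    data = np.empty((len(cdr3s), len(fragments)))
    for j, frag in enumerate(fragments):
        for i, cdr3 in enumerate(cdr3s):
            try:
                data[i, j] = pair_score(cdr3, frag, weights, table, normalize)
            except ValidationError as err:
                raise ValidationError(
                    f"scoring row {rows[i]!r} against column {cols[j]!r}: {err}"
                ) from err
    return pd.DataFrame(data, index=rows, columns=cols)
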
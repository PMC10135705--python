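"""Partition an antigen protein into k near-equal contiguous segments.

A fragment sweep scores CDR3 repertoires against each segment separately,
localising which part of the antigen carries the charge motifs that drive a
cohort-level association.  Segments form a partition (no overlap): extra
residues from ``L mod k`` go to the earliest fragments, so any two fragment
lengths differ by at most one.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import ValidationError
from .scoring import AntigenFragment


@dataclass(frozen=True)
class FragmentationPlan:
    """Half-open 0-based intervals covering ``[0, L)`` in order."""

    antigen_name: str
    k: int
    boundaries: tuple[tuple[int, int], ...]


def plan_fragmentation(length: int, k: int, antigen_name: str = "") -> FragmentationPlan:
    if k <= 0:
        raise ValidationError(f"k must be positive, got {k}")
    if k > length:
        raise ValidationError(
            f"cannot cut a {length}-residue sequence into {k} fragments"
        )
    base, extra = divmod(length, k)
    bounds = []
    start = 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        bounds.append((start, start + size))
        start += size
    return FragmentationPlan(antigen_name, k, tuple(bounds))


def fragment_protein(sequence: str, k: int, antigen_name: str = "antigen") -> list[AntigenFragment]:
    """Cut ``sequence`` into ``k`` contiguous fragments with 1-based indices.

    The first ``L mod k`` fragments carry one extra residue; concatenating
    the fragments in index order reproduces the input exactly.
    """
    plan = plan_fragmentation(len(sequence), k, antigen_name)
    return [
        AntigenFragment(antigen_name, i + 1, sequence[lo:hi])
        for i, (lo, hi) in enumerate(plan.boundaries)
    ]


def whole_protein(sequence: str, antigen_name: str = "antigen") -> AntigenFragment:
    """The full antigen as a single fragment (index 0 by convention)."""
    return AntigenFragment(antigen_name, 0, sequence)
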
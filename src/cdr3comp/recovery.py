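"""Candidate CDR3 extraction from raw reads via conserved anchor motifs.

This is a deliberately simplified stand-in for full V(D)J recombination-read
mining: instead of aligning reads to V/J reference segments, it translates
each read in all six frames and looks for the immunogenetics convention that
a CDR3 spans a conserved cysteine through the J-region phenylalanine or
tryptophan of the ``[FW]G.G`` motif.  Its outputs are candidate CDR3s;
chain assignment comes from caller metadata, never from the sequence.  It
exists so the downstream scoring pipeline can run end-to-end from reads
without the external reference-matching software a production pipeline
would use.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .exceptions import ValidationError

NUCLEOTIDES = set("ACGTN")
STOP = "*"
UNKNOWN = "X"


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"read {self.read_id!r} is empty")
        bad = set(self.sequence) - NUCLEOTIDES
        if bad:
            raise ValidationError(
                f"read {self.read_id!r} contains non-ACGTN letters: {sorted(bad)}"
            )


@dataclass(frozen=True)
class ChainMotif:
    """J-anchor pattern and CDR3 length window for one chain."""

    j_anchor: str = r"[FW]G.G"
    min_length: int = 5
    max_length: int = 30

    def __post_init__(self) -> None:
        if not self.j_anchor:
            raise ValidationError("J-anchor pattern must be nonempty")
        if not self.min_length < self.max_length:
            raise ValidationError("CDR3 length window requires min < max")


@dataclass(frozen=True)
class MotifConfig:
    tra: ChainMotif = field(default_factory=ChainMotif)
    trb: ChainMotif = field(default_factory=ChainMotif)

    def for_chain(self, chain: str) -> ChainMotif:
        if chain == "TRA":
            return self.tra
        if chain == "TRB":
            return self.trb
        raise ValidationError(f"unknown chain {chain!r}")


DEFAULT_MOTIFS = MotifConfig()


def translate_frames(read: ReadRecord) -> list[str]:
    """Six-frame translation: three forward frames then three reverse.

    Stop codons become ``*``; codons containing N become ``X`` and are
    excluded from motif matches downstream.
    """
    if len(read.sequence) < 3:
        raise ValidationError(
            f"read {read.read_id!r} shorter than one codon"
        )
    out = []
    for strand in (Seq(read.sequence), Seq(read.sequence).reverse_complement()):
        for frame in range(3):
            trimmed = strand[frame: frame + 3 * ((len(strand) - frame) // 3)]
            out.append(str(trimmed.translate()))
    return out


def extract_cdr3(peptide: str, chain: str = "TRB",
                 config: MotifConfig = DEFAULT_MOTIFS) -> str | None:
    """Candidate CDR3 in one translated frame, or None.

    Scans J-anchor matches from the right (the J motif sits 3' in a
    junction read) and, for each, takes the rightmost upstream C such that
    the span C..F/W inclusive fits the length window — the shortest
    plausible CDR3 for that anchor, minimising included V-region sequence.
    Spans containing stop or unknown sentinels are rejected.  Absence is a
    normal outcome, not an error.
    """
    motif = config.for_chain(chain)
    pattern = re.compile(motif.j_anchor)
    # overlap-tolerant anchor scan: adjacent motifs like "WGFGQG" contain
    # two anchors and the 3'-most one must win
    anchors = [i for i in range(len(peptide)) if pattern.match(peptide, i)]
    for anchor in reversed(anchors):  # position of the F/W ending the CDR3
        lo = max(0, anchor - motif.max_length + 1)
        hi = anchor - motif.min_length + 1
        for c_pos in range(hi, lo - 1, -1):
            if c_pos < 0 or peptide[c_pos] != "C":
                continue
            span = peptide[c_pos:anchor + 1]
            if STOP in span or UNKNOWN in span:
                continue
            return span
    return None


def extract_from_read(read: ReadRecord, chain: str = "TRB",
                      config: MotifConfig = DEFAULT_MOTIFS) -> list[str]:
    """Unique candidate CDR3s across all six frames, in frame order."""
    seen: list[str] = []
    for peptide in translate_frames(read):
        candidate = extract_cdr3(peptide, chain, config)
        if candidate is not None and candidate not in seen:
            seen.append(candidate)
    return seen


def recover_cdr3_table(reads: list[tuple[str, str, ReadRecord]],
                       config: MotifConfig = DEFAULT_MOTIFS):
    """CDR3 table rows from (case_id, chain, read) triples.

    Returns a pandas DataFrame in the dialect the scoring stage consumes:
    columns ``case_id``, ``chain``, ``cdr3_aa``.  Reads yielding no
    candidate are dropped; extraction order is deterministic in input order.
    """
    import pandas as pd

    rows = []
    for case_id, chain, read in reads:
        for candidate in extract_from_read(read, chain, config):
            rows.append({"case_id": case_id, "chain": chain, "cdr3_aa": candidate})
    return pd.DataFrame(rows, columns=["case_id", "chain", "cdr3_aa"])
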
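"""Recover candidate CDR3s from synthetic junction reads.

Synthesizes nucleotide reads that each embed a known CDR3 between V- and
J-style flanks, translates them in all six frames, extracts candidates by
the C...F/W anchor-motif convention, and reports sensitivity.
"""

from cdr3comp import CohortSpec, extract_from_read, simulate_junction_reads

spec = CohortSpec(seed=20, n_samples=12)
truth, reads = simulate_junction_reads(spec)

recovered = 0
for expected, (case_id, chain, read) in zip(truth["cdr3_aa"], reads):
    if expected in extract_from_read(read, chain):
        recovered += 1

print(f"reads: {len(reads)}; embedded CDR3s recovered: {recovered} "
      f"({100 * recovered / len(reads):.1f}% sensitivity)")
example = reads[0]
print(f"example read {example[2].read_id} ({example[1]}): "
      f"candidates {extract_from_read(example[2], example[1])}")
print()
print("Every candidate starts at the conserved cysteine and ends at the")
print("J-region F/W of the FGXG-style anchor; with no sequencing noise the")
print("extractor recovers every embedded junction.")
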
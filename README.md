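# cdr3comp

Electrostatic complementarity analysis of T-cell-receptor CDR3 repertoires
against candidate tumor antigens — scoring, cohort stratification,
survival comparison and expression association — with a seeded synthetic
cohort generator so every stage runs without controlled-access patient data.

## The problem

Tumor-resident T cells leave sequencing evidence of their receptors: reads
spanning rearranged V(D)J junctions encode the CDR3 loop, the hypervariable
region that contacts antigen. For tumors such as glioblastoma, where cancer
testis antigens (CTAs) are aberrantly expressed, a natural question is
whether the *chemical fit* between a patient's CDR3 repertoire and a CTA
carries prognostic information. This package implements one concrete,
big-data-friendly notion of fit — electrostatic charge complementarity —
and the downstream epidemiology built on it.

## The score

Each residue gets a charge: K, R = +1; D, E = −1; H = +0.5; all others 0
(configurable). Sliding the shorter peptide along the longer, the score at
register *o* is

    S(o) = Σᵢ [ w_d · φ(q_c(i), q_a(o+i)) + w_a · (φ(q_c(i), q_a(o+i−1)) + φ(q_c(i), q_a(o+i+1))) ]

with φ(x, y) = −x·y, w_d = 1, w_a = 0.5. A positive charge directly across
from a negative one raises the score; like charges lower it; a charge pair
that is adjacent rather than directly aligned contributes at half weight.
The **complementarity score (CS)** of a CDR3–antigen pair is max over
registers (the best binding pose); a case's CS against an antigen is the
maximum (default; mean optional) over its CDR3s.

The analyses downstream:

- **fragment sweep** — cut the antigen into *k* near-equal segments and score
  each separately to localise the signal;
- **median split + survival** — divide the cohort at the median CS and compare
  disease-free survival between upper and lower halves with Kaplan–Meier
  curves and a logrank test (both implemented from first principles,
  cross-checked against lifelines in the tests);
- **expression screen** — Pearson correlation of the CS with gene-expression
  panels (immune markers, apoptosis effectors), raw two-sided p-values plus a
  Benjamini–Hochberg adjusted column;
- **CDR3 recovery** — a simplified anchor-motif extractor (C…F/W of the FGXG
  convention, six-frame translation) that pulls candidate CDR3s from raw
  reads so the pipeline can start from sequence files.

## Worked example

```sh
python examples/survival_median_split.py
```

```
cohort: 44 cases, split at CS threshold 3.75
upper group n=19, lower group n=25
KM median DFS: upper 11.9 months, lower 29.8 months
logrank chi-square = 6.581, p = 0.0103

A small p-value says the high-complementarity half of the cohort
progresses faster than the low-complementarity half, as simulated.
```

The cohort is synthetic: 44 cases with seeded CDR3 repertoires scored
against a synthetic antigen, and survival times drawn with a hazard ratio
of 2.5 against the upper-CS half. The logrank test recovers that planted
effect (p ≈ 0.01); the KM medians show the direction. The other examples
(`score_fragment_sweep.py`, `expression_screen.py`, `recover_from_reads.py`)
walk the remaining stages the same way.

The same stages are scriptable from the shell:

```sh
cdr3comp pipeline --seed 17 --outdir run/          # end-to-end synthetic run
cdr3comp fragment antigen.fasta --k 18 --out frags.fasta
cdr3comp survival cdr3s.tsv frags.fasta survival.csv --outdir out/
```

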
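# Methods

## Electrostatic complementarity score

The scoring model treats a CDR3 peptide and an antigen peptide window as
two rigid charged strings. Charges are formal side-chain charges at
physiological pH: K, R = +1; D, E = −1; H = +0.5 (partially protonated);
all other standard residues 0. Histidine's value, like every charge, is
configurable through `ChargeTable`; nonstandard letters (B, J, O, U, X, Z,
`*`) are rejected rather than silently zero-charged, so upstream parsing
errors surface immediately.

At a fixed register the score sums, over CDR3 positions, the negated
charge product with the directly opposed antigen residue (weight
`w_direct = 1.0`) and with its two immediate neighbours (weight
`w_adjacent = 0.5` each): opposite charges add, like charges subtract, and
proximity without direct opposition contributes at reduced weight.
Positions sliding past the antigen's ends contribute nothing. The pair
score is the **maximum** over all registers of the shorter sequence sliding
along the longer — a binding interaction is dominated by its best pose, so
the maximum, not the mean, is aggregated. The same reasoning sets the
default per-case aggregate: the maximum over a case's CDR3s (a single
strongly complementary clone is the salient event); the mean is provided
for sensitivity analysis. No length normalisation is applied by default; a
per-residue flag (divide by slider length) exists for sensitivity checks.

Useful algebraic facts, all enforced by tests: an all-neutral sequence
scores 0 against anything; at equal lengths, negating every antigen charge
negates the score; the pair score is symmetric in its arguments; and
appending a fully charged opposite pair at aligned positions never lowers
the fixed-register score provided `w_direct ≥ 2·w_adjacent` (true for the
defaults — with a heavier adjacent weight the new cross terms could
dominate).

## Fragment sweep

An antigen of length L is cut into k contiguous fragments whose lengths
differ by at most one, the `L mod k` extra residues going to the earliest
fragments. Fragments partition the protein (no overlap): overlapping
windows would double-count charged motifs that straddle boundaries and
change the multiplicity of the sweep. A 1,080-residue protein at k = 18
gives 18 fragments of exactly 60 residues — the canonical segment size for
an 18-way sweep of a CTA-scale protein.

## Median split

Cases with CS strictly above the cohort median form the upper group;
everything else, including ties at the median, falls to the lower group.
With an odd count or median ties the lower group is therefore the larger —
a deterministic convention that makes group sizes reproducible
bit-for-bit. Stratification requires at least four scored cases and at
least two distinct CS values; an all-identical cohort raises a
degenerate-split error rather than fabricating a partition. TRA and TRB
CDR3s pool into one repertoire per case by default; a chain filter allows
per-chain runs.

## Survival statistics

Kaplan–Meier and the logrank test are implemented directly rather than
delegated, because their tie conventions are part of this package's
contract: subjects censored at time t remain at risk for events at t
(events first); censored times shrink later risk sets but contribute no
product-limit factor. The logrank statistic is the standard
observed-minus-expected sum over distinct event times with the
hypergeometric variance, referred to χ²(1); p-values are two-sided
upper-tail. The test suite pins the implementation to hand-worked tables,
to 50 frozen reference values computed once with lifelines (agreement to
1e-8 in χ²), and to a live lifelines cross-check on fresh cohorts; its
sampling behaviour is verified by simulation (type-I error near the
nominal 5%, power > 0.8 at hazard ratio 2 with 100 subjects per group).
The event indicator is treated as a generic right-censored event;
clinical definitions of progression belong to the caller.

## Correlation screen

Pearson r and its two-sided p (t-transform on n−2 df, via scipy) are
computed per panel gene over the inner join of scored and expression
cases; genes absent from the matrix or with constant expression go to a
warnings channel and are skipped, never fatal. Rows are sorted by
ascending raw p (ties: descending |r|, then symbol) and carry a
Benjamini–Hochberg adjusted column computed across the tested panel — raw
p-values are reported unfiltered, the adjusted column is additional
information, not a filter. Expression enters linearly by default, matching
how normalized RNA-seq values are conventionally plotted against a score;
a log2(x+1) flag is available. The screen requires at least three shared
cases; correlation at such sizes is reported, not suppressed, and its
fragility is the caller's concern.

## CDR3 recovery from reads

This module is an explicit simplification: production mining of
recombination reads matches V/J reference segments with dedicated
software, which is out of scope here. Instead, each read is translated in
all six frames (stops → `*`, N-containing codons → `X`); a candidate CDR3
is the span from a conserved cysteine to the J-region F/W of an `[FW]G.G`
anchor. Where several anchors occur, the 3'-most is used (the J motif sits
at the 3' end of a junction read), and the anchor scan tolerates
overlapping motifs; within an anchor, the rightmost cysteine giving a span
inside the length window (default 5–30 residues) wins, minimising included
V-region sequence. Spans containing sentinels are rejected. Chain identity
comes from caller metadata — inferring it would require the very V/J
references this module avoids. Outputs are labelled candidate CDR3s; no
claim is made about the recall/precision of reference-based mining.

## Synthetic cohorts

The generator produces exactly the structure the analysis assumes, so
passing tests demonstrate that the pipeline detects what it is designed to
detect — not that real tumors behave this way. Defaults describe one
study-shaped condition: 44 cases; 2–8 CDR3s per case of length 8–20
(repertoire recoveries from bulk tumor sequencing are sparse); charged
residues up-weighted 1.5× in CDR3 interiors; survival exponential with
baseline hazard 0.03/month (median ≈ 23 months, glioblastoma-like),
hazard ratio 2.5 against the upper-CS group, uniform censoring on (0, 60]
months; and six panel genes whose expression is `max(0, 10 + β·z + ε)`
with z the standardized CS — β ≈ ±1 and noise sd ≈ 1.73 put the population
|r| near 0.5, the regime of a few-dozen-case screen (CIITA and SPHK2
positive; CD19, AIFM3, COX7A2L, UQCRC2 negative). Clipping at zero honours
the nonnegativity of expression matrices and sits ~5 standard deviations
below the offset, so its effect is negligible.

Determinism: the mandatory seed feeds a `SeedSequence` whose spawned
children drive the repertoire, survival, expression, antigen and read
generators independently — consuming one stream cannot perturb another,
and every table is byte-reproducible from the `CohortSpec` alone.

What the generator does **not** emulate: V(D)J recombination statistics
(no gene segments, no insertion/deletion profiles), sequencing error,
clonal abundance structure, covariance between repertoire size and
outcome, or any biological linkage between sequence and hazard beyond the
planted group effect. The synthetic junction reads additionally keep CDR3
interiors cysteine-free so that the rightmost-cysteine extraction rule is
exactly invertible — internal cysteines are rare in productive CDR3s, but
this is a convenience of the generator, not a property of the extractor.

## Numerical and design notes

- Sliding-register scoring is vectorised as a cross-correlation after
  folding the adjacent weight into the template profile; a naive
  double-loop oracle in the tests pins it exactly (float operations are
  identical sums, so agreement is exact, not approximate).
- Ties in the correlation ranking and the median split are broken
  deterministically (documented above), so repeated runs of any pipeline
  command produce byte-identical tables; plots are exempt.
- Case-id joins are exact string matches after whitespace trimming; no
  cohort-specific barcode munging.
- Simulation-based tests size their replicate counts so the asserted bands
  sit several binomial standard deviations from the expected rate
  (e.g. 1,000 replicates for the null-calibration property of the survival
  generator).
- The library is the primary interface; the `cdr3comp` CLI is a thin layer
  for shell pipelines, and `examples/` holds narrative walkthroughs of
  each capability.

## Limitations

The score is a screening statistic, not a binding model: no structure, no
MHC restriction, no hydrophobicity or shape complementarity, and the
direct-plus-adjacent weighting is a minimal realisation of
"direct opposition counts fully, proximity counts less" with all weights
exposed for sensitivity analysis. Conclusions on real cohorts depend on
upstream repertoire recovery and expression normalisation, both outside
this package's scope.
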
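# Methods

## The screen

The pipeline models a matched wound/control transcriptomics experiment in
the chick chorioallantoic membrane: each egg contributes one wounded and one
unwounded CAM sample, hybridized to separate arrays. Downstream, wound-
responsive genes are mapped to human orthologs and filtered for an
endothelial expression signature derived from cDNA-library EST counts, with
a literature keyword score and qPCR validation on the side. Probe-level
array preprocessing (background correction, summarization) is upstream of
this package: the pipeline ingests linear-scale probe × sample matrices. The
one normalization the package does provide is trimmed-mean global scaling
(each array rescaled so its trimmed mean equals a target intensity,
TGT = 100 by default, trimming 2% at each tail — the array-platform
convention; both are parameters).

## Differential expression

The statistic is the Wilcoxon rank sum of the wound group (midranks for
ties), the rank-based variant of Significance Analysis of Microarrays; no
variance-stabilizing fudge constant is needed for a rank statistic.
Significance comes from sample-label permutation: all distinct relabelings
are enumerated when there are no more than `n_permutations` (default 200) of
them — a 3v3 design has exactly C(6,3) = 20 — otherwise relabelings are
sampled with a seeded 64-bit generator. A paired mode permutes by within-egg
label swaps (2^eggs patterns) instead, respecting the matched design; the
unpaired two-class mode is the default.

The calling rule is joint: a gene is called when its centred rank statistic
|W − E₀[W]| clears the cutoff **and** its mean fold change is beyond the
threshold (FC > 2 or < 1/2). Exactly the same joint rule is applied to every
permuted relabeling when counting false calls — the fold-change criterion is
part of the procedure, not a cosmetic post-filter. This matters at n = 3
pairs: the two-sided tail of a 3v3 rank statistic can never be smaller than
2/20 = 0.1, so the rank statistic alone cannot certify FDR < 5%; jointly
with the fold-change gate the permutation null collapses (permuted
relabelings mix conditions and destroy the fold change), and planted effects
are recoverable at FDR < 5%.

The list FDR at a cutoff is the median (configurably the mean) permutation
false-call count divided by the observed call count, clipped to [0, 1] and
regularized to be non-increasing as the cutoff becomes more extreme
(cumulative minimum over cutoffs, the step-up convention). The per-gene
`fdr` reported for each gene is this list FDR evaluated at the gene's own
statistic — a q-value-like convenience; `fdr_at_cutoff` exposes the per-list
form directly.

Fold changes are linear mean ratios wound/control. For presentation,
down-regulation uses the negative-reciprocal convention: ratio r maps to r
if r ≥ 1, else −1/r, so values never fall in (−1, 1); rounding (2 decimals)
happens only at the presentation layer.

## Ortholog mapping

Alignment execution is out of scope; the module consumes BLAST tabular
(outfmt 6) files. EST-to-mRNA assignment discards Bad-ranked hits
(Good: alignment > 100 bp and identity ≥ 96%; Reasonable: > 100 bp and
90 < identity ≤ 95; Bad: all other hits — including, literally, identities
strictly between 95 and 96) and keeps the highest bit score, with a
deterministic tie-break chain: identity, then alignment length, then
lexicographically smallest subject id. Reciprocal best hits use the same
total order in both directions; the output is a one-to-one partial matching
by construction and symmetric under swapping the species roles. Whether the
hit tables are nucleotide- or protein-level is the caller's choice; the
module is agnostic.

## Endothelial filter

For gene counts c_e, c_n in pools of total size N_e, N_n, the Endofactor is
(c_e/N_e)/(c_n/N_n) — equivalently (c_e/c_n) × (N_n/N_e) — infinite when the
gene is absent only from the non-endothelial pool, zero in the mirror case,
and undefined (an error) when absent from both. The pool totals are inputs;
only their ratio enters the factor, and the default ratio 4.391014 is the
single constant under which every finite published Endofactor is exactly
reproduced from its printed counts. Significance uses a standard 2×2
likelihood-ratio (G) test of equal pool proportions (0·log 0 := 0, p from
χ²₁) — a transparent, fully testable stand-in for the original screen's
unpublished likelihood-ratio statistic, sharing its null and asymptotics.
Multiple testing uses Benjamini–Hochberg q-values by default; a Storey-style
variant (π₀ estimated at λ = 0.5) is available behind a flag. The retention
filter is inclusive: q ≤ 0.01.

## Angioscore

Matching is case-insensitive substring matching of the default keyword list;
the stem "endoth" deliberately catches "endothelial" and "endothelium", and
"vascular" also fires inside "neovascularisation" — harmless because the
default counting unit is abstracts-with-at-least-one-keyword, not keyword
occurrences (occurrence counting is available behind the `unit` flag). The
gene–abstract linkage is input data; no live literature queries, for
reproducibility.

## qPCR

ΔCt normalizes the target to the housekeeping gene within each sample;
ΔΔCt = ΔCt(wound) − ΔCt(control); FC = 2^(−ΔΔCt), assuming perfect
doubling. Technical replicates are averaged on the Ct scale first. Per-egg
fold changes are summarized by the geometric mean (fold changes are ratios;
arithmetic mean behind a flag); both the per-egg values and the summary are
emitted. Amplification efficiency is the conventional E = 10^(−1/slope) − 1
from the standard-curve slope; the 90–100% acceptance gate is applied to E
rounded to 0.1%, so the conventional four-digit perfect-doubling slope
−3.3219 (E = 1.000024) passes as intended.

## GO summaries

Category percentages divide by the number of list genes with any annotation
in the term's namespace (not all list genes): a composition statement about
annotated genes, with multi-annotated genes counted once per term so
percentages can exceed 100 in sum. Over-representation is the one-sided
hypergeometric upper tail against a background (default: all annotated
genes on the chip), BH-adjusted across tested terms. Input annotations are
taken as already propagated through the ontology; proprietary functional-
clustering and network tools are not re-implemented.

## Synthetic data

Every generator is a pure function of its parameters and seed.

- **Expression**: log-normal baseline intensities (median 100, log-sd 1);
  a shared multiplicative egg effect (log-sd 0.1) because the paired design
  is central; multiplicative log-normal measurement noise with CV 0.3 by
  default (typical array-replicate variability); planted wound effects on a
  `de_fraction` of genes, drawn log-uniformly from [2, 80] by default —
  spanning the study's observed range up to ~79-fold. With CV = 0, the mean
  fold change recovers the planted effects exactly (egg effects cancel in
  the ratio of group means).
- **Hit tables**: planted one-to-one pairs are mutual best hits with
  Good-rank alignments; decoy paralogs get inflated one-way scores so that
  a naive best-hit mapping would absorb them while RBH rejects them; extra
  weak hits exercise the Reasonable and Bad classes.
- **EST pools**: multinomial draws over the genes *plus an explicit
  unreported remainder category* (a real library contains far more
  transcripts than the genes under study). This keeps pool totals exactly
  conserved while leaving null genes with identical per-EST probabilities
  in both pools, so planted enrichment does not bias null genes toward
  spurious depletion. Defaults: 500 genes taking ~30% of each library,
  pool totals 10,000 and 43,910 (the published ratio), 4% of genes enriched
  20-fold. A noise-free mode emits exact expected counts, under which the
  Endofactor returns the planted enrichment factor exactly.
- **Corpus**: per-gene abstract counts are Poisson (rate 3), each abstract
  keyworded independently (rate 0.5); the truth stores each gene's exact
  keyword-abstract count. Filler sentences avoid every keyword substring.
- **qPCR plates**: stable housekeeping Ct (18), target base Ct uniform in
  20–28, wound Ct shifted by −log₂(FC), Gaussian well noise (sd 0.2 by
  default), nine eggs as in the validation experiment.

What the simulations do not emulate: probe-level effects and
cross-hybridization, array spatial artifacts, heavy-tailed outliers,
correlated gene modules, EST library composition biases beyond a single
pool-size ratio, and real literature term co-occurrence. Passing tests
therefore certify the arithmetic, calibration and wiring of the screen on
idealized data, not performance on raw chip data.

## Problem sizes and numerics

The test suite and analysis drivers use 250–2,000-gene matrices with three
egg pairs (exhaustive 20-assignment permutation mode), 400-gene ortholog
graphs, 500-gene EST pools and nine-egg plates — the full suite runs in a
few seconds while exercising every code path at the design's true
combinatorial size. Numerical choices: correlation-distance clustering
clips distances to [0, 2] and breaks merge ties by the lowest pair index
(the naive O(n³) average-linkage agglomeration is implemented directly so
this tie-break is exact; sample counts are tiny); permutation FDR clips to
[0, 1] before monotone regularization; 0·log 0 := 0 throughout the G-test;
(0, 0) EST count pairs and all-zero arrays raise errors naming the
offending gene or sample rather than propagating NaN.

## Known limitations

The published headline gene counts (282 up, 44 down) depend on the study's
raw chip data and cannot be reproduced from printed tables; the package
instead certifies the procedure's calibration and power on simulations with
known truth. The original endothelial screen's exact likelihood-ratio
statistic is unpublished; the G-test here matches its null behaviour but
not necessarily its finite-sample values. The Angioscore's original corpus
is unavailable, so published scores (e.g. CD44 = 60) are not re-derivable;
the implementation fixes the counting unit (abstracts) and exposes the
alternative.
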
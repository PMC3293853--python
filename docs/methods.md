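# Methods

## Operator-site information models

An aligned set of *n* sites of width *L* is summarized by column base
frequencies `f(b, l) = (count(b, l) + q) / (n + 4q)` with pseudocount
*q*, and weights `R_iw(b, l) = log2(f(b, l) / p(b)) − e(n)` in bits.
The individual information of a window is the sum of its weights; the
mean over the training sites, `R_sequence`, equals the alignment's total
information `Σ_l (2 − H(l))` when *q* = 0 and the correction is off —
this identity is asserted to 1e−9 in the tests and the acceptance script.

Choices a user can make, and the defaults:

- **Pseudocount** *q* = 0.5 per base per column. It keeps every score
  finite for scanning. With *q* = 0, a zero-count base is assigned a
  finite floor of −30 bits rather than −∞, so sorting and thresholding
  stay well defined; the floor is far below any plausible calling
  threshold.
- **Background** `p(b)`: uniform by default, which puts scores on the
  conventional 2-bit-per-position scale that published ARG-box `R_i`
  values use. A genome-composition background (e.g. GC 0.72 for
  *Streptomyces*) is available as an explicitly separate scoring mode;
  scores from the two modes are not comparable.
- **Symmetrization**: on by default. ARG boxes are imperfect palindromes
  bound by a symmetric protein, so reverse complements of all sites are
  appended before counting. The resulting matrix satisfies
  `R_iw(b, l) = R_iw(comp(b), L+1−l)` exactly (integer counts, identical
  arithmetic), which the tests assert with exact equality. The 18-nt
  *S. clavuligerus*-style model was built this way in the source
  analysis; for the 20-nt single-box model the pooling of complements is
  an assumption recorded in the model metadata.
- **Small-sample correction** `e(n) = 3 / (2 ln2 · n)` bits, off by
  default. The original Delila toolchain applies a related correction
  whose exact form is not recoverable from the published description, so
  it is a flag, and all analytic identities in the tests are stated for
  correction-off.
- **Ambiguity codes**: `score_site` rejects non-ACGT characters by
  default; an optional policy scores them as an uninformative flat 0-bit
  contribution. The scanner never reports windows containing ambiguous
  bases (they are scored −∞ internally, below any finite threshold).

**Tandem models.** Two box matrices joined by a spacer of *s* neutral
positions (default geometry of interest: *L* = 18, *s* = 2, total 38 nt).
Neutral positions carry weight 0 for every base, so the tandem score of a
window decomposes exactly into the sum of its two box scores — asserted
exhaustively on random sequences.

**Scanning.** Every window on the requested strand(s) with
`R_i ≥ threshold` is reported, sorted by (offset, strand), reverse-strand
hits in forward coordinates. The implementation scores the reverse strand
by scanning with the reverse-complemented weight matrix, which is
algebraically identical to reverse-complementing each window. A
symmetric model necessarily reports mirrored +/− hits with equal scores
at each locus; `dedupe=True` collapses these keeping the + record, so
one site is counted once. Correctness is checked against a deliberately
naive brute-force per-window scorer (pure-python loops, its own
complement table) on 100 random sequences at GC 0.5 and 0.72 and several
thresholds: hit sets must be identical and scores equal to 1e−9.

**Thresholds.** 5 bits is the single-box candidate-calling threshold and
12.2 bits the tandem-total threshold for confident operators; both are
raw bit cutoffs (no p-value calibration, by design). The tandem threshold
is interpreted as applying to the 38-nt tandem total, not per box.

## Promoter windows

Windows are defined relative to the first base of the start codon
(position 0): the scanning window spans −300..+100 inclusive (401 nt)
and the probe-level window is 800 nt centered on the start codon. Both
are strand-aware; minus-strand windows are reverse-complemented so the
sequence reads 5′→3′ relative to the gene. Windows truncated at contig
ends are flagged and logged, never errors. Internal coordinates are
0-based half-open everywhere; 1-based inclusive coordinates appear only
in the gene-table reader/writer, and BED output is 0-based half-open.
Overlapping promoter windows of adjacent genes are scanned independently
(a locus may be reported under several genes), matching per-gene
presentation; genome-level deduplication is left to the caller.

## Two-channel normalization and the factorial fit

Per array, `M = log2(Cy3/Cy5)` and `A = ½·log2(Cy3·Cy5)` per spot.
Normalization subtracts each print-tip group's weighted median of M
(unit weights for unmasked spots; groups under 10 usable spots fall back
to the global median, logged) and then a global lowess trend of M on A
(span 0.3, 2 robustness iterations). Masked spots and non-positive
intensities are excluded; duplicate spots are then averaged into one
`M_g` per gene, with a gene surviving as long as one spot does.

The per-gene model is a one-way layout over the four conditions:
condition means are OLS estimates (per-condition replicate means),
residual variance is pooled across conditions with `Σ(n_c − 1)` degrees
of freedom and floored at 1e−12, t statistics are two-sided. This is a
deliberate simplification of the moderated-statistics machinery used in
the original analysis (spot-quality weights, duplicate correlation,
array weights), which is not reproducible from the published
description; the downstream `H_r` procedure is defined over (p, M_c)
regardless of the fitter. An optional moderation flag shrinks each
gene's variance toward the median gene variance with 4 prior degrees of
freedom for extra stability at 4 replicates; it is off by default and no
reported quantity depends on it.

`M_c(c5)` is computed literally as `M_c(c3) − M_c(c2)` so the interaction
identity holds bitwise, not merely to rounding. Benjamini–Hochberg
adjustment is applied within each contrast across genes; the
significance gate is min adjusted p over the five contrasts < α. A gene
is dropped from a contrast (`M_c = 0`, p = 1, logged) when an involved
condition retains fewer than 2 replicates.

**H_r discretization.** Per contrast: 0 if uncorrected p ≥ α (default
0.05) or if `M_c` is exactly 0 (tie rule); otherwise `sign(M_c)`.

## The profile rule table

The published type/subtype taxonomy was defined by visual inspection of
profile plots, so any executable rule table is an interpretation. The
shipped table (`profile_rules_v1.tsv`, versioned, first match wins)
encodes 13 mutually exclusive `H_r` patterns chosen under two
constraints: they follow the prose descriptions of the types (I —
regulator-repressed, c1 = +1, subtypes graded by the arginine response;
II — regulator-activated mirror; III — arginine-stimulated with the
regulator, down without; IV — arginine-stimulated regardless; V —
type-I-like arginine response without the strain effect), and every
pattern is *sign-realizable*: because `M_c(c5) = M_c(c3) − M_c(c2)`, a
pattern like (c2 = −1, c3 = 0, c5 = 0) cannot occur at high power, so
the subtype splits were arranged so that each subtype corresponds to an
achievable sign vector. Concretely, within type I the subtypes are
I.1 (no arginine response), I.2 (arginine represses equally in both
strains, no interaction), I.3 (arginine induces only in the mutant),
I.4 (arginine represses only in the wild type, interaction engaged) and
I.5 (opposite arginine responses, strongest interaction); type II
mirrors these with all signs flipped. Wildcards are used where a
component's sign is genuinely uninformative (mostly c4, whose sign
follows c1 + c5). The loader warns when two rules with different labels
overlap ambiguously (neither pattern a strict specialization of the
other); the shipped table has no such overlaps. Non-significant genes
are never labelled; significant genes matching no rule are
"unclassified".

## Synthetic data

The generators emulate the study design, not array physics:

- `gen_expression`: 4 conditions × 4 biological replicates (defaults),
  `M_g = planted condition mean + N(0, sd²)` i.i.d. on the log2 scale
  with sd 0.3 — the replicate-noise scale at which the pipeline is
  benchmarked — and planted mean 4-tuples per subtype taken from
  `SUBTYPE_MEAN_PATTERNS` scaled by the effect size (default 2.0 on the
  log2 scale). The default mixture for benchmarks is 20 genes per
  subtype among 5000 genes. Null genes have identical condition means.
- `gen_sites`: consensus with i.i.d. per-position substitution at rate
  0.05 (default), the sharply peaked regime in which operator models are
  trained from ~22 sites. The default consensus is a synthetic perfect
  20-nt palindrome (`TGAATCGCATATGCGATTCA`), standing in for the real
  imperfect-palindromic consensus which is only published graphically.
- `gen_genome`: i.i.d. background at GC 0.72 (the *Streptomyces*
  chromosome composition) with non-overlapping planted sites and an
  exact truth table.

All generators are pure functions of their parameters and seed
(bit-reproducible, asserted). What they deliberately do not model:
scanner physics, spatial artefacts beyond the loess-testable intensity
trend, correlated replicate noise, real codon/k-mer structure of the
chromosome, and operon structure. Passing the benchmarks therefore
demonstrates the statistical machinery is correct and calibrated under
the stated noise model, not that real arrays or the real genome would
yield the published gene lists — the original raw data has no public
accession, so those numbers are not reproducible here.

## Problem sizes and numerical choices

Benchmarks run at 5000 genes × 16 arrays for the expression half and
100 kb genomes for the motif half, sizes at which every check completes
in seconds while leaving the statistical margins (binomial error on a
5% rate at n = 5000 is ±0.3%) far smaller than the tolerances asserted.
Key tolerances: exact equality for the symmetry, interaction and
ternary-universe invariants; 1e−9 for score/oracle and `R_sequence`
identities; type-I error asserted within 0.04–0.06; planted-subtype
recovery ≥ 90% with false labels ≤ 1%; planted-site sensitivity ≥ 95%.

## Known limitations

- The rule table is one defensible reading of a figure; real-data subtype
  counts cannot be certified against the original classification.
- The unmoderated OLS fit is slightly conservative at 4 replicates
  compared with moderated alternatives; the moderation flag narrows the
  gap but does not reproduce any specific moderated statistic.
- The "weighted" in the print-tip weighted median is implemented as
  binary mask weights; the original spot-quality weighting scheme is not
  public.
- Genome-wide candidate counts depend on whether overlapping promoter
  windows are deduplicated; this package scans windows independently and
  leaves deduplication explicit.
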
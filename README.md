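# argbox

Information-theory models of bacterial operator sites and factorial
two-channel microarray profile classification, built for regulon studies
of the arginine repressor/activator ArgR in *Streptomyces* and similar
systems.

The package serves two audiences in one workflow: bioinformaticians who
want to build weight-matrix models of ARG-box operators from a handful of
experimentally verified sites and scan promoters or whole genomes for new
candidates, and transcriptomics analysts who need to turn a 2×2 factorial
two-channel array experiment (strain × supplementation, common gDNA
reference) into discrete, interpretable expression profiles.

## The models

**Operator sites.** From an aligned set of *n* fixed-width sites, the
per-position per-base weight matrix in bits is

    R_iw(b, l) = log2( f(b, l) / p(b) ) − e(n)

with `f(b, l)` the (pseudocounted) base frequency at position *l*, `p(b)`
the background probability (uniform by default, giving the familiar
`2 + log2 f` form with a 2-bit ceiling per position) and `e(n)` an
optional small-sample correction. The individual information of a window
is `R_i = Σ_l R_iw(window[l], l)`; the mean `R_i` over the training
alignment is `R_sequence`, the total information content of the site set.
Because operators of hexameric regulators are imperfect palindromes,
models can be *symmetrized* (reverse complements appended before
counting), which makes the matrix exactly reverse-complement symmetric.
Tandem operators — two boxes joined by a short neutral spacer, the
arrangement found upstream of arginine biosynthesis operons — are scored
as the sum of the two box scores, spacer positions contributing 0 bits.
A scanner reports every window on either strand above an `R_i` threshold,
in forward coordinates, with BED6 export.

**Expression profiles.** Arrays are normalized spot-wise (per-print-tip
weighted-median centering, then global loess of M on A), duplicate spots
averaged into per-gene `M_g = log2(Cy3/Cy5)` values, and the five
contrasts of the factorial design fitted per gene by OLS with a pooled
within-condition variance:

    c1 = C − A      strain effect, control
    c2 = B − A      arginine effect, wild type
    c3 = D − C      arginine effect, mutant
    c4 = D − B      strain effect, + arginine
    c5 = c3 − c2    interaction

(A/B = wild type ± arginine, C/D = deletion mutant ± arginine.) Each
contrast is discretized into a ternary `H_r` code — 0 if not significant
at uncorrected α = 0.05, otherwise the sign of the contrast estimate
`M_c` — and genes passing the FDR gate (Benjamini–Hochberg adjusted
p < 0.05 in ≥ 1 contrast) are classified into five profile types and 13
subtypes by an ordered, versioned rule table over `H_r` patterns.

Synthetic generators (`gen_sites`, `gen_genome`, `gen_expression`,
`gen_spot_table`) produce inputs with the same statistical structure, so
the whole pipeline is testable and benchmarkable without any external
data.

## Worked example

```python
from argbox import build_site_matrix, gen_genome, gen_sites, rsequence, scan

sites = gen_sites(n_sites=22, mutation_rate=0.05, seed=11)
model = build_site_matrix(sites, symmetrize=True, pseudocount=0.5)
print(rsequence(model, sites))

genome, truth = gen_genome(100_000, gc=0.72, sites=sites, n_plant=50, seed=12)
hits = scan(model, genome, threshold=5.0, dedupe=True)
print(len(hits), max(h.ri for h in hits))
```

Running `examples/01_build_and_scan_model.py` (the script version of the
above) prints:

```
model: 20 nt wide, 44 effective sites (complements appended)
R_sequence = 31.9 bits (mean information of a training site)
50 windows scored >= 5 bits; 50/50 planted sites recovered at exact offsets
top hit: ScanHit(seq_id='seq', offset=4455, strand='+', ri=37.14..., ...)
```

31.9 bits is the mean information a training site carries under the
model; at that sharpness every one of the 50 sites planted in 100 kb of
GC-0.72 background scores above the 5-bit calling threshold at its exact
position. The other examples walk through tandem promoter scanning
(`02`), the factorial contrast/H_r/subtype pipeline (`03`, ~92% planted
subtype recovery at effect 2.0 and noise sd 0.3) and two-channel
normalization (`04`).

A thin CLI mirrors the library: `argbox build-model | scan |
extract-promoters | scan-promoters | normalize | contrasts | classify |
simulate-sites | simulate-genome | simulate-expression` (see
`argbox --help`).

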
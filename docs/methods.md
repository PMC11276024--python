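# Methods

This note documents the models, conventions and numerical choices
behind `termindex`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Coordinates and windows

All genomic coordinates are 1-based inclusive (GFF3 convention).
Strand-aware offsets place position 0 at the poly(A) nucleotide, with
positive offsets downstream in the direction of transcription. bedGraph
input/output uses the UCSC 0-based half-open convention and is
converted on load; minus-strand bedGraph values may be deposited as
negative magnitudes, and the sign is stripped.

The readthrough index (RTI) uses the inclusive offset windows
**−500..−51** (upstream) and **+51..+500** (downstream), each 450 nt
wide. The prose convention "50 to 500 / −500 to −50" is ambiguous at
both boundaries; the 450-nt width fixes the interpretation, and
excluding offsets ±1..±50 keeps imprecise cleavage-site annotation and
the pile-up at the site itself out of both windows. Windows extending
past a chromosome end are truncated (missing positions count 0).

The stored signal is the 3′-end count: each primary, mapped,
non-duplicate alignment contributes one count at its strand-aware
3′-most aligned base. Duplicate exclusion is the default for BAM input
and is recorded in the loader's log; there is no between-library
normalization, because the RTI is a within-sample ratio and the
metagene is CDS-normalized per gene.

## Gene filters

Three structural/expression filters protect the windows, applied in
this order (the counts surviving each stage are logged as a cascade):

1. **Neighbor distance** — the poly(A) site must be ≥ 500 nt (default)
   from the nearest coordinate of the next gene downstream on the same
   chromosome and strand. Only the downstream side is checked: the
   readthrough windows extend only downstream, and an upstream
   neighbor cannot contaminate them. Genes with no same-strand
   downstream neighbor are kept.
2. **mRNA length** ≥ 500 nt (inclusive). Length is the strand-aware
   span from the annotated transcript start to the poly(A) site; when
   an annotation carries no transcript bounds the CDS length is used
   (logged).
3. **Expression** — mean CDS 3′-end density ≥ 1 read/nt in ≥ 3 samples,
   pooled across strains.

## Per-gene test and defective call

RTIs are computed per replicate first, then averaged per strain — the
replicate-level values are the unit of the statistical comparison. A
gene is eligible for testing with ≥ 2 non-missing replicate RTIs per
strain and ≥ 5 overall; otherwise it is reported as *undetermined*
rather than silently dropped. A replicate RTI is missing when its
upstream window is empty; no pseudocount is added by default because
pseudocounts bias low-expression genes and the expression filter makes
empty upstream windows rare (a configurable pseudocount exists).

The test is a one-sided Welch (unequal-variance) t-test for an RTI
increase in the mutant. The defective call requires
`log2(mean_mut/mean_wt) > 1` (at least 2-fold) **and** raw `p < 0.05`.
The fold-change threshold is a configuration knob; the 2-fold reading
is the one consistent with the "at least a 2-fold increase" criterion
and is the default. Raw p-values drive the call deliberately — the
analysis this mirrors uses no multiplicity correction — but a
Benjamini–Hochberg column is emitted for reference. A zero WT mean
with a positive mutant mean yields an infinite log2 ratio, which
satisfies the fold criterion; the p-value still gates the call.

Strain-level summaries report the per-gene-mean RTI distribution per
strain: the mean comparison is a paired two-sided t-test across genes
(genes pair the strains), the distribution comparison an unpaired
two-sided Welch test, with box-plot quartiles. Degenerate cases
(identical inputs with zero variance) return p = 1 by convention
instead of NaN.

Feature association (`associate_rti`) is generic: a numeric gene
feature (e.g. length) is tested by Spearman rank correlation; a
two-class categorical feature (e.g. TATA vs TATA-less promoter, an
annotation input, never inferred) by a two-sided Welch test with
per-class summaries. Constant features and single-class inputs are
errors, not silent zeros.

## Metagene and heatmap

Per gene and replicate, the per-nucleotide signal at offsets −200..+200
is divided by that replicate's mean CDS density; profiles are averaged
across replicates per gene, then mean ± standard error across genes per
offset (401 points). Genes with zero CDS density in any replicate are
excluded with a warning. The heatmap value is the **difference** of
CDS-normalized densities (mutant − WT) per replicate pair — a ratio
would be undefined wherever the WT signal is zero, which is exactly the
downstream region of interest. Replicates are paired across strains by
replicate index; rows are ordered by ascending per-gene log2 RTI
ratio, so the ordering key of the figure is the same quantity as the
defective-call effect size. Both choices are configurable in the sense
that the matrix is returned with its ordering key and can be re-ordered
or re-derived.

## Interactomics (SAF/BNSAF)

SAF = spectral count / protein length (aa), per replicate. BNSAF =
SAF(prey)/SAF(bait) in the same run; the bait's own BNSAF is 1 wherever
defined. SAF is deliberately **not** run-total normalized (NSAF-style):
any run-level constant cancels in the bait ratio, so the extra
normalization would only matter if it were not run-constant, and the
simpler statistic is exactly depth-invariant (tested). Replicates with
zero bait counts are excluded with a warning. Strains are compared per
protein with a paired two-sided t-test over replicate BNSAFs (paired by
replicate index), reporting the percent change `100·(1 − mut/wt)`,
grouped by complex. Chromatin and soluble fractions are analyzed
separately; the interaction effects of interest live in the chromatin
fraction.

## ChIP and TRO normalization

ChIP occupancy is the ratio of ratios
`(IP/input) / (PolII_IP/PolII_input)`; this is the standard reading of
"normalized with the input signal and then with the RNAPII signal", and
it makes occupancy invariant to any common rescaling of the four
signals (tested). Non-positive signals reject the measurement with a
reason rather than propagating. TRO nascent signal is divided by the
18S control of the same reaction. Strain comparisons use a two-tailed
Welch test; dispersion is reported as SE for ChIP and SD for TRO
(matching the conventions of the respective assays), with both emitted.

## Synthetic-data generator

Per gene the expected 3′-end density is flat at the expression level
`e` (reads/nt) across the body, and `e · r · exp(−d/λ)` at distance `d`
downstream of the poly(A) site, with readthrough fraction `r` per
strain and decay length `λ` (default ∞ = constant). With a flat body
the expected RTI is `r · Σ_{d=51..500} exp(−d/λ) / 450`, i.e. exactly
`r` for `λ = ∞`, which gives parameter-recovery tests closed-form
targets. Counts are Poisson by default — nucleotide-resolution 3′-end
counts are low-mean, for which Poisson is the natural first model — and
a negative-binomial option adds overdispersion. Genes are laid out
chain-wise on synthetic chromosomes with a controlled poly(A)-to-next-
gene distance (default 1200 nt; an optional fraction of genes is placed
closer than 500 nt to exercise the neighbor filter); minus-strand
chromosomes are mirrored layouts, so strand handling is exercised
end-to-end. Every generator is a pure function of (parameters, seed).

Study-design defaults: 3 replicates per strain for signal cohorts,
4 for spectral counts, 3 for ChIP/TRO; expression 5 reads/nt and
baseline readthrough r = 0.01 for generic recovery cohorts.

The **paper-mimic preset** is a 337-gene, 3+3-replicate cohort:
expression log-normal (median 5 reads/nt, σ = 0.6, floor 1.5 so all
genes clear the expression filter — the 337 genes represent a
post-filter analysis set), wild-type `r` log-normal with median 0.008
and σ = 1.0, and 73.8% of genes planted defective with a common fold.
That fold (≈ 12.2) is *solved* from the mixture-median equation so the
mutant cohort's theoretical median readthrough is 0.063 — the two
medians and the defective fraction are the generator's targets; the
fold is derived, not tuned. A gene-wise multiplicative fold model
cannot simultaneously match those medians and the corresponding
published mean RTIs (the real mutant distribution is less skewed than
any multiplicative shift of the wild-type distribution), so the preset
targets the medians and the defective fraction only.

The interactomics generator plants CF1A/Rat1 prey suppression of
70–90% (effects 0.15–0.25) with modest replicate variability, CPF
suppression of 50% with high variability (σ = 0.8, so the decline is
real but not consistently significant), and unchanged-to-increased
general transcription factors. The ChIP generator plants a 90% drop in
factor occupancy with unchanged polymerase signal; the TRO generator
plants strong body signal in both strains and downstream signal
essentially only in the mutant.

### What the generator does not emulate

No sequence content, no read-level simulation, no mappability or
library-composition artifacts, no positional structure within the gene
body (ramps, pausing peaks) beyond the optional stress-test ramp, no
correlated noise between replicates, and no alternative poly(A)-site
usage. Passing recovery tests therefore demonstrates correctness of
the statistics under the stated generative model — not robustness to
alignment artifacts or annotation error in real data.

## Problem sizes and tolerances

The test suite and acceptance script use: 100+ random fixtures for
exact window-arithmetic equivalence; 300-gene cohorts for parameter
recovery (median absolute error < 0.02 for r ∈ {0.01, 0.05, 0.15});
2000 genes for null calibration of the defective call and 500 genes for
planted-cohort recovery (±5 percentage points); 50+ random vectors for
t-test oracle agreement at 1e-10. These sizes make the whole suite run
in well under a minute while keeping Monte-Carlo error comfortably
inside each tolerance. All stochastic tests are seeded; the pipeline
itself is deterministic (re-running any stage on identical inputs and
configuration produces byte-identical tables).

## Known limitations

- The neighbor filter checks only the downstream side; a dense
  upstream neighbor on the same strand could still contribute signal
  to the *upstream* window and deflate the RTI.
- Genes whose mutant and wild-type means are both zero are reported
  with an undefined log2 ratio and are never called defective.
- The metagene excludes a gene when any replicate has zero CDS
  density, which is slightly stricter than pooling densities across
  replicates.
- Categorical feature association supports exactly two classes;
  multi-class features must be compared pairwise by the caller.
- All I/O and computation are serial and deterministic; there is no
  parallel mode.
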
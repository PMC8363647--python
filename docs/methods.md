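# Methods

## Intensity model and background correction

Observed foreground intensity per spot and channel is modelled as
X = B + S: truncated-normal background B ~ N(μ_b, σ_b²) (clipped at 0) plus
exponential true signal S. The generator's defaults are μ_b = 100,
σ_b = 15 and signal mean 1000 — foreground roughly ten-fold above
background, typical of usable two-colour array spots. The per-gene true
signal s is shared between the two channels of an array and split
asymmetrically, s·2^{M/2} into the polysome channel and s·2^{−M/2} into the
subpolysome channel, so the planted log-ratio M is exactly encoded while
total intensity is M-invariant. Per gene and array, M = M_true + N(0, σ_n);
M_true is 0 for null genes and ±`effect_log2` for planted genes on tumour
arrays. Dye-swapped arrays (by default the second repeat of every sample)
exchange the red/green assignment. An optional log-normal per-gene baseline
(`abundance_sigma`) adds intensity heteroscedasticity; it is **off by
default** because it makes the marginal signal distribution heavy-tailed
relative to the exponential, which corrupts the moment-based normexp fit
(the third central moment can inflate α̂ two-fold, driving the σ² ≤ 0
fallback and a wildly negative μ̂).

Correction uses the closed-form conditional mean E[S | X = x] =
m + σ·φ(z)/Φ(z), m = x − μ − σ²/α, z = m/σ. The Mills ratio is evaluated in
log space (`log_ndtr`), so the output stays strictly positive and monotone
down to intensities far below background. Parameters are fitted per channel
per array by method of moments: α from the third central moment
(E[(X−EX)³] = 2α³), σ² = Var − α², μ = mean − α, with a fallback to
σ = 0.1α (and μ re-derived) when σ² ≤ 0. The moment fit is a deliberate
closed-form, deterministic approximation to likelihood-based normexp
fitting; its known weaknesses are (i) σ is a small difference of two large,
noisy moments and is effectively unidentifiable when α ≫ σ (sd(σ̂²) ≈
2α²/√n), and (ii) α̂ has relative sd ≈ √(216/n)/3 — about 22% at 500 probes
per array — so per-array corrections carry noise that partially attenuates
recovered log-ratios. Both effects are irrelevant to rank-based inference
(a per-array monotone distortion leaves within-column ranks unchanged) and
are accounted for by the array-permutation null below. Even with exact
parameters the posterior mean shrinks near-zero signals toward the
background floor, so the mean recovered effect is ~3% below the planted
value; the recovery that matters (gene calling at the published thresholds)
is verified directly.

## Rank-product test

Fold-change columns are all (tumour array, control array) pairwise
differences of M (k = n_t × n_c; the design is unpaired and this is the
deterministic choice requiring no pairing metadata). Ranks use average ties;
RP is the geometric mean of ranks; each gene appears in both the UP and the
DOWN list; FC is reported linear (2^mean d) to match fold-change thresholds;
significance: FC ≥ 2 (inclusive — "at least two") and pfp < 0.2 (strict).
p-values use +1 smoothing, p_g = (1 + #{null RP ≤ RP_g})/(1 + n_perm·G);
pfp_g = p_g·G/rank_g, reported raw (a cumulative-minimum monotonisation is
available behind a flag). Default n_perm = 1000; a seed is required.

Two permutation null schemes are provided:

* `columns` — every column's ranks are independently permuted (the classical
  rank-product null). It is exact when the k columns are independent
  replicate comparisons and admits exhaustive enumeration over all (G!)^k
  column permutations for tiny problems (exhaustive mode reports the exact
  tail probability, without smoothing). Under the all-pairs scheme, however,
  columns sharing an array are correlated (ρ ≈ 0.5), and this null is far
  too narrow: simulated null experiments give a KS uniformity p ~ 1e-54.
* `arrays` (pipeline default) — gene labels are permuted within each
  *array* of the M-value table and all pairwise fold changes and ranks are
  recomputed. This preserves the between-column correlation structure, and
  null p-values are uniform (KS p ≈ 0.4 at G = 500, 24 + 6 arrays).

Sampled nulls are drawn from column-sorted inputs (a uniform permutation of
a multiset does not depend on input order), which makes sampled p-values
exactly invariant to gene relabelling in the columns scheme; the arrays
scheme applies explicit data-independent permutation indices so that
negating all M values swaps the UP and DOWN outputs exactly. In the arrays
scheme gene-order invariance holds in distribution rather than realisation.

Array similarity uses d(a,b) = 1 − Pearson r of M profiles with
average-linkage agglomeration (scipy), exported as Newick.

## UTR feature scanners

* TOP: position 1 is C followed by ≥ `min_run` consecutive pyrimidines;
  TOP-like if the same pattern starts at positions 2–5; TOP takes
  precedence. The pyrimidine run length is configurable with default 4
  (published TOP definitions use runs of 4–15).
* uORF: any ATG whose first base lies in the 5′UTR, reading to its first
  in-frame stop; it counts if the stop ends strictly before the last base of
  the CDS and the total length (start through stop, inclusive) is ≥ 9 nt.
  Overlapping uORFs all count; stops inside the CDS count.
* ARE: non-overlapping, leftmost-first matches of `TATTTAT[AT][AT]` in the
  3′UTR.
* TISU: membership in a supplied gene list (primary mode), or a consensus
  scan of `SAASATGGCGGC` spanning the start codon with ≤ 1 mismatch outside
  the invariant ATG.
* MFE: `RNAfold` when requested and available (kcal/mol); otherwise a
  built-in dynamic-programming proxy equal to −1 × the maximum number of
  nested Watson–Crick (+GU by default) pairs with hairpin loops ≥ 3 nt.
  The proxy is comparable within a run but is not an energy; sequences
  < 5 nt score 0. All scanners work in DNA space; U→T on input.

## Synthetic data

Transcripts are assembled per gene from planted blocks: a 5′-prefix forcing
the TOP class, an optional self-complementary hairpin (8 bp stem) for
"structured" UTRs, uORF cassettes (`ATG` + stop-free codons + `TAA`) and a
TISU context (`SAAS` UTR suffix + `ATGGCGGC` CDS start), embedded in random
filler scrubbed of accidental ATGs and AREs; every planted flag is
re-verified with the default scanners (with regeneration on collision), so
truth tables agree with the annotation stage exactly. The drawn 5′UTR
length is a target minimum that grows if the planted blocks need more room;
an explicit per-class length cap turns that into an error naming the gene.
Up-regulated genes default to shorter (mean 70 vs 150 nt), less structured
5′UTRs with fewer uORFs and more TISU elements, mirroring the biological
signature the enrichment stage is meant to detect; TOP and ARE rates are
class-independent. CDSs are built from sense codons (start ATG, single
terminal stop, length divisible by 3).

Particle fields are non-overlapping rasterised ellipses on 512×512 grids at
0.02 μm/px (about 17 particles over ~20 fields, matching electron-microscopy
field counts): elongated particles draw minor semi-axis 0.10–0.16 μm and
axis ratio 3.5–5; enlarged draw area 0.7–1.4 μm² at ratio ≤ 1.25; "other"
draw small areas (0.12–0.35 μm²) at ratio 1.4–2.4 so they fail both rules.
Truth areas are analytic (πab), hence pixel-size invariant. Placement is
rejection sampling capped at 10,000 attempts.

One global seed expands into fixed per-component substreams
(`default_rng([seed, component])`), so any generator can be re-run
independently and two identical runs are byte-identical.

What the generators do **not** emulate: spatial/print-tip artefacts,
within-array normalisation problems, probe cross-hybridisation, image noise
beyond rasterisation, or realistic GO term hierarchies (no graph
propagation). Passing tests therefore demonstrate correctness of the
statistics under the stated generative model, not robustness to those
artefacts.

## Enrichment

Binary features: Pearson χ² without continuity correction (a Yates flag
exists) on list vs rest-of-chip 2×2 tables; tables with a zero margin are
flagged untestable (p = NA). Continuous features: Welch two-sample t.
GO terms: one-sided Fisher exact (equal to the hypergeometric tail) against
a configurable reference universe that may include the list, with sample
odds ratios (a·d)/(b·c) and optional Benjamini–Hochberg adjustment; raw
p-values are the default report. Note that Pearson χ² and the conditional
two-sided Fisher p agree only loosely at moderate counts (typically within
a factor of two for cells ≥ 20), though they order tables nearly
identically.

## Morphology

Descriptors come from connected-component region properties: pixel-count
area, equivalent-ellipse axes from second central moments, weighted-contour
perimeter; circularity 4πA/P² clamped at 1 (coarse rasters can exceed it).
Border-touching particles are excluded by default; labels under 5 px are
skipped with a warning. Classification applies strict inequalities with
elongated taking precedence over enlarged (configurable). The per-field
Mann–Whitney comparison is exact by full enumeration of all C(n1+n2, n1)
assignments for ≤ 8 fields per condition (two-sided: probability of a U at
least as far from n1·n2/2 as observed), and the tie-corrected normal
approximation otherwise.

## Numerical and interface choices

TSV everywhere (tab-separated, header row, '.' decimal, no quoting) for
bit-exact diffability; FASTA per transcript region; label grids as
plain-text integer matrices (16-bit TIFF accepted on input). All CLI stages
exit non-zero with a one-line diagnostic on declared errors; `run-all` logs
the fully resolved configuration and aborts naming the failing stage.
Problem sizes used by the test-suite and the acceptance script (500 genes,
30 arrays, 1000 permutations, 10–20 replicate seeds; 6 particle fields)
were chosen as the smallest sizes at which the statistical contracts are
sharp.

## Known limitations

* The moment-based normexp fit does not estimate σ reliably when α ≫ σ; μ
  and α recover to a few percent at n = 50,000 but σ̂ has sampling error
  larger than typical background SDs. Likelihood-based fitting would be
  needed for accurate σ.
* pfp is reported raw and can exceed 1 and be non-monotone along the list.
* The built-in folding proxy ignores stacking energies and loop penalties.
* GO analysis treats terms independently (no ontology propagation or
  redundancy clustering).
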
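# Methods

`trisomethyl` analyses a single-cell-clone design for constitutional
trisomy 8 mosaicism: three fibroblast clones trisomic for chromosome 8 and
three disomic clones from the same patient, plus two unrelated reference
fibroblast lines (one XY, one XX).  Three data layers are analysed — log2
expression arrays, genome-wide BAC methylation arrays (MeDIP), and promoter
tiling arrays for 5mC and 5hmC (MeDIP/hMeDIP) — and joined at the gene
level.  This note documents the statistical procedures, their assumptions,
the defaults, and what the synthetic generator does and does not emulate.

## Expression analysis

**Clone designation.**  A clone is accepted as trisomic (disomic) when at
least a fraction `fish_fraction` (default 0.95, i.e. 285 of 300 nuclei) of
scored interphase FISH nuclei show three (two) signals; everything else is
rejected as mosaic.

**Filtering and scaling.**  The variance filter keeps the
`ceil(fraction * n)` probes with the largest across-sample SD (sample SD,
n−1), ties broken toward the lexicographically smaller probe id so results
are deterministic.  Row standardization (mean 0, SD 1) uses the population
SD (n): it is a scaling step, not an inferential one; test statistics use
the sample convention.  Standardizing a constant row is undefined, so
zero-variance rows are dropped with a logged warning.  Median centering
subtracts each probe's across-sample median and is idempotent.

**Group-significant probes.**  Probes separating the three culture groups
are screened with a per-probe one-way ANOVA on standardized, filtered data,
with Benjamini–Hochberg correction and a q < alpha cut (default 0.05).  A
PCA view of the same standardized data (correlation-matrix PCA, returning
scores and loadings only) is exposed as a diagnostic; significance never
comes from PCA projections.  Note the power limit: with group sizes 3/3/2
and the default effect size (log2 1.5 against noise SD 0.25), per-probe
ANOVA p-values rarely reach the BH threshold at array scale, so this screen
selects few or no probes on the default simulation.  That is a property of
the design, not a defect; the recovery checks therefore cluster the
variance-filtered matrix directly.

**Clustering.**  Average linkage throughout; Euclidean distance between
samples, correlation distance (1 − Pearson) between genes.  Cutting the
sample tree at k = 3 gives the flat labels used by the cluster-purity
check (the trisomic triplet alone in one cluster).

**t-tests.**  Welch (unequal variance) two-sided t-tests, since equal
group variances are not assumable across clones and references.  The
degenerate zero-variance case returns p = 1 for identical means and p = 0
otherwise.

**SAM.**  The moderated statistic d = r/(s + s0): for two classes, r is
the mean difference and s the pooled standard error; for the multiclass
statistic, r = sqrt(between-group mean square) and s = sqrt(within-group
mean square), so d² reduces to the ANOVA F when s0 = 0.  s0 is chosen by
percentile minimization: among the 5%-step percentiles of s, pick the one
minimizing the coefficient of variation of the d-scale (MAD within
s-quantile bins).  The null distribution comes from label permutations —
all distinct assignments when fewer than `n_permutations` exist (20 for
3v3, 56 for 3v5; always the case at this design size), otherwise a seeded
sample without replacement.  q-values follow the median-FDR recipe: at the
cut |d|_(i), the estimate is pi0 × median over permutations of the number
of null |d*| exceeding the cut, divided by i, clipped to [0, 1] and
monotonized to be non-increasing in |d|.  pi0 is the fraction of observed d
inside the permuted interquartile range, scaled by 2.  Fewer than 50
permutations is refused (unstable FDR).

**Intersection calling.**  A gene is trisomy-associated only if it passes
all four criteria: Welch p < alpha in trisomy-vs-disomy AND in
trisomy-vs-(disomy+reference), and SAM q ≤ `sam_q_max` (default 10%) in
both contrasts.  Fold change is reported against the combined
disomy+reference group as a signed linear value: 2^Δ for Δ ≥ 0 else
−2^(−Δ), so |fc| ≥ 1 and fc(a,b) = −fc(b,a).

**Dosage profile.**  Genes on the trisomic chromosome are listed in
positional order with per-group means of median-centered expression.  A
gene counts as overexpressed when its trisomy-group median exceeds the
disomy-group median by more than `overexpression_margin`, default
log2(1.5)/2 ≈ 0.29 — the midpoint between "no change" and the 3:2 dosage
ratio, i.e. nearest-mean classification.  A margin-free comparison
(median > median) would count half of all unaffected genes as
overexpressed by chance at these group sizes, which is why the midpoint
rule is the default; the margin is configurable.

**qPCR.**  Comparative CT: ddCT = (CT_target,sample − CT_control,sample) −
(CT_target,calibrator − CT_control,calibrator); fold = 2^(−ddCT).

## Genome-wide (BAC) methylation

**Smoothing.**  "Factor 0.33" smoothing is implemented as the minimal
local smoother consistent with it: a three-point weighted moving average
along genomic order per sample, neighbor weight `smoothing_factor`
relative to the center, weights renormalized to sum 1 (so constants are
preserved and chromosome ends simply drop the missing neighbor).  It is
linear and shift-equivariant.

**Gene counts and bins.**  A clone's gene count is the number of gene
intervals overlapping it under half-open arithmetic (any overlap).  Clones
are grouped per chromosome by gene count; a bin is analysed when it holds
at least `bin_min_fraction` (default 0.1%, boundary inclusive) of the
chromosome's clones.

**Testing.**  Each bin is tested with one-way fixed-effects ANOVA over
clone × sample observations — "weighted" in the sense that unequal group
sizes weight groups by observation count, the standard unequal-n ANOVA —
followed by Tukey HSD (Tukey–Kramer studentized-range comparisons, valid
for unequal n).  A bin is flagged when the ANOVA rejects at alpha and the
focal group (trisomy, or XX for the sex contrast) differs from every other
group at alpha in the Tukey comparisons; the double Tukey condition keeps
the realized null flag rate well below alpha.  Clone-level observations
within a bin are treated as independent; no spatial autocorrelation
correction is applied — a known statistical limitation of the clone-wise
procedure.  Because smoothing precedes binning, a strong gene-poor signal
bleeds into neighboring gene-count bins on the same chromosome (visible as
flagged low-count bins beyond the planted ones); this is a property of the
smooth-then-bin order, not leakage across chromosomes.  p-values across
bins are reported nominally (no cross-bin correction) to match the
procedure being reimplemented; a BH switch can be applied downstream from
the emitted table.

## Promoter (tiling) methylation

**Centering.**  Each sample's log2 IP/input ratios are centered by
subtracting Tukey's biweight mean over all array features (bisquare
weights, scale 9 × MAD, iterated to 1e−8; MAD 0 falls back to the median).
Robust centering keeps enrichment peaks from dragging the location
estimate.

**Windowed KS score.**  For each probe, the in-window set is all probes
within `ks_window_bp`/2 (default 375 bp, inclusive) of its center on the
same chromosome; the comparison set is every out-of-window probe on the
array (per-chromosome background via `background="chromosome"`).  The
one-sided two-sample statistic D⁺ = sup_t [F_background(t) − F_window(t)]
asks whether the window is drawn from a more positive distribution; the
p-value is the asymptotic exp(−2 m n D⁺²/(m+n)) and the score is −log10 p,
capped at `score_cap` (default 300).  Windows with fewer than two probes
score 0 with a warning.  Scores are computed on per-group mean scaled
tracks by default (per-sample mode available).

**Potts segmentation.**  Exact L0 segmentation by dynamic programming in
O(n²): minimize the within-segment sum of squares plus
`potts_gamma` × (segments − 1), every segment at least `potts_min_segment`
points (defaults 2 and 2); cost ties break toward fewer segments.  The
penalty operates on the score scale (Potts objectives are
scale-dependent).  The smoother is applied to the score tracks; a
ratio-domain segmentation can be run by passing scaled ratios to the same
function.

**Enriched-gene calling.**  A gene's aggregate score is the maximum
segment mean of its promoter's Potts-segmented probe scores, so any
supporting evidence spans at least `potts_min_segment` probes —
single-probe spikes cannot support a call; genes with fewer probes than
the minimum segment are unscorable.  The call threshold is either fixed
(`score_threshold`, with score ≥ 1.3 ≈ p ≤ 0.05 as the conventional
significance floor) or chosen so the called set size lands in a target
bracket (default 150–200, midpoint 175); the threshold used is always
reported.

**Chromosome comparisons.**  Per promoter, the arm-average scaled level is
median-centered across all promoters on the array (per arm) and the
chromosome's promoters are compared between arms with a paired two-sided
t-test.  Centering across the whole array (not per chromosome) is what
makes a chromosome-wide depletion detectable.  Limitation: when the tested
chromosome carries a large share of the array, a genuine shift on it moves
the arm's global median and leaks a small opposite offset onto every other
chromosome; with genome-like chromosome shares (any chromosome a small
minority) the leak is negligible at desk scale, which is how the generator
defaults are chosen.  The per-sample X-vs-autosome comparison is a Welch
t-test of X promoter levels against all autosomal levels; its rank-plot
data are the sorted median-centered X levels (a permutation of the input).

## Integration

Expression classes from log2 fold change with inclusive boundaries: under
if fc ≤ −0.5, over if fc ≥ +0.5, intermediate between.  The cut-offs are
interpreted on the log2 scale: a signed linear fold change cannot lie in
(−1, 1), so ±0.5 cuts only make sense for log2 values.  For an enriched
promoter set, the summary reports the fraction of genes per expression
class (fractions sum to 1) and a Welch t-test comparing log2 fold changes
of enriched versus non-enriched genes; a chromosome-restricted mode
reproduces single-chromosome summaries.  `run_pipeline` executes all
stages on simulated inputs, seeded from `Config.seed`, and writes every
table plus a manifest (config values, hash, seed, version); reruns are
byte-identical.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure the analyses assume, at
desk scale (defaults ≈5,000 expression genes, ≈600 BAC clones, ≈6,000–20,000
promoter probes; the full array sizes are reachable via size arguments):

- Expression: per-gene baseline N(7, 2) log2 units (an arbitrary plausible
  array scale — only differences matter); 65% of trisomic-chromosome genes
  shifted by log2(3/2) in the trisomy group; 30 trans genes off the
  chromosome shifted by ±U(0.5, 1.0); 150 genes carrying a
  reference-specific signature of ±U(0.3, 0.8), because the references are
  unrelated individuals rather than the patient's own clones (without this
  third population, a k = 3 clustering of the design would be ill-posed);
  i.i.d. N(0, 0.25) noise per cell.
- BAC methylation: clone ratios N(0, 0.15); gene counts drawn from a
  distribution with 45% zero-gene clones and most clones at 0–3 genes
  (range 0–20); gene-poor clones (≤1 gene) on the trisomic chromosome
  shifted by −0.3 in the trisomy group; gene models are placed inside their
  clone so the overlap counter recovers the drawn counts exactly.
- Promoter tracks: probes in promoter blocks of 15 at 100-bp spacing,
  background N(0, 0.3); peak promoters get +1.5 within ±400 bp of the
  promoter center; chromosome-wide offsets (e.g. 5hmC depletion −0.5 on the
  trisomic chromosome, trisomy samples only) are applied per group or per
  sex; chromosome shares are genome-like (the trisomic chromosome holds
  ~8% of probes).
- FISH: binomial nucleus counts at a given true trisomic fraction.

Not emulated: probe-level microarray chemistry (GC bias,
cross-hybridization, dye effects), platform preprocessing, spatial
autocorrelation of methylation beyond the injected block structure,
per-promoter CpG density, and miRNA-specific structure beyond a biotype
label.  Passing recovery tests therefore demonstrates that the procedures
recover the effects they model under clean noise assumptions — not that
they are robust to array artefacts, which the upstream platform pipeline
is responsible for removing.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open everywhere; probe positions are probe
  centers.  Missing values in matrices are hard errors.
- Deterministic tie-breaks: variance filter (probe id), Potts (fewer
  segments), enriched-gene ranking (score then gene id).
- Biweight mean with MAD 0 returns the median; identical ANOVA groups
  return F = 0, p = 1; identical Tukey groups return p = 1.
- All simulation and permutation randomness flows from explicit seeds
  (numpy `default_rng` / `SeedSequence`); equal seeds give bit-identical
  outputs.
- Acceptance-style checks run at the desk-scale sizes above with 8–20
  seeds per statement; the oracle checks (Potts enumeration, ECDF
  supremum, all-pairs overlap) are exact.

## Known limitations

- The gene-density ANOVA ignores spatial correlation between neighboring
  clones, so its p-values are anti-conservative for real arrays.
- Median-centering leakage for chromosome-level tests (above).
- The size-targeted enriched-gene threshold adapts to the dataset; across
  datasets the fixed-score mode is the comparable one.
- SAM multiclass uses an F-like statistic; published SAM implementations
  differ in the exact multiclass contrast, and no claim of formula-level
  equivalence with any particular tool is made.
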
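# Methods

This note records the models, conventions and numerical choices behind
`stereomorph`, in the spirit of a statistical-software methods appendix.

## Coordinate and sectioning conventions

Coordinates are continuous µm in a right-handed frame. Voxel indexing is
0-based with voxel centers at `(i + 0.5) · voxel_size`; this single
convention is used by the rasterizer, the cell sampler, the sectioner and
the thickness solver. Virtual sectioning cuts slabs of uniform thickness
*T* along one axis with the first cut at a uniform random offset in
[0, T) (systematic uniform random, SUR). A cell belongs to exactly one
section, decided by its reference point — the nucleus centroid, the
standard fractionator proxy for "first appearance of the nucleolus". A
section's region area is defined as (slab voxel count × voxel volume)/T,
so that summed area × T reproduces the voxelized volume exactly; the
central voxel layer serves as the 2D profile where an image-like mask is
needed (nucleator seeding). Sectioning a grid whose axial voxel size
exceeds T produces alternating empty slabs; phantoms for sectioning
should use an axial voxel size that divides T (the built-in study
geometries use 40 µm).

## Phantoms and cohorts

Regions are ellipsoids or concentric shells, optionally rescaled so the
analytic solid volume hits a target; ground truth records analytic
volumes (not voxel counts), and voxelized volume agrees with analytic to
≤ 2% at the default resolutions (converging under refinement). Cell
populations place an exact requested total uniformly over the region's
labeled voxels; class mixtures and laminar profiles are split exactly
(largest-remainder), and only marker flags (PV, VVA) are binomially
thinned. Cortical layers are fractional depth bands of the region's
extent along a chosen axis — by default bands I–III / V / VI at
0–45/45–80/80–100% of depth with occupancies 0.45/0.40/0.15,
a coarse but serviceable laminar model.

Between-animal variation is log-normal with the requested arithmetic
group mean and CV (volumes and counts are positive and CVs reach 0.25; a
Gaussian alternative is exposed). Mutant means are scaled by
`1 + effect`; layer-restricted effects multiply on top. Default cohort
conditions mirror the study: group sizes 9 vs 10 (imaging arm), 7 vs 6
(striatal stereology), 8 vs 6 (cortical immunostaining); volume CVs 0.06
with a −10…−11% caudate-putamen effect; neuron totals with CV 0.14–0.16
and a −20.8% effect; interneuron populations ~10⁴ with CV 0.17 and the
double-labeled deficit concentrated entirely within the layer-V band. An
optional shared log-scale size factor (SD 0.04 in the study replica)
induces positive inter-regional volume correlations; no literature value
is asserted for it. All generators consume one `numpy` Generator; a fixed
seed reproduces cohorts byte-identically.

What the generator does *not* emulate: real mouse-brain shapes and
curvature, staining/penetration artifacts, lost caps and tissue
shrinkage, spatially clustered cells, or correlated marker noise. Passing
tests therefore demonstrate correctness of the estimators under their
design assumptions, not robustness to histological artifacts.

## Stereology

* **Counting frame.** Acceptance is `x ∈ (x₀, x₀+w]`, `y ∈ (y₀, y₀+h]` —
  left/bottom exclusion (with their infinite extensions), top/right
  inclusion. For point references this is equivalent to the classical
  unbiased frame and tiles the plane without loss or double counting.
  Ties are resolved by exact floating-point comparison, no epsilon.
* **Fractionator.** Sections every k-th with random start; an independent
  uniform grid phase per section; frames tile at the step period (a
  residue of exactly zero on a grid node belongs to the lower neighbour's
  inclusion edge, which exists only when the frame spans the full step).
  The height fraction uses the *nominal* 40 µm section thickness;
  shrinkage-corrected thickness is out of scope.
* **Disector.** The z-window is (top, bottom) in µm below the section
  surface — default 5–15 µm, i.e. a 10 µm disector with guard zones —
  counting reference depths in [top, bottom).
* **Nucleator.** n systematically rotated rays (default 4) with a uniform
  random phase; intercepts found by coarse march plus bisection to 1e-9
  relative tolerance, unbiased over the phase for star-shaped profiles.
* **Density estimator.** N = (ΣQ⁻/Σv_dis)·V_ref with V_ref from voxel
  counting of the label volume (how the reference volume was obtained is
  not otherwise constrained). Probes are placed uniformly at random
  within the region profile per layer band, rejecting placements whose
  frame would leave the region so every probe volume lies in tissue.
  Layer-band estimates add up to the whole-region estimate exactly only
  when sampled disector volume per band is proportional to the band's
  reference volume (uniform sampling intensity); otherwise they differ by
  the usual ratio-estimator weighting.
* **Precision.** Cavalieri CE uses the Gundersen–Jensen m = 1 formula,
  CE = √((3A − 4B + C)/240)/Σa with A = Σaᵢ², B = Σaᵢaᵢ₊₁, C = Σaᵢaᵢ₊₂
  and an optional nugget for area-estimation noise. An exactly constant
  sequence is treated as having zero systematic variance by convention
  (the raw covariogram sums carry end-effect terms that are the right
  predictor for smooth profiles but are nonzero even for constants).
  Count CE² = 1/ΣQ⁻ + CE²_SURS(section-wise Q⁻). Group tables report
  CV = SD/mean and mean CE²/CV², the fraction of observed between-animal
  variance attributable to sampling; a healthy design keeps it well
  below 1.

## Morphometry and thickness

Regional volumetry is voxel counting per region and hemisphere (mid-grid
sagittal split by default) with exact roll-ups over the
region → structure → super-group hierarchy. Percent change is
100·(mean_mut − mean_wt)/mean_wt — reductions negative — paired with both
pooled and Welch t-tests. Correlation matrices pool animals across
genotypes (per-genotype matrices by pre-filtering).

Cortical thickness solves Laplace's equation on the cortical ribbon with
Dirichlet boundaries (0 inner, 1 outer, background treated as outer when
no outer label exists) by red–black Gauss–Seidel with over-relaxation
(ω = 1.9) to a maximum-update residual of 1e-5 (configurable).
Streamlines start at outer-boundary voxel centers and are integrated with
RK4 at 0.2 voxel steps along the normalized gradient, both down to the
inner surface and up to the outer; the two half-lengths are summed. On a
64³ concentric-shell phantom (radii 20/28 voxels) thickness is correct
within 1.5 voxel spacings everywhere and the potential matches the
closed form (1/R_in − 1/r)/(1/R_in − 1/R_out) to the discretization
limit — mean absolute error < 0.02, dominated by the jagged voxelized
boundary rather than solver tolerance, and shrinking with resolution.
Group t-maps are pointwise two-sample t-tests on a shared surface point
set, thresholded at uncorrected p < 0.05 by design; no surface
registration is attempted, so group comparisons require phantoms built on
one grid. Streamline step, solver tolerance and the bidirectional
thickness definition are package choices where no standard is fixed.

## Enrichment

Marker gene sets are an input (GMT); the gene universe is always supplied
explicitly (all genes tested for differential expression), never inferred
from set unions. Each set's 2×2 overlap table with the DEG list is tested
with the two-sided Fisher exact test (point-probability method), adjusted
across sets by Benjamini–Hochberg step-up with significance at q < 0.05.
Overlaps are decomposed by sign: the down-regulated fraction is NaN for
empty overlaps, and 1.0 reproduces the "exclusively down-regulated"
pattern expected when a cell population is depleted rather than
transcriptionally regulated. Marker-panel contrasts (e.g. D2⁺ vs D1⁺
MSN markers) treat markers as the test units — a deliberate, flagged
choice, since per-animal marker measurements are often unavailable.

## qPCR

Standard curves regress Cq on log10 relative quantity over a serial
dilution of pooled cDNA (≥3 points spanning ≥2 decades); efficiency is
10^(−1/slope) − 1, and non-monotone dilution series are flagged and
rejected. Reference stability is a NormFinder-style two-level
decomposition re-implemented from its published model (simplified
random-effects on the log scale): after per-sample centering across the
candidate panel, stability² = mean intergroup bias² + mean intragroup
variance/n; the best pair minimizes the stability of the averaged
pseudo-gene. Quantities are normalized to the geometric mean of the best
pair (exactly invariant to per-sample scale factors); group fold changes
are log2 of the ratio of group means of relative quantities — the
standard-curve convention, not per-sample ΔΔCq — gated by Shapiro–Wilk
and tested with pooled and Welch t-tests. No Cq outlier filtering by
default (an optional MAD filter exists behind a flag). The default plate
simulates 0.2-cycle Gaussian Cq noise and 15% biological CV; the
pipeline recovers injected fold changes with |bias| < 5% at the study's
group sizes.

## Statistics

"Student's t-test" is implemented as the pooled-variance two-sided test,
with Welch always co-reported: published p-values for the same contrast
are not always reproducible under a single convention, so both are
printed and labeled. The summary-statistic entry path and the raw-data
path share one closed form, so they agree exactly when summaries come
from the raw data. Two-way ANOVA uses type-II sums of squares
(statsmodels OLS) with the interaction dropped when a design cell has
fewer than two observations; post hoc tables report both Tukey HSD over
cell means and Bonferroni-adjusted pairwise pooled t-tests within layer,
each labeled, because published reports mix the two conventions.
Shapiro–Wilk (Royston approximation, via scipy) gates at p > 0.05, with
3 ≤ n ≤ 50 flagged as the supported range. Pearson matrices are
pairwise-complete with NaN (never silent zeros) for degenerate columns.
Group sizes are always explicit inputs, never hard-coded.

## Problem sizes and tolerances in the test suite

Monte-Carlo checks balance statistical resolution against runtime:
estimator unbiasedness uses 500 SUR replicates on a full-size phantom
(666 016 cells, the study's wild-type mean); effect-recovery uses 200
cohorts with count populations at one tenth of the study total (mean
66 602) and the counting frame enlarged to ≈141 µm square so each animal
still tallies ~300 cells — sampling fractions change, the estimator and
its expectation do not. Recovered mean percent changes are asserted
within 1 (volumes) and 2 (counts) percentage points of the injected
effect, commensurate with the Monte-Carlo standard error at those
replicate counts. Null calibrations (normality gate, t-test, ANOVA,
t-maps) are asserted within binomial error of the nominal 5% level.

## Known limitations

No lost-cap/shrinkage corrections, physical disector pairs, or
number-weighted (3D) nucleator; no atlas registration or Jacobian
morphometry; no multiple-comparison correction across regions or surface
points (uncorrected by design); pSI specificity indices are not computed
from expression profiles — marker sets are consumed, not derived; the
laminar geometry is a planar-band approximation of real cortical layers.
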
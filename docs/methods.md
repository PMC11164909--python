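# Methods

This note documents the models, estimators and design choices behind
`stormquant`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic data does and does not emulate.

## Data model

The unit of data is the localization table: one row per single-emitter blink
event, with coordinates in nm (origin top-left, y down), a 0-based frame
index, a photon count and a per-localization lateral precision. Coordinates
are point locations; the only rasterized objects are masks and rendered
images, which bin points into half-open pixels by
`floor((coord − origin)/pixel_size)`. Region masks (nucleus, cytoplasm) are
binary rasters with a physical pixel size and origin; manually drawn masks,
when available, always override the automatic segmentation.

## Drift correction

Fiducial beads are assumed present in (nearly) every frame and much brighter
than sample emitters. Detection thresholds photons at the 0.99 quantile of
all rows, links candidates to the nearest track whose running mean is within
500 nm, and keeps tracks present in ≥ 90% of frames. Drift is estimated per
200-frame window (4 s at 20 ms exposure) as the mean (optionally median, for
blink-contaminated tracks) of each track's positions relative to that
track's first-window mean, averaged without weights across tracks, placed at
window centers, linearly interpolated per frame, linearly extrapolated
beyond the first/last window centers, and anchored to zero at frame 0. With
the linear end extrapolation the estimate of a steady linear drift is exact
up to noise; windowed estimation cannot follow within-window motion, so for
a random walk with step SD s the residual floor is ≈ s·sqrt(window/6)
(the Brownian-bridge deviation from linear interpolation), about 2.9 nm at
s = 0.5 nm and window = 200. Under the default conditions (3 beads, 10 nm
precision) the window-mean noise adds only ~0.4 nm.

A corollary worth knowing: the *fractional* RMSE reduction for random-walk
drift depends on the walk's realized excursion, which varies several-fold
across seeds even though the residual is at the estimator's floor.

## Nanodomain detection

Detection mirrors the standard SMLM chromatin-cluster chain:

1. **Render**: 10 nm histogram over the mask's bounding box.
2. **DoG**: difference of Gaussians with σ₁ = FWHM_exp/(2√(2 ln 2))/√2 and
   σ₂ = 1.6 σ₁, where FWHM_exp is the expected domain size (default 80 nm in
   the nucleus, 40 nm in the cytoplasm — cytosolic dsDNA nanoclusters run
   ~30–50 nm). σ₁ is the matched-filter scale for a Gaussian blob of the
   expected size.
3. **Seeds**: local maxima inside the mask, at least one expected FWHM
   apart, above mean + 1 SD of the DoG values inside the mask. The
   minimum-distance rule treats seeds closer than one domain width as
   splits; it assumes domains are at least about a domain width apart, which
   holds in the regimes studied here.
4. **Fit regions**: the DoG raster thresholded at mean + 0.5 SD, dilated by
   3σ₁ (so Gaussian tails are captured), connected-component labelled. Each
   component with at least one seed is fitted separately — this keeps each
   EM problem small and stable instead of fitting one giant mixture per
   nucleus.
5. **GMM**: full-covariance EM on the localization coordinates (not raster
   intensities), means initialized at the seeds, covariance eigenvalues
   floored at the squared localization precision, optional uniform
   background component over the fit-region area (off by default).
   Convergence at |Δ log L| < 10⁻⁶·|log L| or 200 iterations.
   Localizations are hard-assigned by maximal responsibility; components
   with < 10 assigned localizations are dropped as noise. Counts are blink
   events — no blink merging is applied, so "localizations per domain"
   counts localized spots, not molecules.

**Size.** Each domain's scalar size is FWHM = 2√(2 ln 2)·(λ₁λ₂)^¼ from the
covariance eigenvalues — the geometric mean of the two eigen-axes, which
preserves the area of the anisotropic Gaussian and is rotation-invariant.
Because the observed spread of a domain is its true spread convolved with
localization error, the mean squared precision of the assigned
localizations is subtracted from the eigenvalues before the reduction
(`deconvolve_precision`, on by default; floored at 1 nm²). At 10 nm
precision this correction is what keeps 45 nm domains from reading ~13%
too large; for 90 nm domains it is a ~1% effect.

**Nearest-neighbor distance.** nnd between domains i, j is
max(0, ‖cᵢ−cⱼ‖ − FWHMᵢ/2 − FWHMⱼ/2): the gap between boundary discs,
zero when discs overlap.

**Colocalization.** A channel-A domain is colocalized when the gap to the
nearest channel-B disc is ≤ `gap_tolerance` (default 0, i.e. touching).
This is a domain-level contact criterion, deliberately simple and swappable;
it is not pixel-overlap (Manders) nor coordinate-based (CBC). Report
direction is A-in-B with A the protein channel, B the DNA channel.

## Statistics

Per-cell values are the statistical units (cells, not domains, are
independent replicates). Two-condition comparisons use the two-tailed
Mann–Whitney U test: exact null distribution when n·m ≤ 400 with no ties,
otherwise the normal approximation with tie and continuity corrections
(the switch is explicit and tested against full enumeration). Associations
use Pearson's product-moment r with a t-transform p-value. The exact test is
slightly conservative at n = 20 per arm (measured type-I error ≈ 0.04 at
α = 0.05 over 1000 null replicates), which is the expected behaviour of a
discrete exact test.

## Synthetic data

The generator emulates the *point-pattern* structure of the experiment, not
its optics: no PSF, no camera frames, no 3-D. One cell is an elliptical
nucleus (default semiaxes 3.5 × 3 µm, lymphocyte scale, in a 20 × 20 µm
field) containing `n_nuclear_domains` isotropic Gaussian domains with
truncated-normal sizes and negative-binomial localization counts
(mean + dispersion; counts are blink events and are overdispersed relative
to Poisson). Draws are truncated at 4σ from the domain center (−0.15%
spread bias) so every localization is attributable to its domain. Optional
periphery bias places a configurable fraction of domains in the
0.8–1.0 normalized-radius ring. Cytosolic nanoclusters (default
30–50 nm, ~60 localizations) are placed in the annulus between the nucleus
and an outer ellipse 2 µm wider; uniform background covers the whole field;
localization precision noise is added independently per localization;
frames are assigned uniformly (a per-emitter geometric run-length blink
model is available); fiducial beads contribute one bright localization per
frame; drift (none/linear/random-walk) translates everything. Ground truth
(true centers, sizes, counts, drift, bead positions) is recorded before
noise.

Defaults (50 domains of 80 ± 10 nm, 200 localizations per domain, 2
background localizations/µm², 10 nm precision, 20,000 frames) were chosen
once as a realistic dSTORM regime; the nuclear totals per cell are not
published quantities and the defaults are tunable, not claims.

**Population coupling.** `simulate_population` jitters each cell's mean
domain size by a latent z ~ N(0, 8 nm) and can couple the cytosolic cluster
count and size to z with a configured Pearson ρ. The latent vectors are
standardized and orthogonalized per arm — the exact-sample construction
familiar from `MASS::mvrnorm(empirical = TRUE)` — so the realized latent
correlation equals ρ instead of fluctuating around it (sampling SD ~0.1 at
100 cells would otherwise dominate recovery tests). The cost is a weak
O(1/n) dependence between cells of an arm; per-cell noise remains
independent.

What passing tests on this generator demonstrate: the detection chain
recovers sizes, counts, spatial statistics and planted couplings without
bias under Gaussian-domain, known-precision conditions. What they do not
demonstrate: robustness to non-Gaussian domain shapes, spatially varying
background, multi-emitter overlap, chromatic misregistration, or
segmentation error on real images — masks here are exact by construction.

## Validation battery sizes

The acceptance battery runs at sizes chosen for minutes-scale runtime on one
CPU: 200 domains for the nnd oracle; all 45 tie-free sample-size pairs with
n + m ≤ 10 for Mann–Whitney enumeration; 100 random rotations for FWHM
invariance; 20,000-frame drift recovery with 3 beads; 30 cells per arm
(40 domains each) for two-arm recovery; 100 cells for each correlation
design; 1000 replicates for the type-I error. Detection recovers per-arm
mean FWHM and localizations per domain to within a few percent of the
configured 90/45 nm and 200-localization truths at these sizes.

## Known limitations

- 2-D only; axial structure is treated as projected.
- The fit-region strategy can merge domains closer than ~one DoG scale;
  the seed minimum distance can under-split genuinely touching domains.
- Colocalization is a binary contact measure; no cross-correlation curves.
- The drift estimator does not handle beads that bleach mid-acquisition
  (presence threshold simply drops them).
- No redundant cross-correlation fallback when zero fiducials are found;
  the error message asks for an external trace instead.
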
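# Methods

This note documents the models, numerical choices and limitations behind
`contourval`, in the order the workflow runs.

## Data model and geometry

A study is a complete cross-product design: every
(subject, rater, structure, method, session) cell holds one binary mask
and one time in minutes.  The default design is 6 subjects × 5 raters ×
5 structures × 2 methods (M = manual, AM = auto-generated then edited) ×
2 sessions = 600 contour records, 150 per contour set (M1, M2, AM1,
AM2).  Manifest validation accepts exactly the full cross-product;
adding or removing any record is an error that names the offending cell.

Masks are 3D binary volumes on regular anisotropic grids.  Array order
is (slice, row, col) = (z, y, x); the spacing tuple uses the same order;
voxel indices are 0-based and the physical coordinate of voxel `v` is
`origin + v·spacing` (voxel-center convention).  NIfTI orientation
beyond per-axis spacing is ignored, and masks to be compared must share
a grid (same shape, spacings equal within 1e-6 mm); they are *never*
resampled, because resampling silently changes both overlap and surface
metrics.  Foreground is any stored value > 0, so the {0,1} and {0,255}
mask dialects load identically.  Timing analyses merge the two femoral
heads into one `femoral_heads` ROI (their times are summed per cell
before any averaging), giving 4 timing ROIs.

## Similarity metrics

**DSC** is `2|A∩B|/(|A|+|B|)`.  Two empty masks raise an error rather
than returning 1: an empty clinical contour is a data defect, not
agreement.  `dice(empty, nonempty)` is 0.

**MDA** is the symmetrized mean surface distance.  The surface of a mask
is the set of foreground voxels with at least one background 6-neighbor
(array edges count as background); 6-connectivity gives the thinnest
standard surface and is what the brute-force test oracle implements.
The directed distance d(A→B) is the mean over A's surface voxel centers
of the Euclidean distance, with anisotropic spacing, to the nearest
surface voxel center of B, computed by evaluating an exact
spacing-aware Euclidean distance transform of B's surface at A's surface
voxels.  MDA is the equal-weight average of the two directed means —
not weighted by surface point counts — so symmetry holds by
construction.  Against an O(n·m) all-pairs nearest-neighbor oracle the
two routes agree to 1e-9.

Because MDA is computed between voxel-center point sets, a level-set
shift of b mm registers as an MDA slightly below b (roughly half a voxel
less, plus the strict-inequality cut of the thresholded signed
distance).  Tests that compare MDA against an analytic offset therefore
use grids fine enough to resolve the shift.

## STAPLE fusion

The inter-observer reference is the binary STAPLE consensus (see the
README for the EM update equations).  Choices, all exposed in
`StapleConfig`:

- initial sensitivities/specificities `p = q = 0.99`;
- foreground prior γ = mean foreground fraction of the rater masks
  within the crop region ("auto"), held fixed across iterations — with γ
  fixed, the EM objective (the observed-data log-likelihood, recorded
  per iteration) is provably non-decreasing, and the pipeline asserts
  this within 1e-9 on every run;
- convergence when the relative change of ΣW drops below 1e-6, cap 100
  iterations;
- consensus = W ≥ 0.5, ties counted as foreground;
- computation restricted to the bounding box of the union of rater
  masks dilated by ceil(10 mm / spacing) voxels per axis.  Without the
  crop, the large empty background dominates γ and the specificity
  estimates — a known STAPLE pitfall.  The margin is configurable;
- per-rater probability products accumulated in log space; `p`, `q`
  clamped to [1e-6, 1−1e-6] each M-step to avoid absorbing states.

References are built per (structure, subject, method, session), giving
four reference families (Ref_M1, Ref_M2, Ref_AM1, Ref_AM2).  Raters are
processed in sorted-id order; the result is invariant to input order.

## Statistical kernels

All tests are two-sided at α = 0.05.  The paired location test applies
the Shapiro–Wilk gate to the paired *differences* (the quantity the
paired t-test assumes normal): gate p ≥ α selects the paired t-test,
otherwise the Wilcoxon signed-rank test.  The gate threshold equals the
test α by default.

Wilcoxon follows the classical convention: zeros dropped, midranks for
ties, statistic = min(W⁺, W⁻).  For n ≤ 25 the two-sided p is exact,
computed by a dynamic program over the 2ⁿ sign assignments on doubled
(hence integer) midranks; the signed-rank distribution is symmetric
about Σranks/2, so the two-sided p doubles the lower tail.  Beyond 25 a
normal approximation with tie correction (−Σ(t³−t)/48 in the variance)
and a 0.5 continuity correction is used; at n = 25 the two routes agree
within 0.02 on seeded data.  The cutoff is an argument, so studies with
n = 30 vectors can force exactness if desired.

McNemar uses only the discordant cells b, c: exact
`p = min(1, 2·Σ_{k≤min(b,c)} C(b+c,k)·2^{−(b+c)})` (binomial sign test),
or `(|b−c|−1)²/(b+c)` on χ²₁ with continuity correction.  Both are
reported in the bias report; for the pooled table (3, 4, 8, 81) they
give 0.3877 and 0.3865, both rounding to 0.39.

Quantiles (quartiles, 5th/95th whiskers, IQR ratio) use linear
interpolation between order statistics — for sorted `x_(1..n)` at level
`t`, `h = (n−1)t`, result `x_(⌊h⌋+1) + (h−⌊h⌋)(x_(⌊h⌋+2) − x_(⌊h⌋+1))`
(numpy's default) — chosen for determinism across implementations and
stated so external oracles can match exactly.  Boxplot summaries flag
points outside the 5th–95th band singly as outliers.

No multiple-testing correction is applied anywhere; the run report
instead records the number of tests performed, so a reader can judge the
multiplicity burden.

Reports carry p-values at full precision in machine outputs and rounded
to 2 decimals (percents to integers, half away from zero) in rendered
tables.

## Timing analysis

Per-rater savings average the whole-pelvis time (the sum of the four
timing-ROI times — an identity the tests check) over subjects and
sessions; per-ROI and pelvis rows average over raters too.  Saving is
`|T_M − T_AM|/T_M`; displayed percents round half away from zero.
Timing consistency runs 16 paired t-tests (t by design, not gated) on
the 30-element rater×subject vectors: M1–M2, AM1–AM2, M1–AM1, M2–AM2
for each timing ROI.  Zero-variance contrasts are flagged per test
rather than aborting the batch.

## Blind-review bias test

Decisions are paired per (rater, subject, ROI).  CONFUSING judgments
and incomplete pairs are excluded and individually identified in the
report (real studies rarely publish how many were dropped; keeping the
identities preserves auditability).  Distractor rows — duplicated
contours inserted into the blind review — are ignored.  The default
bias design uses 4 reviewing raters × 6 subjects × 4 ROIs = 96 pairs.

## Synthetic study generator

The generator stands in for non-shareable patient CTs and defines the
conditions under which the pipeline's guarantees are tested.

**Grid**: 64 slices × 96 × 96 at (3.0, 1.17, 1.17) mm — the anisotropy
of a 512-matrix, 600 mm-FOV CT with 3 mm slices, cropped in-plane so a
600-mask study stays desk-scale.

**Organs**: per-subject blobs `{x : level(x) < 0}` where `level` is a
signed ellipsoid function scaled to ≈mm near the surface plus a
correlated Gaussian deformation field (white noise smoothed by a
Gaussian kernel of the stated correlation length, rescaled to the target
pointwise sd).  Default centers/radii lay out pelvis-scale proportions
(bladder and nodal volume large, rectum elongated cranio-caudally,
femoral heads near-spherical, ~1.5–4 mm deformation amplitude).  With
amplitude 0 the ellipsoid volume matches (4/3)πabc within 5%.

**Observer models** — one per purpose:

- *flip*: i.i.d. voxel noise with per-rater (p, q) — exactly the
  generative model STAPLE assumes, so sensitivity recovery can be
  verified end to end (recovered within ±0.02 at ≥3×10⁴ foreground
  voxels, consensus DSC ≥ 0.98).  AM raters get error rates scaled
  toward perfect by a factor (default 0.5).
- *boundary*: `{x : signed_distance(x) < bias + ε(x)}` with a per-rater
  systematic bias (default −1.5…+1.5 mm, retained across that rater's
  sessions) and a correlated noise field ε (default correlation length
  20 mm) with σ_M = 2.5 mm and σ_AM = 1.25 mm.  Spatially correlated
  boundary noise is how real observer disagreement behaves —
  concentrated where the organ limit is ambiguous.  Editing a proposed
  contour perturbs it less than redrawing, hence σ_AM = σ_M/2 as the
  default directional regime.  Session-to-session variation is a fresh
  field draw with the rater's bias retained.

**Times**: lognormal per timing ROI for M, with default log-means set so
ROI expectations sit at realistic pelvis values (≈4 min bladder/rectum,
≈19 min nodes, ≈9 min femoral heads; log-sd 0.3); AM times are an
independent lognormal draw times a multiplier (default 0.55, the
≈45%-saving regime).  Each femoral head carries half the merged-ROI
time so the per-ROI sum identity holds exactly.

**Decisions**: one four-cell joint draw per (rater, subject, ROI);
default joint (3, 4, 8, 81)/96, the mostly-accepted, mildly-AM-favoring
regime.

**Determinism**: every cell's randomness comes from its own substream,
derived by seeding a generator with the master seed plus CRC-hashed
identity tokens, so regenerating one cell (or extending the design)
never shifts any other cell's realization.

What the generator does *not* emulate: CT intensities, inter-structure
anatomical constraints (organs may overlap), deformable-registration
observer behavior, or learning/fatigue effects in times.  Passing tests
therefore demonstrate the correctness and sensitivity of the *analysis
machinery* under controlled conditions, not the clinical performance of
any particular atlas.

## Problem sizes in the test suite

Unit tests run on masks up to 64³.  The directional end-to-end fixture
uses 3 subjects × 5 raters × 5 structures, single session, 10 seeds —
large enough that the σ_AM = σ_M/2 separation is detected for every
structure in ≥9/10 seeds, small enough for a desk run.  The acceptance
script uses the same scaled study at one seed plus the full default
design for timing and decision analyses.

## Known limitations

- MDA is defined between voxel-center surface point sets; sub-voxel
  surface positions (as mesh-based implementations estimate) are out of
  scope, so absolute MDA values from other tools may differ by a
  fraction of a voxel.
- STAPLE results depend on the crop margin and prior convention;
  commercial implementations that fix γ differently will not be
  bit-identical, though the consensus is stable under these choices for
  well-agreeing raters.
- The manifest requires a complete cross-product; partially collected
  studies must be subset to a complete sub-design first.
- Exact Wilcoxon enumeration is O(n·Σranks) per test and is capped at
  n = 25 by default.
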
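# Methods

## Scope and model of the data

`atpuncta` analyses array-tomography (AT) ribbons: stacks of ultrathin
(70 nm) serial sections, immunolabelled and imaged one section at a
time, then reassembled into a 3D volume whose axial resolution equals
the section thickness. The quantities of interest are the small
pre-synaptic puncta and the larger plaque-associated accumulations of
pre-synaptic proteins (CSPα, synaptophysin) around beta-amyloid (Aβ)
deposits: their densities (objects/mm³), their volume classes, their
object-based co-localization across channels, and how their density
varies with distance from the dense plaque core.

Because the post-mortem imaging data this kind of analysis is run on
are not freely available, the package ships a first-class synthetic
ribbon simulator with complete ground truth. Every analysis stage is
validated against the simulator, not against real images; what that
does and does not establish is discussed at the end.

## Analysis pipeline

1. **Registration** (`register`). Serial sections predominantly
   misalign by in-plane translation during ribbon pickup, so sections
   are aligned by chained pairwise cross-correlation on a reference
   channel (nuclei by default; configurable) and the per-section
   translation is applied to all channels. Integer estimation uses
   masked (overlap-normalized) cross-correlation, which is unbiased by
   content lost at the frame edge under translation — plain phase
   correlation shows occasional 1-px bias there. A sub-pixel mode
   (Fourier upsampling of the correlation peak) exists but is off by
   default: integer shifts are the appropriate model for this
   acquisition. Estimated shifts beyond a sanity bound (default 10% of
   the frame) are clamped with a warning rather than applied blindly.
   Out-of-frame voxels are zero-filled and excluded from the validity
   mask so that densities are normalized by genuinely analysable
   volume only.

2. **Segmentation** (`segment`). Channels are binarized with one or
   more automatic global thresholds whose masks are combined voxelwise.
   The default pair is Otsu (biases high, catches bright objects) and
   Triangle (biases low, catches dim objects), combined by union, so
   both high- and low-intensity synapses are captured. Thresholds are
   global per stack, not per section; per-section thresholds would make
   the persistence rule (below) inconsistent across sections. The
   dense plaque core is segmented with a fixed threshold — by default
   half the Aβ channel's 99.9th intensity percentile, which is robust
   across exposure levels — keeping the largest connected component;
   a diffuse-only plaque yields a "no core" result and distance
   analysis is then refused for that stack.

3. **Persistence filtering** (`segment.persistence_filter`). Any
   connected component whose voxels occupy fewer than two sections is
   removed as a single-section artifact (debris, staining speckle).
   Under 26-connectivity a component's occupied sections are
   necessarily consecutive, so "present in two or more consecutive
   sections" reduces to counting distinct sections. The filter is
   idempotent and never creates voxels.

4. **Quantification** (`quantify`). Objects are 26-connected
   components (26-connectivity suits compact puncta; configurable
   through the labelling structure). Volume is voxel count × pitch² ×
   thickness; no mesh fitting. The equatorial diameter is the diameter
   of the sphere with equal volume, d = (6V/π)^(1/3). Objects below an
   8 μm³ volume gate are excluded from accumulation statistics; gated
   objects are classed as focal spots (V < 50 μm³) or amorphous
   deposits (50–100 and >100 μm³), with half-open [lo, hi) intervals
   and ties going up. Objects with 8 ≤ V < 10 μm³ count as focal
   spots: the gate governs inclusion and 10–50 μm³ is a descriptive
   bin. Co-localization is object-based: an object is co-localized
   with another channel when at least 10% of its voxels fall inside
   that channel's binarized mask, and the summary statistic is the
   percentage of objects so flagged. Intensity-weighted measures
   (Manders, Pearson) are deliberately out of scope.

5. **Distance binning** (`spatial`). Object centroids are assigned to
   10 μm-wide shells around the plaque core (0–10, 10–20, 20–30,
   30–40 μm; half-open; beyond 40 μm is tallied as out of range).
   Distance is measured from the core centroid by default, with an
   edge-based option (distance to the core boundary); both conventions
   appear in the field and neither is asserted as canonical. Counts
   are normalized by each shell's analysable volume, computed by
   counting validity-mask voxels whose distance value falls in the bin
   — not by analytic sphere-shell formulas, because stacks truncate the
   shells, severely so for the outer bins of a shallow ribbon. The
   30–40 μm bin serves as the reference: far enough from the plaque to
   represent non-plaque neuropil. In multi-plaque stacks each object
   is assigned to its nearest core.

6. **Statistics** (`stats`). Responses may be power-transformed toward
   normality: Tukey's ladder of powers (λ scanned over −2…2 in steps
   of 0.025, keeping the λ with the best Shapiro–Wilk statistic) or
   Box–Cox with λ chosen by maximum likelihood or by Guerrero's
   variance-stabilization method (blocks of 2 consecutive values).
   Both require positive data; an explicit shift constant must be
   supplied otherwise and is reported with the result. Normality is
   checked with Shapiro–Wilk (scipy). Group comparisons use a linear
   mixed-effects model, `response ~ fixed + (1 | case)`, with stacks
   nested in cases, fitted by REML through statsmodels' MixedLM.
   Fixed-effect t-tests use Satterthwaite's degrees-of-freedom
   approximation, computed here from the closed-form REML
   log-likelihood of the random-intercept model: df = 2g²/(∇g'A∇g),
   where g(θ) is the contrast's sampling variance as a function of the
   variance components θ = (σ²_case, σ²_resid), ∇g its central-difference
   gradient, and A the inverse of the numerically observed REML
   information. The implementation agrees with lme4/lmerTest to ~5
   significant digits on shared test data (one suite test runs
   lmerTest via Rscript as an independent oracle). Boundary fits
   (between-case variance → 0) are reported with a `singular` flag and
   ordinary-least-squares degrees of freedom, in which case the group
   test coincides with a pooled two-sample t-test. Outliers are
   retained; no multiple-testing correction is applied across bins
   (per-bin reporting), and per-case median aggregation is available
   as an option. "Type III-style" marginal t-tests are reported; for a
   one-way design the ANOVA types coincide.

## Synthetic ribbon simulator

`simulate.simulate_ribbon` renders a four-channel volume (Aβ, CSPα,
synaptophysin, nuclei) on the AT voxel grid (default 0.1 μm lateral
pitch — a convention, as acquisition pitch is instrument-specific — and
0.07 μm section thickness) containing:

- a **plaque**: a dense ellipsoidal core (segmentable by a fixed
  threshold) with an exponentially decaying diffuse halo, or a diffuse
  halo only, or none;
- an **oligomer field** in the Aβ channel, decaying exponentially from
  the core edge and returning to baseline by 20 μm;
- **synaptic puncta**: soft-edged spheres of configurable diameter
  (default 0.5 μm, diffraction-limited scale) at a configurable
  density (default 0.8 objects/μm³, the order of magnitude of human
  cortical neuropil) or fixed count;
- **accumulation populations** per channel: ellipsoids with volumes
  drawn from a three-class mixture over 10–50 / 50–100 / >100 μm³
  (default weights 0.564 : 0.226 : 0.148 rescaled to sum to one, the
  observed partition of CSPα accumulations; log-uniform within class,
  which reproduces the observed per-class mean sizes of ≈25 and
  ≈71 μm³ without further assumptions; the top class is capped at
  330 μm³, the largest object size on record). Radial placement
  follows a truncated normal in distance from the core (default mode
  15 μm, spread 5 μm). In shallow stacks the axial semi-axis is capped
  at 40% of the stack depth and the lateral axes absorb the remaining
  volume, as real deposits extend beyond the imaged ribbon;
- a **co-localization design**: a configured fraction of
  source-channel accumulations receive a co-centred equal-shape
  target-channel partner (voxel overlap ≈ 1), while unpaired objects
  are kept clear of the other channel's objects, so the designed
  fraction is recoverable;
- **misalignment**: independent integer per-section shifts, uniform in
  [−max, +max] px (section 0 anchored), recorded in the ground truth
  so registration can be scored exactly;
- **noise**: additive Gaussian background plus signal-scaled Gaussian
  (a Poisson approximation adequate at moderate photon counts); and
- **speckles**: bright single-section disks, the artifact class the
  persistence filter exists to remove, placed clear of same-channel
  multi-section objects so filter scoring is exact.

Objects are rendered as hard ellipsoidal supports with a narrow linear
intensity roll-off at the rim; the support's voxel count defines the
recorded true volume, so ground truth and voxel-counting measurement
agree by construction. Same-channel accumulations keep a minimum
surface separation (default 1 μm) so that distinct deposits remain
resolvable; this hard-core exclusion intentionally thins crowded
regions and therefore distorts the radial placement law at high
density — the placement-law test disables it (`min_separation_um =
None`). If a drawn volume cannot be placed in a crowded field, the
volume is redrawn: requested counts are always honoured, at the cost
of a slightly lighter upper volume tail in small stacks.

Identical seed and configuration give bit-identical volumes and
ground-truth tables.

## Numerical and design choices

- Axes are (section, row, col) = (z, y, x); all distances are
  anisotropy-corrected using (thickness, pitch, pitch).
- Deterministic object ordering: components are id-ordered by the scan
  position of their minimum voxel index.
- Threshold menu: Otsu, Triangle, Li, Yen, Mean, Isodata
  (scikit-image); constant-intensity volumes yield an empty mask plus
  a warning rather than an arbitrary threshold.
- Satterthwaite derivatives use relative steps of 1e-4 (gradient) and
  1e-3 (Hessian) on the variance scale, with one-sided fallbacks at
  the σ²_case ≥ 0 boundary; non-finite or non-positive df estimates
  fall back to the residual df, and df is capped at n − p.
- Degenerate inputs are contracts, not crashes: single-section stacks
  refuse registration and persistence filtering; "no core" refuses
  distance binning; zero analysed volume refuses density; all-equal
  responses refuse power selection and flag the model fit singular.

## Validation strategy, problem sizes, and limits

The test suite validates each stage against ground truth or against
independent oracles: exhaustive per-voxel reference implementations
(BFS labelling, literal overlap and bin arithmetic) on small random
stacks, a 40-digit decimal evaluation of the equatorial-diameter
closed form, lmerTest for the mixed model, and seeded Monte-Carlo
calibration runs. Calibration experiments use 8 cases × 3 stacks
(group test; 1000 replicates) and 8 stacks × 4 bins (distance
analysis; 200 replicates) at desk-scale stack sizes (up to
512×512×30 voxels), chosen so the full suite completes in minutes.

One documented calibration limit: with three bin contrasts sharing one
reference bin, each tested at α = 0.05, the probability that *all
three* are simultaneously non-significant under the null is bounded
near ~0.88 (the contrasts are correlated at ρ ≈ 0.5; only a
reference-dominated variance structure would push it higher, and that
same structure breaks the homoscedastic model's per-test calibration
because Poisson density noise scales inversely with shell volume).
The per-contrast type-I error is calibrated at ~5%; the joint
"all-non-significant" rate observed is ~0.85 and cannot reach 0.90
without correcting for multiplicity, which the pipeline deliberately
does not do (per-bin reporting; a Holm option would be the remedy if
familywise control were wanted).

What passing these tests shows: the implementation measures what it
claims to measure on data matching its assumptions — rigid integer
misalignment, ellipsoidal objects with compact support, Gaussian-ish
noise, a single dominant plaque core. What it does not show: behaviour
under tissue deformation, section loss or folds, optical PSF blurring
and z-bleed-through, chromatic misregistration, autofluorescence
structure, or densely confluent deposits — none of which the simulator
emulates. Results on real AT ribbons therefore require the usual
visual QC of thresholds and alignments.
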
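# Methods

This note records the models implemented in `caslquant`, the numerical
choices behind them, what the synthetic generators do and do not emulate,
and the design decisions taken where the underlying workflow left them
open.

## Perfusion quantification

### Kinetic model

Absolute CBF is obtained from the one-compartment kinetic model for
continuous/pseudo-continuous labelling:

CBF = 6000 · λ · ΔS · e^(PLD_eff/T1_blood) / (2 α T1′ S_control (1 − e^(−τ/T1′)))

All times enter the expression in seconds; the factor 6000 converts
ml g⁻¹ s⁻¹ to the conventional ml/100 g/min. The model assumes a single
well-mixed tissue compartment, complete label arrival by the end of the
post-labelling delay (single-PLD regime), and decay of the label with
T1_blood during the delay and with tissue T1′ during accumulation. No
arterial-transit-time, dispersion or partial-volume corrections are
applied — the printed one-compartment form is used as-is, with T1′ taken
as the tissue T1 fitted from the inversion-recovery scan (no
perfusion/apparent-T1 correction).

Parameters, units, defaults:

| parameter | meaning | default | unit |
|---|---|---|---|
| τ (`tau`) | labelling duration | 3000 | ms |
| PLD (`pld`) | nominal post-labelling delay | 200 | ms |
| TR (`tr`) | repetition time | 3450 | ms |
| `n_slices` | slices per readout | 5 | — |
| λ (`lambda_bbp`) | blood–brain partition coefficient | 0.89 | ml/g |
| `t1_blood` | arterial blood T1 at 7 T | 1700 | ms |
| α (`alpha`) | labelling efficiency | **no default** | — |
| `fat_suppression_offset` | pre-readout gradient delay | 7 | ms |

α is deliberately left without a default: it is a measured, session-
specific quantity, and silently assuming one would bias every CBF value.
The estimator from the downstream vessel scan is
α = mean over the vessel mask of (control − label)/(2·control), clipped
to (0, 1] — the scan itself defines the measurement; this estimator is the
package's documented choice.

### Slice timing

`PLD_eff(slice) = PLD + offset + (slice − 1)(TR − τ − PLD)/n_slices`,
with 1-based slice numbers in acquisition order. Arrays are indexed
0-based throughout; the +1 conversion happens only where `effective_pld`
is called. The 7 ms fat-suppression offset shifts every slice's delay
additively.

### Surround subtraction

For a strictly alternating control/label series, each label frame is
paired with the mean of its flanking control frames:
ΔS = mean(control_before, control_after) − label, and S_control is that
same mean. A label frame at the series edge (no second flanking control)
uses its single neighbour — the method's edge handling is not prescribed
anywhere, so the single-neighbour rule is the package's convention. The
interleave convention (control first) and the per-frame condition
annotation (baseline vs challenge) are attached at read/simulation time
and never re-inferred downstream.

### Realignment

Frames are registered to the first scan with a 6-parameter rigid
transform (3 translations in mm, 3 rotations in degrees about the volume
centre, applied in physical coordinates so anisotropic voxels are handled
correctly) minimising the mean squared intensity difference over the
valid overlap. Optimisation is Powell search from the identity — adequate
for the small inter-frame motion of a restrained subject; frames that
fail to converge are flagged and retained unresampled. The cost is
evaluated with cubic interpolation (linear interpolation leaves a
~0.2° bias near the optimum at this matrix size) while the final
resampling of the data is linear. Constructed-motion tests recover a
(2, −1, 0)-voxel shift to < 0.1 voxel and a 5° in-plane rotation to
< 0.06°.

### Smoothing

In-plane Gaussian smoothing with FWHM twice the voxel size per axis
(σ = FWHM / (2√(2 ln 2))), no through-slice smoothing. Smoothing is
mask-aware: the map×mask and the mask are smoothed separately and
divided, so voxels at the brain edge are not dragged toward zero.
Convolution uses periodic boundaries, which keeps the normalised kernel
mass exact (the whole-map mean is preserved to machine precision with a
full mask); the in-plane borders of an ASL field of view are background,
so wrap-around mixes only zeros.

## T1 mapping

The three-parameter relaxation model S(TI) = A + B e^(−TI/T1) is fitted
per voxel (the general form is kept; B = −2A is *not* imposed, so
imperfect inversion is absorbed by B). The model is partially linear: for
fixed T1 the optimal (A, B) solve a least-squares system, so a dense
log-spaced T1 grid (~100 points over 60–9000 ms, always including the
multi-start anchors 300/800/1500/3000 ms) locates the global basin
vectorised over voxels, and a bounded Levenberg–Marquardt refinement
(relative tolerance 1e-8) polishes each voxel. The refinement is only
accepted if it does not worsen the grid optimum, which guarantees the
reported residual is ≤ the residual at every multi-start initialisation.
Voxels with a flat signal (no recovery information), |B| ≈ 0, or refined
T1 outside the open window (50, 10000) ms are masked invalid — never
silently zeroed. Signed input is assumed by default (spin-echo IR
reconstructed signed); magnitude data are first passed through polarity
restoration, which flips the sign of samples before the minimum-signal
inversion time. The sample at the minimum itself is left positive, the
one genuinely ambiguous point of the heuristic.

## Cerebrovascular reactivity

%ΔCBF = (CBF_challenge − CBF_baseline)/CBF_baseline × 100, voxelwise.
Baseline voxels below a floor (default 5 ml/100 g/min, far below perfused
tissue) are masked rather than allowed to produce unbounded ratios;
masked voxels are excluded from regional means. Two properties are
asserted numerically: CVR is invariant to any common multiplicative
recalibration of both maps (a wrong global α cancels), and
cvr(a,b) = −cvr(b,a)·(b/a) voxelwise.

The end-to-end recovery check simulates both conditions, quantifies,
averages per condition, smooths in-plane, and maps CVR. Smoothing before
the ratio matters at nonzero noise: a noisy denominator biases the
voxelwise ratio upward by ≈ f·σ²_B/B² (Jensen), which at 1 % frame noise
and 60 repetitions amounts to ~2–3 percentage points in low-CBF regions;
in-plane smoothing suppresses the voxel-level variance and removes the
bias, while being exactly transparent to the noise-free value because the
challenge scales CBF multiplicatively everywhere. Realignment is opt-in
in this check: the simulator injects no motion, so registration is
exercised by its own constructed-motion tests.

## Group statistics

Voxel-based analysis: voxelwise two-sample t (pooled-variance Student by
default, Welch by option — the pooled form matches common graph-software
defaults), Benjamini–Hochberg FDR across in-mask voxels at q = 0.05,
connected-component labelling of surviving voxels (6-neighbour face
connectivity by default, in-plane 8-connectivity by option), and removal
of components smaller than k = 10 voxels. The whole-brain in-mask set is
the multiple-testing family. Region-based analysis: per-region means over
valid voxels (regions with zero valid voxels are flagged missing, not
zeroed), then per-region two-sample tests with BH-FDR across regions.
Longitudinal mixed-effects modelling is intentionally *not*
re-implemented; the module emits tidy long-format tables
(subject/genotype/age/condition/region/bregma_level/value) consumable by
any standard fitting routine.

MAD screening keeps values inside median ± 3 × MAD inclusive, where MAD
is the raw median absolute deviation (no 1.4826 consistency factor — the
literal reading of the rule; the scaled variant is a flag). When more
than half the values coincide the MAD is zero and only values exactly
equal to the median survive; this degenerate behaviour is deliberate and
loud in the docstring. The two-stage aggregation for image-based
measurements screens images within (animal × region), discards an animal
for a region when fewer than 3 images survive, averages, then screens the
per-animal values within each region cell (the grouping cell is
configurable; the default is per region).

## Vessel morphometry

Maximum projection over a fixed depth (default use case: 30 µm of a
z-stack with known spacing), background subtraction by grey opening with
a disk footprint (radius default 50 px, chosen well above vessel
half-widths so vessels drop out of the background estimate while smooth
illumination gradients survive), multi-scale Hessian tubeness (Sato
response, scale-normalised, maximum over scales {1, 2, 4} px — spanning
capillary to arteriole radii at 40× sampling), threshold segmentation,
projected area (pixel count × pixel size²), and skeleton main-axis
length. The skeleton is an 8-connected graph with step weights 1
(orthogonal) and √2 (diagonal) times the pixel size, so lengths are
physical path lengths in µm; the main axis of a component is its graph
diameter (longest geodesic), computed by exhaustive all-pairs Dijkstra up
to 500 skeleton pixels and by the double-sweep heuristic (exact on trees)
above that, with the exact method as the validating oracle in tests.
Skeleton components under 5 pixels are discarded as noise. The headline
"average main-axis length" is the mean of per-component longest paths
within the field of view; per-component values are also emitted.

The threshold is user-defined, as in the interactive workflow. For the
synthetic harness, where no user exists, `footprint_matched_threshold`
plays the user's role operationally: it picks the enhancement threshold
whose segmentation maximises Dice overlap with the half-maximum footprint
of the background-subtracted image — the computational analogue of a
human tracing the visibly bright vessels. No fixed fraction-of-maximum or
Otsu cut tracks the half-maximum footprint across tube widths 2–8 px
(the tubeness response width is set by the filter scale as much as by the
vessel), whereas the footprint-matched rule is width-agnostic. An Otsu
fallback also exists and is labelled as such.

## Synthetic data

The generators emulate the study's acquisitions with known ground truth:

* **ASL series** — interleaved control/label frames (control first,
  120 frames = 60 pairs by default); control = M0, label = M0 − ΔS with
  ΔS from the forward kinetic model evaluated with each slice's PLD_eff
  and S_control = M0 (the steady-state control signal — the quantification
  divides by S_control with no further modelling, so the simulator mirrors
  that). A challenge multiplies CBF by a factor f, making ground-truth CVR
  100(f − 1)%.
* **IR series** — S(TI) = M0 − 2·M0·e^(−TI/T1) per voxel, signed by
  default, with a magnitude option to exercise polarity restoration.
* **Labelling-efficiency pair** — control = M0 everywhere; label =
  M0(1 − 2α) inside a vessel mask.
* **Vessel images** — polyline tubes with Gaussian cross-section
  (width = FWHM) on a background field; ground truth is the exact
  polyline length and the half-width footprint mask.

Noise is additive Gaussian, independent across voxels and frames, with
standard deviation expressed as a fraction of the voxelwise M0 (so
background stays noise-free). The phantom is a stack of nested
rectangular shells (12 regions by default, CBF 30–250 ml/100 g/min,
grey-matter-like T1 1700–1900 ms, uniform M0 = 1000) — fully controlled,
trivially partitioned, and deliberately *not* anatomical. What the
generators do **not** emulate: physiological drift and pulsation, motion,
arterial transit heterogeneity, Rician magnitude noise, partial-volume
mixtures, spatially varying coil sensitivity, vessel branching/curvature
beyond polylines, and depth-dependent microscopy attenuation.
Consequently, a passing round trip demonstrates that the inverse chain is
the exact inverse of the stated forward model under these idealisations —
it validates the implementation, not the model's adequacy on real data.

The noise level (1 % of M0) and S_control magnitude used in the
validation suites are stated synthetic defaults, not values inferred from
the study's raw data (which are not deposited).

## Problem sizes

The validation suites run at deliberately desk-scale sizes chosen as the
package's own test-design choice: a 32×32×5 phantom (matching the 5-slice
protocol geometry), 120-frame series, 500-voxel Monte-Carlo T1
recovery at SNR 50, 20-seed null simulations on 24×24×5 grids, and
20 seeded 220×220 vessel images. All tolerances asserted in
`tests/test_acceptance.py` (noise-free round trips < 1e-6 relative,
regional bias < 3 % at 1 % noise, T1 median error < 2 % at SNR 50,
CVR ± 3 points, morphometry within 10 %) are met at these sizes.

## Known limitations

* Single-PLD quantification only; no transit-time or dispersion modelling.
* Realignment assumes small motion (local search from identity) and
  within-modality intensity constancy.
* The registration-based T1→ASL resampling contract covers rigid motion
  between scans of the same geometry; no nonlinear template normalisation
  (a shared phantom space replaces study-template construction).
* The MAD rule's zero-width degenerate case is strict by design and will
  discard legitimate variation when > 50 % of values tie exactly.
* Skeleton lengths of oblique vessels carry the inherent ~8 % digital
  overestimation of 8-connected chain codes at worst-case angles.
* 3D vessel tracing, diameter estimation and branch statistics are out of
  scope.
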
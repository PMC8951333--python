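# Methods

## Hemodynamic model and analysis chain

The analysis consumes relative perfusion maps (laser speckle contrast
imaging) and oxy-/deoxyhemoglobin concentration-change maps
(multispectral reflectance imaging) as the instrument delivers them;
speckle-contrast computation and spectral unmixing are upstream of this
package. A recording covers occlusion, an intravenous injection during
occlusion, and several hours of reperfusion, sampled at ~1 frame/s.

*Downsampling.* Frames are reduced to one per minute by the
within-minute pixelwise mean (not decimation), which suppresses noise
consistently with reporting one frame per minute. A trailing partial
minute is dropped; event indices map to the minute containing them.
On integer-valued frames the minute means are bit-exact against a
brute-force mean because 60-term integer sums are exactly
representable in double precision.

*Vessel masking.* Large cortical vessels carry flow-independent
specular signal and are excluded from all region statistics. The mask
is the set of pixels above a percentile (default 95) of non-background
intensities of the pre-reperfusion mean map. The percentile rule is
rank-based: exactly the top (100 − q) % of pixels is marked, so the
vessel strips in a phantom must occupy less than that share for full
capture — the default phantom uses ≈3.4 % vessel coverage against the
default q = 95. The threshold value and method tag are recorded in the
output. A constant reference map yields an empty mask with a warning.

*Baseline.* B is the mean over healthy-hemisphere non-vessel pixels of
all downsampled frames strictly before reperfusion. The injection
frame is recorded but does not split the baseline window. Hemisphere
geometry is supplied as a label map (phantom truth or user-drawn);
there is no automatic midline detection.

*Segmentation.* The pre-reperfusion mean map, restricted to
ischemic-hemisphere non-vessel pixels, is classified by the relative
flow r = ref / B: core r < 0.33, penumbra 0.33 ≤ r ≤ 0.70, normal
r > 0.70. The boundary convention (core strictly below, penumbra
closed, normal strictly above) makes the three intervals tile exactly.
Numerically, the comparison is made on the ratio against the threshold
literal rather than on ref against θ·B: the product 0.33 × 100 exceeds
33 by one unit in the last place, which would misclassify a pixel
sitting exactly on the printed boundary; the ratio form preserves the
printed decimal semantics (33.0 at B = 100 is penumbra).

*Core tracking.* Two distinct uses of the 33 % criterion are
implemented, mirroring the two questions asked of the data: static
masks from the pre-reperfusion mean (used for traces) and a dynamic
per-frame re-classification (used to follow core growth/shrinkage).
The vessel mask is applied to the tracked counts as well, for
consistency with the static masks. Fractions are reported relative to
the ischemic-hemisphere non-vessel pixel count.

*Traces.* Per region and signal, the frame means over the static mask
are divided by their own first value, so every trace starts at exactly
1 (the first element is set to 1.0 explicitly to keep the contract
exact under floating-point division). The time axis places reperfusion
at minute 0. Hemoglobin traces use the same multiplicative scaling as
flow, around a nonzero resting level; this treats the published
"changes scaled to start at 1" uniformly across signals, which is the
simplest convention compatible with a ratio-based readout.

## Stereology

Cross-sectional areas are estimated with the classical isotropic 2D
nucleator, â = π · mean(lᵢ²), from intercept lengths lᵢ measured from
an interior point to the boundary. The estimator is unbiased for
regions star-shaped about that point; measurements must assert the
star-shape assumption, and the multi-intercept signed variant for
non-star-shaped regions is deliberately not implemented — infarcts are
treated as star-shaped about an interior point. Both systematic ray
designs (n equally spaced directions with a random rotation; lower
variance, the default) and fully random isotropic designs are offered.
Volumes follow the Cavalieri estimator V = d · Σ aᵢ with section
spacing d in mm (0.6 mm in the emulated sectioning protocol); µm
inputs are converted explicitly at I/O. No shrinkage correction is
applied to areas.

## IHC and homing quantification

"Same settings across a batch" is operationalized as one fixed global
threshold per channel; positive pixels are those strictly above it.
Aggregation order is ROI → region mean per section → section mean per
animal; the extravasation ratio is mean IgG area over mean CD31 area
per region, and per-animal region ratios are normalized to the
healthy-region ratio (healthy ≡ 1). Regions with zero CD31 area are
flagged NaN and excluded from averages. Homing ROIs must share one
area; the homing ratio mean(ischemic ROI means)/mean(healthy ROI
means) is invariant to global positive rescaling of the image, which
is what makes it robust to labeling-efficiency differences between EV
preparations.

## Behavior and EV bookkeeping

The Hargreaves session latency removes exactly one instance of the
maximum and one of the minimum of the five trials (stable under ties,
order-agnostic) and averages the remaining three. Corner-test sessions
are exactly ten L/R outcomes; the statistic is the right-turn
fraction. Neurological scores are integers 0–4; 1–4 counts as
successful occlusion induction. Missing sessions are absent rows,
never imputed.

The hemolysis gate reads "exceeded 0.2" strictly: A₄₁₄ = 0.2 is kept,
and a missing value fails. A subject is retained only when every
timepoint passes. Dose equalization is by dilution only (factors ≥ 1)
down to the subject's lowest-concentration timepoint. Pooling defaults
to equal per-subject particle contributions, capped by the
least-endowed sample (a full-volume mode is available); particle
counts are conserved in both modes. Post-intervention readouts are
divided by the subject's pre-intervention value (pre ≡ 1); subjects
with a zero or missing pre value are excluded with a warning.

## Phantom design

The phantom emulates the geometry and dynamics the analysis must
resolve, not the biophysics: a rectangular two-hemisphere field (96 ×
128 px, 0.08 mm/px) split at a midline column, an elliptical ischemic
core (default 20 % of baseline perfusion) with a penumbral annulus
(50 %), straight bright vessel strips at baseline × 3 irrespective of
the region underneath (so vessel masking is a meaningful step), and
additive Gaussian noise truncated at zero for perfusion (default SD 2,
i.e. 2 % of the baseline of 100 arbitrary units). Recording runs at
1 frame/s for 420 s with occlusion from frame 0, injection at frame
60 and reperfusion at frame 180; after reperfusion each region relaxes
exponentially toward a plateau (defaults 0.6/0.9/1.0 of baseline for
core/penumbra/normal, τ = 40 s — a single-exponential chosen as the
simplest kinetics matching qualitative reperfusion traces).
Hemoglobin phantoms rest at level 1.0 and step to per-region multiples
of it (oxy 1.5/1.2/1.0, deoxy mirrored 0.5/0.8/1.0).

What the phantom does **not** model — speckle statistics, optical
forward models, curved anatomy, motion, spatially correlated noise,
partial-volume effects at region boundaries — bounds what passing
tests show: they validate the analysis logic (thresholding semantics,
masking, scaling, bookkeeping) under controlled conditions, not
robustness to every artifact of real recordings.

## Problem sizes and tolerances

The validation suite uses 20-seed phantom batches for partition and
core-fraction checks (mean absolute recovery error ≤ 0.02 at 2 %
noise; measured ≈ 0.002), 10⁴ isotropic rays for the ellipse nucleator
check (within 2 % of πab), sections at d = r/10 for the sphere
Cavalieri check (within 2 %; midpoint section placement makes the
cylinder exact), 50 seeds for the symmetric homing phantom (mean ratio
within 1 % of 1), and 10⁴ random 5-tuples for the trimmed-mean oracle.
Exact contracts (trace first value, mask partition, noiseless IHC
ratios, particle conservation, dose equality) are asserted to machine
precision.

## Known limitations

Hemisphere geometry must be provided; the vessel thresholding rule is
a configurable percentile stand-in for an unspecified manual
convention; the nucleator assumes star-shaped regions; group-level
hypothesis testing (mixed models, ANOVA, multiple-comparison
corrections) is out of scope and left to standard statistical
packages on the tidy outputs this package produces.
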
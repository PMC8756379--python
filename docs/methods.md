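# Methods

`erkscope` quantifies two kinds of single-cell microscopy readouts from
mammary epithelial cells whose mechanical microenvironment (substratum
stiffness) tunes EGFR/Erk signaling: (1) Erk activity trajectories
reported by a kinase translocation reporter (KTR), and (2) fluorescent
EGF ligand (EGF-488) binding and internalization as sub-resolution
puncta. Because such studies rarely deposit raw imagery, the package
includes ground-truthed synthetic generators that emulate the relevant
signal structure, so every stage can be verified end to end.

## Erk-KTR trajectories

**Model.** The KTR is exported from the nucleus when Erk is active, so
per-cell activity is the background-subtracted cytoplasm-to-nucleus
ratio

    C/N(t) = (I_cyto(t) − I_bg(t)) / (I_nuc(t) − I_bg(t)),

dimensionless and positive. Frames with a non-positive numerator or
denominator are excluded and reported. Background is a user-supplied
scalar or per-frame series (measured in cell-free regions); the package
makes no attempt to choose those regions.

**Smoothing.** A 3-frame moving average (endpoints averaged over the two
available frames) removes frame-to-frame measurement noise. All
downstream statistics (pulses, AUC, fixed-time readouts) operate on
smoothed trajectories by pipeline convention, though the functions
themselves accept any trajectory.

**Pulse detection.** A pulse is a strict local maximum exceeding its
flanking troughs by a relative threshold (default 20 %). The flanking
troughs of a candidate at index *i* are the trajectory minima between
*i* and the neighbouring candidate peaks; series endpoints count as
troughs, otherwise boundary pulses would be undetectable by definition.
The phrase "increase relative to neighboring time points" is ambiguous
about which flank governs; the default `mode="smaller"` calls a pulse
when `cn[i] ≥ 1.2 · min(mL, mR)` (closer to classic peak-finder
selectivity semantics and scale-free), and `mode="larger"` provides the
stricter alternative. Flat-topped plateaus are represented by their
first frame — a deterministic, order-independent tie-break. Reported
prominence is `cn[i]/trough − 1` for the governing trough. Because the
rule is a ratio, pulse calls are invariant under any positive rescaling
of the trajectory; this is property-tested and the detector is checked
for exact agreement against a brute-force implementation on thousands of
short grid-valued trajectories.

**AUC.** The response to a stimulus at time *t₀* is the baseline-
subtracted frame sum `Σ (cn[t] − B)` over frames with stimulus-relative
time in a half-open window, default early `(0, 60]` min and late
`(60, end]` min. The baseline *B* is the windowed mean of C/N within
±10 min of *t₀* (the same ±10-min convention used for all fixed-time-
point readouts). The AUC is deliberately a plain frame sum
(dimensionless·frames), matching the summation convention of the
original analysis; a time-weighted variant (× frame interval) is
available but not default. On noise-free exponential step-decay
trajectories the AUC agrees with its geometric-series closed form to
machine precision.

**Classification.** A cell with ≥ 2 detected pulses is *pulsing*
regardless of mean activity; otherwise it is *on* when its time-averaged
C/N is at least `on_threshold` and *off* below. No canonical numeric
cutoff between "constantly active" and "constantly inactive" exists, so
`on_threshold` is a mandatory parameter with no default — the package
refuses to invent one silently, and logs the chosen value in provenance.

## 3D internalization quantification

Per z-slice, background is estimated as a Gaussian blur (default
σ = 3 px) of that slice and subtracted; negatives are clamped at zero
(non-physical, and they destabilize Otsu). Slices never mix. The
residual image is thresholded (`fixed` AU value, `quantile`, or `otsu`;
the applied threshold is always recorded), 3D connected components are
labelled (default 26-connectivity — a single bright spot spans slices
with diagonal voxel contacts; 6-connectivity available), and objects are
kept when their voxel count lies in `[min_size, max_size]` (defaults
2–200, inclusive). Double-positive filtering retains EGF-channel objects
with any voxel inside the EGFR-channel mask (per-voxel reading of
"doubly positive"); a per-object minimum overlap fraction is exposed for
the stricter per-object reading. The readout is total retained voxel
volume divided by the nucleus count; nuclei are counted from a
max-projected Hoechst-like channel (Otsu + 2D labelling + ≥ 20 px size
filter) unless an explicit count is supplied, which always wins.
Connectivity is lattice-based and ignores voxel anisotropy; calibrated
volumes use the voxel-size product when provided.

The Gaussian σ, intensity threshold and size bounds have no published
values in this analysis class; the defaults here are declared,
config-exposed, provenance-logged choices, not reproductions.

## 2D membrane-binding quantification

Z-stacks are collapsed by maximum-intensity projection (essential for
rounded tissues whose apical surface spans several slices), then
processed with rolling-ball background subtraction (default radius
25 px, via `skimage.restoration.rolling_ball` — the standard
implementation of the eponymous Fiji operation; grayscale opening with a
disk footprint is available as an alternative estimator) followed by a
Gaussian blur (default σ = 1 px; 0 skips). Puncta are detected exactly as
in 3D but with 2D 8-connectivity and area bounds (defaults 2–100 px²).
Each object is assigned to exactly one cell of the segmentation mask —
by default the cell containing its centroid, with a nearest-cell
fallback within 10 px for centroids on background (membrane puncta in
projections often straddle label edges), else the object is dropped and
counted; majority-overlap assignment is an option. Per-condition
summaries report mean, SD, quartiles (linear interpolation between order
statistics — a stated convention, since plotting conventions vary),
min/max, and pairwise fold-changes of means.

## Synthetic data

The generators emulate three qualitative regimes observed across
substratum stiffness — low/flat activity (soft), pulsatile
(intermediate/stiff), constant-on — plus transient and sustained step
responses to stimulation, and the corresponding image phenotypes. No
quantitative per-stiffness distributions (pulse rates, amplitudes) are
published, so the `soft`/`intermediate`/`stiff` presets are documented
qualitative emulations.

**Trajectories.** Clean signal = baseline + regime term; pulses are
symmetric triangular bumps (half-width `pulse_width_frames`, additive
amplitude) at frames drawn from a homogeneous Poisson process
(`pulse_rate_per_hr`), rounded to frames, thinned left-to-right to a
minimum gap of 2× the pulse half-width, and rejected within one
half-width of the series ends — both constraints keep every ground-truth
pulse resolvable, so detector recall is well defined. Step regimes add a
plateau (`response_peak`) or an exponential return to baseline
(`2^(−Δt/half-life)`). Noise is multiplicative lognormal with unit mean
and a configured CV — appropriate for a ratio of positive intensities.
Defaults: 120 frames at 1 min (time-lapse intervals of 1–3 min are
typical), baseline 1.0, rate 4/hr, amplitude 0.5, half-width 3 frames,
CV 0.05.

**Z-stacks.** Non-overlapping disk cells in (y, x); spherical puncta of
radius 2 px rasterized fully inside their cell with centre separation
≥ 2r + 3 so labelling recovers each object individually; an exact
fraction (`round(f·n)`) of puncta is co-positive in the EGFR-like
channel, which also carries a diffuse membrane ring; nuclei are spheres
at cell centres. Background is a level plus linear x-gradient with
Poisson counting noise applied to the background field only, so
zero-background scenes are exactly noise-free and the full 3D chain
recovers ground truth exactly — which is tested.

**Membrane scenes.** Cells form a full Voronoi tessellation (a confluent
epithelium with shared label boundaries) from seeds on a jittered grid,
which keeps cell sizes even for every RNG seed while boundaries stay
irregular. Puncta are disks placed by a greedy pass over a shuffled list
of admissible pixels (inside the cell, clear of image edges, pairwise
separation ≥ 2r + 3) — deterministic per seed and robust where rejection
sampling stalls. With `contact_exclusion`, centres must additionally lie
at least `exclusion_distance_px + 1` from inter-cell boundary pixels;
the one-pixel margin keeps noise-induced sub-pixel centroid shifts of
*detected* objects robustly outside the stated zone. Per-cell counts are
exact by default (`count_mode="exact"`), making area-budget ratios
between conditions exact by construction; Poisson counts are available.

What the generators deliberately omit: optical PSF, photobleaching,
cell motion, segmentation errors, z-dependent attenuation, and
heterogeneous per-cell noise. Passing tests therefore demonstrate the
correctness of the quantification logic under the stated signal model,
not robustness to every real-microscope artifact.

## Numerical and design choices

- Axis order is (z, y, x), 0-based; areas/volumes are px²/px³ with
  optional physical calibration metadata.
- Thresholds are strict (`value > t`); bounds of size filters are
  inclusive.
- All randomness flows from a single top-level integer seed through
  `numpy.random.default_rng`; identical config + seed gives
  byte-identical images and bitwise-identical CSV payloads.
- Every data-derived decision (e.g. Otsu thresholds, nucleus counts,
  dropped-object counts) is echoed into the run's `provenance.json`.
- Problem sizes used by the verification script — 12,000 short
  trajectories for the pulse-rule oracle, 200 cells for pulse recovery,
  1,000 random 4×4×4 masks for the labelling oracle, 25 cells/condition
  at 512×512 px for fold recovery — are chosen as the smallest sets that
  make the statistical checks stable and are stated alongside each
  reported value.

## Known limitations

- The pulse rule's "smaller flank" default is one of two defensible
  readings of the original description; both are implemented, and
  results near threshold can differ between modes.
- `on_threshold` intentionally has no default; population class
  fractions are only comparable across runs sharing the same value.
- Rolling-ball radius, Gaussian sigmas, and intensity/size cutoffs are
  declared defaults, not published constants; absolute puncta areas and
  volumes depend on them (ratios between conditions are much less
  sensitive, as the fold-recovery tests show).
- Nucleus counting assumes well-separated nuclei; clumped nuclei should
  be counted externally and passed explicitly.
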
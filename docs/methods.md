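# Methods

This note records the models, conventions and numerical choices behind
tomopipe, and what its synthetic tests do and do not demonstrate about
real data.

## Geometry and coordinate conventions

All operations share one detector convention: column `j` of an `n_det`-wide
detector maps to the signed ray offset

    t(j) = (j − (n_det − 1)/2 − cor_offset_px) · Δx

with `Δx` the pixel pitch and `cor_offset_px` the horizontal offset of the
rotation axis from the detector centre column, positive rightward.  The
parallel ray at angle θ (degrees, converted explicitly wherever
trigonometry happens) and offset `t` is the line `x cos θ + y sin θ = t`.
Projection stacks are ordered `(angle, vertical, horizontal)`; sinogram
sets are the pure transpose `(vertical_slice, angle, horizontal)`; volumes
are `(z, y, x)` on a square grid of side `n_det`, pixel = detector pitch,
centred on the rotation axis.  Scans cover `[0°, 180°)` half-open by
default, with one extra frame at exactly 180° appended for flip
diagnostics (`ScanConfig.include_final_180`); reconstructions use the
angles actually present, so the near-duplicate 180° frame contributes a
negligible double weight unless it is excluded.

## The four spaces and the standard chain

Each correction runs in the space where its artefact is simple:

1. **detector** — zinger/dead-pixel repair on raw counts (median
   replacement only, never interpolation, so noise is not spread);
2. **projection** — flat/dark normalisation to transmission, monitor
   normalisation, the single-distance phase filter, then the negative log;
3. **sinogram** — ring suppression (static defects are straight vertical
   lines here), centre-of-rotation refinement, centre-of-mass hysteresis
   alignment;
4. **image** — filtered back projection output.

The framework machine-checks only *space* compatibility of a process list;
the scientific ordering within a space is the documented convention above,
deliberately left to the user (a legitimate chain may, e.g., skip ring
removal or insert a custom filter).

## Synthetic data: what is emulated, what is not

Line integrals through ellipse phantoms are exact (closed-form chord
lengths), so every correction can be tested against analytic ground truth.
The simulator composes, in order: exact transmission (with the rotation-axis
offset, a per-row linear rotation-centre shift for in-plane tilt of α
degrees — `(y − (n_rows−1)/2)·tan α` pixels at row y — and per-frame
hysteresis jitter applied exactly in ray geometry), a smooth ±5% parabolic
beam profile, per-column gain stripes, Poisson photon noise at `I0`
incident photons per pixel plus Poisson dark counts, and finally zingers,
dead pixels and vertical drift on the recorded frames.

Default conditions used throughout the tests: 256-column detectors for
registration tasks, `I0 = 10⁴` for the noisy rotation-centre check, ±3 px
uniform jitter for hysteresis, 10%-of-signal column defects for ring
removal, 512 angles × 256 detectors for reconstruction fidelity, and the
2160-row frame height of a full-frame sCMOS tomography detector for the
tilt-geometry check (where 0.05° of in-plane tilt gives
`2160·tan 0.05° = 1.885 ≈ 2` pixels of rotation-centre difference
top-to-bottom).

Not emulated: cone/fan-beam geometry, detector point-spread and optical
distortion, propagation fringes (the phase filter is tested against its own
transfer function, not against wave optics), scintillator afterglow,
beam-hardening, and sample deformation.  Passing tests therefore show that
the corrections invert the injected artefact models exactly or nearly so —
not that those models capture every behaviour of a physical beamline.
A single 2-D phantom is extruded vertically by default; genuinely 3-D
objects (needed for vertical-movement diagnostics to be observable at all)
are modelled as per-row phantom stacks (`sphere_phantom_stack`).

## Corrections: definitions and numerical choices

**Outlier repair.**  A pixel is an outlier when it deviates from its
window median (default 3×3) by more than `outlier_k = 3` robust sigmas,
where the robust sigma is `1.4826 ×` the local MAD **floored at 2% of the
local level**.  The floor is essential: on noiseless smooth projections the
local MAD is ~0 and a literal MAD threshold flags ~12% of pixels at object
edges, while genuine zingers (10× amplitude) deviate by hundreds of percent
— so the floor removes false positives at no sensitivity cost.  Repair
iterates to a fixed point (an adjacent outlier can be shadowed until its
neighbour is repaired), which also makes the operation exactly idempotent.

**Flat/dark.**  `(I − D̄)/(F̄ − D̄)` with per-pixel mean (or median)
reduction of the field stacks, clamped to `[eps, ∞)` with `eps = 10⁻⁶`
(bounding attenuation at ≈13.8, beyond any measurable signal).  Pixels
where `F̄ ≤ D̄` carry no flux information; they are repaired with the
neighbourhood median of the transmission image and counted in metadata.

**Phase filter.**  The single-distance homogeneous-object low-pass
`H(u,v) = 1/(1 + π λ z (δ/β)(u² + v²))` applied to transmission frames
before the log, with frequencies in cycles per unit length on the pixel
grid.  `H(0,0) = 1` and `H ≤ 1`, so in the unpadded (periodic) transform
the frame mean is preserved exactly and no Fourier magnitude grows; the
default reflect padding (half a frame) trades that exactness for
wrap-around mitigation, moving the mean by O(10⁻³) on rough frames.

**Ring suppression.**  An angle-independent column defect survives intact
in the per-column mean over angles `m(x)`.  Defect columns are detected
from the residual of `m` against its 21-column running median — a robust
z-score above 3, with a 95th-quantile floor on the scale so the smooth
profile's own curvature (the sqrt-edges of convex objects) never trips the
flag — and the baseline at flagged columns is rebuilt by linear
interpolation from clean neighbours; the excess is subtracted from every
row.  A plain moving-average residual subtraction was rejected: at any
window it either perturbs clean sinograms by several percent RMS or leaks
1/window of the stripe (e.g. 9.4% RMS / 95.2% at window 21 on a disc).
The robust variant leaves clean sinograms untouched and suppresses a 10%
defect by ≥98%.

**Centre of rotation.**  The 180° frame is flipped horizontally; in a
parallel beam it then equals the 0° frame translated by twice the axis
offset.  The translation is the peak of the FFT cross-correlation of
mean-subtracted, zero-padded frames (rows summed), refined to subpixel by a
three-point parabolic fit; `offset = shift/2`.  Accuracy on noiseless
256-column scans is ≲0.05 px across offsets in [−8, +5.5]; Poisson noise
at `I0 = 10⁴` roughly doubles that — both far inside the 2 px error that
visibly degrades a reconstruction.

**Hysteresis (COM) alignment.**  Per-row centre of mass
`c(θᵢ) = Σⱼ j·p(i,j)/Σⱼ p(i,j)` is fitted with
`a sin θ + b cos θ + c₀` by least squares over the actual scan angles (a
three-parameter fit — amplitude, phase and offset); each row is translated
by `fit(θᵢ) − c(θᵢ)` with linear interpolation, then all rows by
`(n_det−1)/2 − c₀` to centre the rotation axis.  Linear interpolation
preserves mass and first moment on fully supported rows, so the correction
is exact to rounding (residuals ~10⁻¹⁴ px); truncated objects violate the
precondition and are rejected upstream by the positive-mass check only —
non-truncation is a documented user obligation.

**FBP.**  Rows are zero-padded to a power of two ≥ 4×`n_det` and filtered
with the discrete band-limited ramp kernel (`h[0] = 1/2`,
`h[odd n] = −2/(πn)²`, zeros elsewhere; DC bin forced to zero).  Using the
kernel's transform rather than literal `|u|` samples avoids the
low-frequency deficit that loses ~11% of density on large objects; padding
below 4× costs another ~9% through kernel truncation.  Back projection
interpolates each filtered row linearly at `x cos θ + y sin θ + centre +
cor_offset_px` and scales by `π/(2 n_angles)/Δx`, making densities
quantitative in the phantom's units (disc interior recovered to ~3% at 512
angles; verified independently against scikit-image's `iradon`, which
agrees on the recovered density to ~1% once its half-pixel centre
convention is accounted for).  Pixels outside the inscribed circle are
computed but flagged in metadata as outside the reliable field of view.

**Flip diagnostics.**  Global 2-D shift from zero-padded FFT
cross-correlation with separable parabolic refinement; `dy` is reported as
the displacement of the 180° frame's content (positive = sample appears
lower).  The frame is then split into `n_bands = 8` horizontal bands and
per-band horizontal shifts measured the same way; since the per-row shift
is twice the local rotation-centre offset, the least-squares slope `m` of
shift versus row gives `tilt = atan(m/2)` and a top-to-bottom centre
difference of `n_rows·tan(tilt)`.  Default thresholds: 1 px vertical shift
("vertical movement"), 0.02° tilt (flags the 0.05° reference case with
margin), correlation score 0.5 ("possible deformation" — no deformation
field is estimated).

## Process lists and provenance

A process list is `{"steps": [{"plugin": name, "params": {...}}, ...],
"description": ...}` in JSON, embedded verbatim as a string attribute in
HDF5 outputs.  Execution appends one provenance record per step with the
*resolved* parameters (defaults filled in), the package version, timestamp
and space transition.  Because every stochastic operation takes an explicit
seed and no plugin keeps hidden state, replaying the embedded list on the
same input reproduces the stored volume bit-identically — the property the
acceptance script measures as `provenance_replay_max_abs_diff = 0`.

## Problem sizes

The test-suite and acceptance runs use desk-scale sizes chosen to keep the
whole suite in tens of seconds while leaving each effect comfortably
measurable: 64–320 detector columns for unit tests, 256–512 angles/columns
for fidelity checks, and a single 2160-row two-frame scan for the tilt
geometry.  All scale linearly in angles × rows × columns.

## Known limitations

* Single-process, sequential execution; plugins declare their granularity
  (`frame` / `slice` / `global`) so a parallel runner could be added, but
  none is provided.
* COR estimation assumes the 0°/180° pair shows the same rigid object;
  deformation biases it (and lowers the reported score).
* COM alignment requires non-truncated rows with positive mass; attenuation
  sinograms of weakly absorbing objects near zero mass are fragile.
* Ring removal targets isolated defect columns; broad smooth gain drifts
  are left to flat-field correction, and wavelet/regularised variants are
  out of scope.
* Out-of-plane tilt is not quantified; it shows up only as a depressed
  correlation score.
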
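"""Sinogram-space operations: extraction, centre-of-rotation estimation,
ring suppression, and centre-of-mass sine-fit hysteresis alignment.

A point object traces a sine curve in the sinogram, so the per-row (per
angle) centre of mass of a non-truncated sinogram follows
``A sin(theta + phi) + c0`` exactly; deviations from the fitted sine are
per-row translation errors (motor hysteresis), and ``c0`` locates the
rotation axis.  Static detector defects are angle-independent and therefore
perfectly straight vertical lines in the sinogram — removable by subtracting
the high-pass part of the column-mean profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .framework import (
    DataBlock,
    PROJECTION_AXES,
    SINOGRAM_AXES,
    Space,
    TomoError,
)

__all__ = [
    "SineFit",
    "CorEstimate",
    "to_sinograms",
    "to_projections",
    "estimate_cor",
    "remove_rings",
    "com_align",
]


@dataclass
class SineFit:
    """Least-squares sine through the per-angle centre of mass.

    The fitted model at angle theta (radians) is
    ``amplitude * sin(theta + phase) + offset`` — equivalently
    ``a sin(theta) + b cos(theta) + c0`` with amplitude = hypot(a, b),
    phase = atan2(b, a), offset = c0 (detector pixels).
    """

    amplitude: float
    phase: float
    offset: float
    per_angle_residuals: np.ndarray

    def predict(self, angles_deg: np.ndarray) -> np.ndarray:
        theta = np.deg2rad(np.asarray(angles_deg, dtype=float))
        return self.amplitude * np.sin(theta + self.phase) + self.offset


@dataclass
class CorEstimate:
    """Signed centre-of-rotation offset from the detector centre column."""

    offset_px: float
    score: float
    method: str = "flip-register"


def to_sinograms(block: DataBlock) -> DataBlock:
    """Projection stack (angle, vertical, horizontal) -> sinogram set
    (vertical_slice, angle, horizontal).

    A pure axis permutation — no value is recomputed; every element is
    preserved bit-exactly.
    """
    block.require_space(Space.PROJECTION)
    if block.axes != PROJECTION_AXES:
        raise TomoError(f"expected axes {PROJECTION_AXES}, got {block.axes}")
    return block.replace(
        values=np.ascontiguousarray(np.transpose(block.values, (1, 0, 2))),
        space=Space.SINOGRAM,
        axes=SINOGRAM_AXES,
    )


def to_projections(block: DataBlock) -> DataBlock:
    """Inverse permutation of :func:`to_sinograms`."""
    block.require_space(Space.SINOGRAM)
    if block.axes != SINOGRAM_AXES:
        raise TomoError(f"expected axes {SINOGRAM_AXES}, got {block.axes}")
    return block.replace(
        values=np.ascontiguousarray(np.transpose(block.values, (1, 0, 2))),
        space=Space.PROJECTION,
        axes=PROJECTION_AXES,
    )


def _parabolic_peak(c: np.ndarray, k: int) -> float:
    """Refine integer argmax k of a 1-D correlation by a 3-point parabola."""
    if k == 0 or k == len(c) - 1:
        return float(k)
    denom = c[k - 1] - 2.0 * c[k] + c[k + 1]
    if denom == 0:
        return float(k)
    return k + 0.5 * (c[k - 1] - c[k + 1]) / denom


def _xcorr_shift_1d(a: np.ndarray, b: np.ndarray, axis: int = -1) -> tuple[float, float]:
    """Shift s maximising correlation of a with b translated by s along axis.

    Frames are mean-subtracted and zero-padded to twice the axis length so
    the correlation is linear, not circular.  Rows (the other axis) are
    summed, giving a single 1-D correlation over horizontal lags; the peak is
    refined to subpixel by a parabolic fit.  Returns (shift, peak score) with
    score normalised by the frame norms.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a0 = a - a.mean()
    b0 = b - b.mean()
    na, nb = np.linalg.norm(a0), np.linalg.norm(b0)
    if na == 0 or nb == 0:
        raise TomoError("no features to register (zero-variance frame)")
    n = a.shape[axis]
    nfft = 2 * n
    fa = np.fft.rfft(a0, n=nfft, axis=axis)
    fb = np.fft.rfft(b0, n=nfft, axis=axis)
    cc = np.fft.irfft(fa * np.conj(fb), n=nfft, axis=axis)
    if a0.ndim == 2:
        cc = cc.sum(axis=0 if axis in (-1, 1) else 1)
    # Lag ordering: cc[s] = sum a0[x] b0[x - s], s in [-(n-1), n-1] wrapped.
    lags = np.concatenate([np.arange(0, n), np.arange(-n, 0)])
    order = np.argsort(lags)
    cc_sorted = cc[order]
    lags_sorted = lags[order]
    k = int(np.argmax(cc_sorted))
    # _parabolic_peak returns a fractional index; lags are contiguous ints.
    shift = lags_sorted[0] + _parabolic_peak(cc_sorted, k)
    score = float(cc_sorted[k] / (na * nb))
    return float(shift), score


def estimate_cor(
    proj_0deg: np.ndarray, proj_180deg: np.ndarray
) -> CorEstimate:
    """Estimate the rotation-axis offset from a 0°/180° projection pair.

    The 180° frame is flipped horizontally; in a parallel beam the flipped
    frame equals the 0° frame translated by twice the axis offset.  The
    translation is located by normalised cross-correlation with subpixel
    parabolic refinement, and the offset is half of it (positive = axis
    right of the detector centre column).
    """
    a = np.asarray(proj_0deg, dtype=float)
    b = np.asarray(proj_180deg, dtype=float)
    if a.shape != b.shape:
        raise TomoError("0° and 180° frames must have the same shape")
    flipped = b[..., ::-1]
    shift, score = _xcorr_shift_1d(a, flipped, axis=-1)
    offset = shift / 2.0
    n_det = a.shape[-1]
    if abs(offset) >= n_det / 2:
        raise TomoError(f"implausible COR offset {offset:.1f} px")
    return CorEstimate(offset_px=offset, score=score)


def remove_rings(
    block: DataBlock | np.ndarray,
    smooth_window: int = 21,
    flag_k: float = 3.0,
) -> DataBlock | np.ndarray:
    """Suppress straight-line (ring) artefacts via the mean column profile.

    An angle-independent detector defect adds the same offset to one column
    of every sinogram row, so it survives intact in the per-column mean over
    angles ``m(x)`` while genuine object structure averages smooth.  The
    high-pass residual of ``m`` against its ``smooth_window`` running median
    detects defect columns (robust z-score above ``flag_k``, with an
    upper-quantile floor on the scale so the smooth profile's own curvature
    never trips the flag); the baseline at flagged columns is rebuilt by
    linear interpolation from clean neighbours and the excess is subtracted
    from every row.  Stripe-free sinograms therefore pass through unchanged,
    and each row's sum changes by exactly the subtracted residual's sum.
    """
    is_block = isinstance(block, DataBlock)
    sino = np.asarray(block.values if is_block else block, dtype=float)
    n_det = sino.shape[-1]
    if smooth_window % 2 == 0 or smooth_window < 1:
        raise TomoError("smooth_window must be odd and >= 1")
    if smooth_window >= n_det:
        raise TomoError("smooth_window must be smaller than the detector width")

    def _correct2d(s: np.ndarray) -> np.ndarray:
        m = s.mean(axis=0)
        smooth = ndimage.median_filter(m, size=smooth_window, mode="nearest")
        r = m - smooth
        mad = np.median(np.abs(r - np.median(r)))
        scale = max(1.4826 * mad, np.quantile(np.abs(r), 0.95)) + 1e-12
        flagged = np.abs(r) > flag_k * scale
        if not flagged.any() or flagged.all():
            return s.copy()
        cols = np.arange(n_det)
        baseline = np.interp(cols[flagged], cols[~flagged], m[~flagged])
        resid = np.zeros(n_det)
        resid[flagged] = m[flagged] - baseline
        return s - resid[None, :]

    if sino.ndim == 2:
        out = _correct2d(sino)
    else:
        out = np.stack([_correct2d(s) for s in sino])
    if is_block:
        return block.replace(values=out)
    return out


def centre_of_mass_rows(sino: np.ndarray) -> np.ndarray:
    """Per-row centre of mass on the column index grid 0..n_det-1."""
    sino = np.asarray(sino, dtype=float)
    mass = sino.sum(axis=-1)
    if np.any(mass <= 0):
        row = int(np.nonzero(mass <= 0)[0][0])
        raise TomoError(f"row {row} has non-positive total mass")
    j = np.arange(sino.shape[-1])
    return (sino * j).sum(axis=-1) / mass


def fit_sine(com: np.ndarray, angles_deg: np.ndarray) -> SineFit:
    """Least-squares fit of com(theta) = a sin(theta) + b cos(theta) + c0."""
    com = np.asarray(com, dtype=float)
    angles_deg = np.asarray(angles_deg, dtype=float)
    if len(com) != len(angles_deg):
        raise TomoError("centre-of-mass and angle arrays differ in length")
    if len(com) < 3:
        raise TomoError("sine fit needs at least 3 angles")
    theta = np.deg2rad(angles_deg)
    design = np.column_stack([np.sin(theta), np.cos(theta), np.ones_like(theta)])
    coef, *_ = np.linalg.lstsq(design, com, rcond=None)
    a, b, c0 = coef
    fitted = design @ coef
    return SineFit(
        amplitude=float(np.hypot(a, b)),
        phase=float(np.arctan2(b, a)),
        offset=float(c0),
        per_angle_residuals=com - fitted,
    )


def _shift_row_linear(row: np.ndarray, shift: float) -> np.ndarray:
    """Translate a 1-D row by a subpixel amount, linear interp, edge clamp."""
    n = len(row)
    coords = np.clip(np.arange(n) - shift, 0, n - 1)
    lo = np.floor(coords).astype(int)
    hi = np.minimum(lo + 1, n - 1)
    w = coords - lo
    return row[lo] * (1 - w) + row[hi] * w


def com_align(
    block: DataBlock | np.ndarray, angles_deg: np.ndarray | None = None
) -> tuple[DataBlock | np.ndarray, SineFit, np.ndarray]:
    """Correct per-row hysteresis misalignment and centre the rotation axis.

    The centre of mass of each sinogram row is computed, a sine
    ``a sin(theta) + b cos(theta) + c0`` is fitted through it over the actual
    scan angles, and each row is translated (subpixel, linear interpolation)
    so its centre of mass lands on the fitted curve; finally every row is
    shifted by ``(n_det - 1)/2 - c0`` so the fitted rotation centre coincides
    with the sinogram centre.  Rows must be fully supported (object not
    truncated at either detector edge), otherwise centre-of-mass shift
    equivariance — and hence the correction — breaks down.

    Returns ``(corrected, SineFit, per_row_shifts)`` where ``per_row_shifts``
    is the total translation applied to each row, rightward positive.
    """
    is_block = isinstance(block, DataBlock)
    sino = np.asarray(block.values if is_block else block, dtype=float)
    if sino.ndim != 2:
        raise TomoError("com_align expects a single 2-D sinogram (angle, detector)")
    if angles_deg is None and is_block:
        angles_deg = block.angles_deg
    if angles_deg is None:
        raise TomoError("com_align needs the per-row scan angles")

    com = centre_of_mass_rows(sino)
    fit = fit_sine(com, angles_deg)
    centre = (sino.shape[-1] - 1) / 2.0
    fitted = com - fit.per_angle_residuals
    shifts = (fitted - com) + (centre - fit.offset)
    out = np.empty_like(sino)
    for i in range(sino.shape[0]):
        out[i] = _shift_row_linear(sino[i], shifts[i])

    if is_block:
        corrected = block.replace(values=out)
        corrected.meta = dict(corrected.meta)
        corrected.meta["com_align"] = {
            "amplitude": fit.amplitude,
            "phase": fit.phase,
            "offset": fit.offset,
            "shifts_px": shifts.tolist(),
        }
        return corrected, fit, shifts
    return out, fit, shifts
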
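"""Detector- and projection-space corrections.

Order matters: outlier (zinger / dead pixel) repair happens in detector space
on raw counts, flat/dark normalisation converts counts to transmission and
moves the data to projection space, monitor normalisation and the single
distance phase filter act on transmission images, and the negative log
finally yields line-integral attenuation ready for sinogram extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .framework import DataBlock, Space, TomoError

__all__ = [
    "CorrectionOptions",
    "PaganinParams",
    "flat_dark_correct",
    "remove_outlier_pixels",
    "monitor_normalize",
    "neg_log",
    "paganin_filter",
]


@dataclass
class CorrectionOptions:
    """Knobs for outlier repair and flat/dark normalisation.

    outlier_k : flag threshold in robust sigmas (MAD-based).
    window    : odd median-neighbourhood size.
    contrast_floor : lower bound on the robust scale as a fraction of the
        local signal level, so sub-percent smooth structure (curvature at
        object edges in noiseless data) never outcompetes a genuine outlier,
        which deviates by hundreds of percent.
    eps       : transmission clamp floor; bounds attenuation at -ln(eps).
    flat_reduce : 'mean' or 'median' reduction over flat/dark frames.
    """

    outlier_k: float = 3.0
    window: int = 3
    contrast_floor: float = 0.02
    eps: float = 1.0e-6
    flat_reduce: str = "mean"

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if not (0.0 < self.eps < 1.0):
            raise ValueError("eps must be in (0, 1)")
        if self.flat_reduce not in ("mean", "median"):
            raise ValueError("flat_reduce must be 'mean' or 'median'")


@dataclass
class PaganinParams:
    """Single-distance phase filter parameters.

    delta_beta : ratio delta/beta of the (assumed homogeneous) object.
    distance_z : propagation distance (same length unit as wavelength and
                 pixel_size); 0 gives the identity filter.
    wavelength : X-ray wavelength.
    pixel_size : detector pixel pitch.
    pad        : symmetric reflect padding (pixels) applied before the FFT to
                 mitigate wrap-around; None pads by half the frame.
    """

    delta_beta: float
    distance_z: float
    wavelength: float
    pixel_size: float
    pad: int | None = None

    def __post_init__(self) -> None:
        if self.delta_beta <= 0 or self.wavelength <= 0 or self.pixel_size <= 0:
            raise ValueError("delta_beta, wavelength and pixel_size must be > 0")
        if self.distance_z < 0:
            raise ValueError("distance_z must be >= 0")


def _reduce_frames(frames: np.ndarray, how: str) -> np.ndarray:
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        return frames
    return np.median(frames, axis=0) if how == "median" else frames.mean(axis=0)


def flat_dark_correct(
    block: DataBlock,
    flats: np.ndarray | float | None = None,
    darks: np.ndarray | float | None = None,
    options: CorrectionOptions | None = None,
) -> DataBlock:
    """Normalise raw counts to transmission: (I - D) / (F - D), clamped.

    ``flats`` / ``darks`` may be frame stacks, single frames, or scalar
    constants; if omitted they are taken from ``block.meta``.  Pixels where
    the reduced flat does not exceed the reduced dark carry no flux
    information; they are repaired with the neighbourhood median of the
    transmission image and counted in the output metadata
    (``n_degenerate_pixels``).  The result is clamped to ``[eps, inf)`` and
    tagged projection space.
    """
    opts = options or CorrectionOptions()
    if flats is None:
        flats = block.meta.get("flats")
    if darks is None:
        darks = block.meta.get("darks")
    if flats is None or (hasattr(flats, "__len__") and len(flats) == 0):
        raise TomoError("flat_dark_correct needs at least one flat frame or constant")
    if darks is None or (hasattr(darks, "__len__") and len(darks) == 0):
        raise TomoError("flat_dark_correct needs at least one dark frame or constant")

    fbar = _reduce_frames(np.atleast_2d(np.asarray(flats, dtype=float)), opts.flat_reduce)
    dbar = _reduce_frames(np.atleast_2d(np.asarray(darks, dtype=float)), opts.flat_reduce)

    denom = fbar - dbar
    bad = denom <= 0
    if np.all(bad):
        raise TomoError("all pixels degenerate: flat does not exceed dark anywhere")
    safe_denom = np.where(bad, 1.0, denom)

    values = np.asarray(block.values, dtype=float)
    trans = (values - dbar) / safe_denom
    n_bad = int(np.count_nonzero(bad))
    if n_bad:
        # Repair degenerate pixels from their spatial neighbourhood.
        for i in range(trans.shape[0]):
            med = ndimage.median_filter(trans[i], size=opts.window, mode="nearest")
            trans[i] = np.where(bad, med, trans[i])
    trans = np.maximum(trans, opts.eps)

    meta = dict(block.meta)
    meta.pop("flats", None)
    meta.pop("darks", None)
    meta["n_degenerate_pixels"] = n_bad
    return block.replace(values=trans, space=Space.PROJECTION, meta=meta)


def remove_outlier_pixels(
    block: DataBlock | np.ndarray,
    options: CorrectionOptions | None = None,
) -> tuple[DataBlock | np.ndarray, np.ndarray]:
    """Flag and repair zingers / hot / dead pixels per frame.

    A pixel is flagged when it deviates from its local median by more than
    ``outlier_k`` robust sigmas (1.4826 x local median absolute deviation,
    floored at ``contrast_floor`` times the local level so exactly-flat or
    merely smooth neighbourhoods do not flag); flagged pixels are replaced
    by the local median — median replacement, never interpolation, so noise
    is not spread spatially.  Unflagged pixels are returned bit-identical.

    Returns ``(repaired, mask)`` with the boolean outlier mask over frames.
    """
    opts = options or CorrectionOptions()
    is_block = isinstance(block, DataBlock)
    frames = np.asarray(block.values if is_block else block, dtype=float)
    if not np.all(np.isfinite(frames)):
        raise TomoError("remove_outlier_pixels requires finite input")
    single = frames.ndim == 2
    stack = frames[None] if single else frames
    if opts.window > min(stack.shape[1:]):
        raise TomoError("window does not fit in frame")

    repaired = stack.copy()
    mask = np.zeros(stack.shape, dtype=bool)
    for i in range(stack.shape[0]):
        frame = stack[i]
        # Repairing an outlier changes its neighbours' medians, which can
        # expose a previously shadowed outlier (e.g. adjacent zingers);
        # iterate until the detector finds nothing, which also makes the
        # operation exactly idempotent on its own output.
        for _ in range(10):
            med = ndimage.median_filter(frame, size=opts.window, mode="nearest")
            absdev = np.abs(frame - med)
            mad = ndimage.median_filter(absdev, size=opts.window, mode="nearest")
            scale = np.maximum(
                1.4826 * mad, 1e-12 + opts.contrast_floor * np.abs(med)
            )
            flag = absdev > opts.outlier_k * scale
            if not flag.any():
                break
            frame = np.where(flag, med, frame)
            mask[i] |= flag
        repaired[i] = frame

    if single:
        repaired, mask = repaired[0], mask[0]
    if is_block:
        return block.replace(values=repaired), mask
    return repaired, mask


def monitor_normalize(
    block: DataBlock, monitor: np.ndarray | None = None
) -> DataBlock:
    """Scale each projection by mean(monitor) / monitor[i].

    Beam-intensity fluctuations recorded by an upstream monitor (e.g. an ion
    chamber) are divided out so every frame corresponds to the same incident
    flux.  Readings default to ``block.meta['monitor']``.
    """
    if monitor is None:
        monitor = block.meta.get("monitor")
    if monitor is None:
        raise TomoError("monitor_normalize needs monitor readings")
    monitor = np.asarray(monitor, dtype=float)
    n = block.values.shape[0]
    if len(monitor) != n:
        raise TomoError(f"{len(monitor)} monitor readings for {n} projections")
    bad = np.nonzero(monitor <= 0)[0]
    if bad.size:
        raise TomoError(f"non-positive monitor reading at frame {bad[0]}")
    scale = monitor.mean() / monitor
    shape = (n,) + (1,) * (block.values.ndim - 1)
    return block.replace(values=block.values * scale.reshape(shape))


def neg_log(block: DataBlock) -> DataBlock:
    """Transmission -> attenuation line integrals: -ln(value) per pixel."""
    values = np.asarray(block.values, dtype=float)
    if np.any(values <= 0):
        raise TomoError(
            "neg_log received non-positive transmission; upstream clamp violated"
        )
    return block.replace(values=-np.log(values))


def paganin_transfer(shape: tuple[int, int], params: PaganinParams) -> np.ndarray:
    """The low-pass transfer function H(u, v) = 1 / (1 + pi l z (d/b)(u²+v²)).

    Frequencies are in cycles per unit length on the pixel grid; H(0,0) = 1,
    so the frame mean is preserved, and H <= 1 everywhere.
    """
    fy = np.fft.fftfreq(shape[0], d=params.pixel_size)
    fx = np.fft.fftfreq(shape[1], d=params.pixel_size)
    f2 = fy[:, None] ** 2 + fx[None, :] ** 2
    coeff = np.pi * params.wavelength * params.distance_z * params.delta_beta
    return 1.0 / (1.0 + coeff * f2)


def paganin_filter(block: DataBlock, params: PaganinParams) -> DataBlock:
    """Single-distance propagation phase filter on transmission images.

    Each frame is reflect-padded, Fourier-filtered with
    ``1 / (1 + pi * wavelength * distance * (delta/beta) * (u² + v²))``
    and cropped back.  Apply before :func:`neg_log`.  ``distance_z = 0`` is
    the identity.
    """
    frames = np.asarray(block.values, dtype=float)
    single = frames.ndim == 2
    stack = frames[None] if single else frames
    ny, nx = stack.shape[1:]
    pad = params.pad
    if pad is None:
        pad = max(ny, nx) // 2
    py = min(pad, ny - 1) if pad else 0
    px = min(pad, nx - 1) if pad else 0

    h = paganin_transfer((ny + 2 * py, nx + 2 * px), params)
    out = np.empty_like(stack)
    for i in range(stack.shape[0]):
        frame = stack[i]
        if py or px:
            frame = np.pad(frame, ((py, py), (px, px)), mode="reflect")
        filtered = np.fft.ifft2(np.fft.fft2(frame) * h).real
        if py or px:
            filtered = filtered[py : py + ny, px : px + nx]
        out[i] = filtered
    if single:
        out = out[0]
    return block.replace(values=out)
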
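"""Experimental-problem detection from a 0°/180° projection pair.

In a parallel beam, the projection at 180° is the mirror image of the one at
0°: flipping it horizontally and registering it against the first frame
should give the identity.  Any residual transform is diagnostic — a vertical
shift means the sample moved vertically; a horizontal shift measures the
rotation-axis offset; a horizontal shift that varies linearly with detector
row reveals in-plane tilt of the rotation axis; a poor correlation score
suggests sample deformation.  A surprisingly small tilt matters: at 0.05°
the rotation centre differs by about two pixels between the top and bottom
of a 2160-row frame, enough to visibly degrade a reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .framework import TomoError
from .sinogram import _parabolic_peak, _xcorr_shift_1d

__all__ = ["FlipReport", "flip_compare", "estimate_tilt"]

DEFAULT_DY_THRESH_PX = 1.0
DEFAULT_TILT_THRESH_DEG = 0.02
DEFAULT_SCORE_THRESH = 0.5


@dataclass
class FlipReport:
    """Result of registering the flipped 180° projection onto the 0° one.

    dx_px / dy_px     : global shift of the flipped frame (px).
    band_shifts       : per-horizontal-band dx values.
    band_centres_rows : centre row of each band.
    tilt_deg          : in-plane tilt estimated from the band-shift slope.
    centre_diff_px    : rotation-centre difference top-to-bottom row,
                        ``n_rows * tan(tilt)``.
    score             : peak normalised correlation of the global match.
    verdicts          : flagged problems, each with the threshold used.
    """

    dx_px: float
    dy_px: float
    band_shifts: np.ndarray
    band_centres_rows: np.ndarray
    tilt_deg: float
    centre_diff_px: float
    score: float
    verdicts: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "dx_px": self.dx_px,
            "dy_px": self.dy_px,
            "band_shifts": np.asarray(self.band_shifts).tolist(),
            "band_centres_rows": np.asarray(self.band_centres_rows).tolist(),
            "tilt_deg": self.tilt_deg,
            "centre_diff_px": self.centre_diff_px,
            "score": self.score,
            "verdicts": self.verdicts,
        }


def estimate_tilt(
    band_shifts: np.ndarray,
    band_centres_rows: np.ndarray,
    n_rows: int | None = None,
) -> tuple[float, float]:
    """In-plane tilt from per-band horizontal flip shifts.

    The flip shift at row y is twice the rotation-centre offset there, so
    the least-squares slope m of shift vs row gives the tilt as
    ``atan(m / 2)``.  ``centre_diff_px`` is the rotation-centre difference
    across the full frame height, ``n_rows * tan(tilt)``; when ``n_rows`` is
    not given the covered row span is used.
    """
    shifts = np.asarray(band_shifts, dtype=float)
    rows = np.asarray(band_centres_rows, dtype=float)
    if len(shifts) < 2 or len(shifts) != len(rows):
        raise TomoError("estimate_tilt needs >= 2 matching bands")
    if np.ptp(rows) == 0:
        raise TomoError("all band centres coincide; tilt unobservable")
    design = np.column_stack([rows, np.ones_like(rows)])
    (m, _), *_ = np.linalg.lstsq(design, shifts, rcond=None)
    tilt_rad = np.arctan(m / 2.0)
    if n_rows is None:
        n_rows = float(np.ptp(rows))
    centre_diff = n_rows * np.tan(tilt_rad)
    return float(np.rad2deg(tilt_rad)), float(centre_diff)


def _global_shift_2d(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """(dx, dy, score): translation of b best aligning it onto a.

    Full-frame normalised cross-correlation via zero-padded FFT with
    separable 3-point parabolic subpixel refinement of the peak.
    """
    a0 = a - a.mean()
    b0 = b - b.mean()
    na, nb = np.linalg.norm(a0), np.linalg.norm(b0)
    if na == 0 or nb == 0:
        raise TomoError("no features to register (zero-variance frame)")
    ny, nx = a.shape
    fy, fx = 2 * ny, 2 * nx
    cc = np.fft.irfft2(
        np.fft.rfft2(a0, s=(fy, fx)) * np.conj(np.fft.rfft2(b0, s=(fy, fx))),
        s=(fy, fx),
    )
    cc = np.fft.fftshift(cc)
    ky, kx = np.unravel_index(np.argmax(cc), cc.shape)
    dy = _parabolic_peak(cc[:, kx], ky) - fy // 2
    dx = _parabolic_peak(cc[ky, :], kx) - fx // 2
    score = float(cc[ky, kx] / (na * nb))
    return float(dx), float(dy), score


def flip_compare(
    proj_0deg: np.ndarray,
    proj_180deg: np.ndarray,
    n_bands: int = 8,
    dy_thresh_px: float = DEFAULT_DY_THRESH_PX,
    tilt_thresh_deg: float = DEFAULT_TILT_THRESH_DEG,
    score_thresh: float = DEFAULT_SCORE_THRESH,
) -> FlipReport:
    """Flip the 180° projection horizontally and register it onto the 0° one.

    The global 2-D shift (dx, dy) is found by normalised cross-correlation;
    the frames are then split into ``n_bands`` horizontal bands and the
    horizontal shift of each band is measured the same way, yielding the
    tilt estimate via :func:`estimate_tilt`.  Verdicts fire when |dy|
    exceeds ``dy_thresh_px`` (vertical sample movement), |tilt| exceeds
    ``tilt_thresh_deg`` (in-plane tilt) or the correlation score falls below
    ``score_thresh`` (possible sample deformation).
    """
    a = np.asarray(proj_0deg, dtype=float)
    b = np.asarray(proj_180deg, dtype=float)
    if a.shape != b.shape:
        raise TomoError("projection frames must have the same shape")
    if a.ndim != 2:
        raise TomoError("flip_compare expects 2-D frames")
    if n_bands < 2:
        raise TomoError("n_bands must be >= 2")
    n_rows = a.shape[0]
    flipped = b[:, ::-1]

    dx, dy, score = _global_shift_2d(a, flipped)
    # Report dy as the displacement of the 180-degree frame's content
    # relative to the 0-degree frame: +4 means the sample appears 4 rows
    # lower in the later frame.
    dy = -dy

    # Per-band horizontal shifts; vertical drift compensated by the global dy
    # is ignored within bands (bands are wide relative to plausible dy).
    edges = np.linspace(0, n_rows, n_bands + 1).astype(int)
    band_shifts, band_centres = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi - lo < 1:
            continue
        try:
            s, _ = _xcorr_shift_1d(a[lo:hi], flipped[lo:hi], axis=-1)
        except TomoError:
            continue  # featureless band
        band_shifts.append(s)
        band_centres.append((lo + hi - 1) / 2.0)
    band_shifts = np.asarray(band_shifts)
    band_centres = np.asarray(band_centres)

    if len(band_shifts) >= 2:
        tilt_deg, centre_diff = estimate_tilt(band_shifts, band_centres, n_rows)
    else:
        tilt_deg, centre_diff = 0.0, 0.0

    verdicts: list[dict] = []
    if abs(dy) > dy_thresh_px:
        verdicts.append(
            {"problem": "vertical movement", "value": dy, "threshold": dy_thresh_px}
        )
    if abs(tilt_deg) > tilt_thresh_deg:
        verdicts.append(
            {"problem": "in-plane tilt", "value": tilt_deg, "threshold": tilt_thresh_deg}
        )
    if score < score_thresh:
        verdicts.append(
            {"problem": "possible deformation", "value": score, "threshold": score_thresh}
        )

    return FlipReport(
        dx_px=dx,
        dy_px=dy,
        band_shifts=band_shifts,
        band_centres_rows=band_centres,
        tilt_deg=tilt_deg,
        centre_diff_px=centre_diff,
        score=score,
        verdicts=verdicts,
    )
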
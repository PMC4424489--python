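"""Analytic ellipse phantoms, exact parallel-beam sinograms, and a scan
simulator with a catalogue of injectable experimental artefacts.

The simulator emulates a 180° parallel-beam absorption scan: line integrals
through an ellipse phantom are computed in closed form (the chord length of a
ray through an ellipse), converted to transmitted counts via Beer-Lambert with
a flat-field beam profile, and optionally corrupted with the experimental
problems a beamline actually sees — rotation-axis offset, in-plane tilt,
per-projection motor-hysteresis jitter, per-projection vertical drift,
column-gain stripes (ring artefacts), zingers and dead pixels, plus Poisson
photon noise.  Every injected parameter is echoed back in a ``true_params``
record so corrections can be tested against ground truth.

Coordinate convention (shared by all modules): detector column ``j`` maps to
signed ray offset ``(j - (n_det - 1)/2 - cor_offset_px) * det_spacing``,
positive rightward; the rotation axis therefore projects onto detector
coordinate ``(n_det - 1)/2 + cor_offset_px``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np

from .framework import DataBlock, PROJECTION_AXES, Space, TomoError

__all__ = [
    "Ellipse",
    "Phantom",
    "ScanConfig",
    "ArtefactConfig",
    "analytic_sinogram",
    "simulate_scan",
    "inject_artefacts",
    "shepp_like_phantom",
    "off_centre_phantom",
    "sphere_phantom_stack",
]


@dataclass(frozen=True)
class Ellipse:
    """One ellipse of an analytic phantom.

    ``centre`` and ``semi_axes`` are in field-of-view units; ``phi_deg`` is
    the counter-clockwise rotation of the major axis; ``rho`` is the
    attenuation density (per unit length — may be negative for subtractive
    structures).
    """

    centre: tuple[float, float]
    semi_axes: tuple[float, float]
    phi_deg: float = 0.0
    rho: float = 1.0

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if a <= 0 or b <= 0:
            raise ValueError("ellipse semi-axes must be positive")


@dataclass(frozen=True)
class Phantom:
    """A list of ellipses plus the physical field-of-view width."""

    ellipses: tuple[Ellipse, ...]
    field_of_view: float = 1.0

    def __init__(self, ellipses, field_of_view: float = 1.0) -> None:
        object.__setattr__(self, "ellipses", tuple(ellipses))
        object.__setattr__(self, "field_of_view", float(field_of_view))

    def total_mass(self) -> float:
        """Integrated density: sum of rho * pi * a * b over ellipses."""
        return float(
            sum(e.rho * np.pi * e.semi_axes[0] * e.semi_axes[1] for e in self.ellipses)
        )

    def density(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Evaluate the phantom density at points (x, y)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.zeros(np.broadcast(x, y).shape)
        for e in self.ellipses:
            ca = np.cos(np.deg2rad(e.phi_deg))
            sa = np.sin(np.deg2rad(e.phi_deg))
            dx = x - e.centre[0]
            dy = y - e.centre[1]
            u = (ca * dx + sa * dy) / e.semi_axes[0]
            v = (-sa * dx + ca * dy) / e.semi_axes[1]
            out += np.where(u * u + v * v <= 1.0, e.rho, 0.0)
        return out

    def render(self, n: int, det_spacing: float) -> np.ndarray:
        """Rasterise onto an n×n grid centred on the origin (pixel = pitch).

        Row index increases with +y, column with +x, matching the
        reconstruction grid convention.
        """
        c = (n - 1) / 2.0
        coords = (np.arange(n) - c) * det_spacing
        x, y = np.meshgrid(coords, coords)  # y varies with row
        return self.density(x, y)


@dataclass
class ScanConfig:
    """Acquisition geometry and photon statistics of a simulated scan.

    Defaults model a small desk-scale absorption scan: a half-open [0, 180)
    angular range with, by default, one extra frame at exactly 180° appended
    for flip diagnostics (``include_final_180``).
    """

    n_angles: int = 180
    angle_range_deg: tuple[float, float] = (0.0, 180.0)
    n_det: int = 128
    n_rows: int = 8
    det_spacing: float | None = None  # default: field_of_view / n_det
    i0: float = 1.0e4
    n_flats: int = 4
    n_darks: int = 4
    dark_level: float = 20.0
    noise_on: bool = False
    include_final_180: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_angles < 1:
            raise ValueError("n_angles must be >= 1")
        if self.noise_on and self.i0 <= 0:
            raise ValueError("i0 must be positive when noise is on")

    def angles_deg(self) -> np.ndarray:
        lo, hi = self.angle_range_deg
        angles = lo + (hi - lo) * np.arange(self.n_angles) / self.n_angles
        if self.include_final_180:
            angles = np.append(angles, hi)
        return angles


@dataclass
class ArtefactConfig:
    """Injectable experimental artefacts; everything defaults to 'off'.

    cor_offset_px
        Horizontal offset of the rotation axis from the detector centre
        column, in pixels (positive rightward).
    tilt_deg
        In-plane tilt of the rotation axis: detector row ``y`` sees an extra
        rotation-centre offset ``(y - (n_rows-1)/2) * tan(tilt)`` pixels
        (small-angle per-row shift model, keeping the ground truth analytic).
    jitter_px
        Half-width of the uniform per-projection horizontal shift emulating
        translational-motor hysteresis in mapping scans.
    stripe_gains
        Per-column multiplicative gain map (length n_det), the static
        detector defect that becomes a straight line in the sinogram and a
        ring in the reconstruction.
    zinger_rate / zinger_amp
        Poisson rate per pixel of spurious X-ray strikes on the sensor and
        their multiplicative amplitude.
    dead_pixels
        (row, col) detector elements stuck at ``dead_value``.
    vertical_drift_px
        Per-projection vertical shift schedule (length = number of frames),
        emulating vertical sample/stage movement.
    """

    cor_offset_px: float = 0.0
    tilt_deg: float = 0.0
    jitter_px: float = 0.0
    stripe_gains: np.ndarray | None = None
    zinger_rate: float = 0.0
    zinger_amp: float = 10.0
    dead_pixels: tuple[tuple[int, int], ...] = ()
    dead_value: float = 0.0
    vertical_drift_px: np.ndarray | None = None


def _ellipse_projection(
    e: Ellipse, theta_rad: np.ndarray, t: np.ndarray
) -> np.ndarray:
    """Closed-form line integral of one ellipse.

    The ray at angle theta and signed offset t is {(x, y): x cos(theta) +
    y sin(theta) = t}.  Projecting the ellipse onto the ray-normal direction
    gives an interval of half-width s(theta); the chord length through the
    ellipse at offset u from its projected centre is
    2 (a b / s^2) sqrt(s^2 - u^2).
    """
    phi = np.deg2rad(e.phi_deg)
    a, b = e.semi_axes
    # Angle of the ray normal relative to the ellipse axes.
    rel = theta_rad - phi
    s2 = (a * np.cos(rel)) ** 2 + (b * np.sin(rel)) ** 2
    tc = e.centre[0] * np.cos(theta_rad) + e.centre[1] * np.sin(theta_rad)
    u2 = (t - tc) ** 2
    inside = u2 < s2
    out = np.zeros(np.broadcast(theta_rad, t).shape)
    chord = 2.0 * e.rho * a * b / s2 * np.sqrt(np.maximum(s2 - u2, 0.0))
    return np.where(inside, chord, out)


def analytic_sinogram(
    phantom: Phantom,
    angles_deg: np.ndarray,
    n_det: int,
    det_spacing: float,
    cor_offset_px: float = 0.0,
    extra_offset_px: np.ndarray | float = 0.0,
) -> np.ndarray:
    """Exact parallel-beam sinogram of an ellipse phantom.

    Entry (i, j) is the line integral along the ray at angle
    ``angles_deg[i]`` and signed offset
    ``(j - (n_det-1)/2 - cor_offset_px - extra_offset_px[i]) * det_spacing``.
    ``extra_offset_px`` may be scalar or per-angle; it is how tilt (per-row)
    and hysteresis jitter (per-angle) enter the ground truth exactly.

    Returns an (n_angles, n_det) float array.  Rays missing every ellipse
    give 0.
    """
    if det_spacing <= 0:
        raise ValueError("det_spacing must be positive")
    angles_deg = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    theta = np.deg2rad(angles_deg)[:, None]
    centre = (n_det - 1) / 2.0
    offsets_px = np.asarray(extra_offset_px, dtype=float)
    if offsets_px.ndim == 1:
        offsets_px = offsets_px[:, None]
    j = np.arange(n_det)[None, :]
    t = (j - centre - cor_offset_px - offsets_px) * det_spacing
    sino = np.zeros((len(angles_deg), n_det))
    for e in phantom.ellipses:
        sino += _ellipse_projection(e, theta, t)
    return sino


def _beam_profile(n_rows: int, n_det: int) -> np.ndarray:
    """Smooth synthetic flat-field: a gentle 2-D parabolic falloff (±5%)."""
    r = (np.arange(n_rows) - (n_rows - 1) / 2.0) / max(n_rows, 2)
    c = (np.arange(n_det) - (n_det - 1) / 2.0) / max(n_det, 2)
    return (1.0 - 0.1 * r[:, None] ** 2) * (1.0 - 0.1 * c[None, :] ** 2)


def simulate_scan(
    phantom: Phantom | Sequence[Phantom],
    scan: ScanConfig,
    artefacts: ArtefactConfig | None = None,
) -> tuple[DataBlock, np.ndarray, np.ndarray, dict]:
    """Simulate a parallel-beam absorption scan with injected artefacts.

    ``phantom`` is either one :class:`Phantom`, extruded along the vertical
    axis (every detector row sees the same 2-D object, apart from
    tilt-induced per-row rotation-centre shifts), or a stack of ``n_rows``
    phantoms giving each detector row its own cross-section (a genuinely
    3-D object — needed e.g. to make vertical sample movement observable).
    Per-frame counts are
    ``I0 * exp(-line integral) * beam_profile * stripe_gains``,
    Poisson-sampled when ``noise_on`` with the configured seed, plus
    ``dark_level``; zingers, dead pixels and vertical drift are applied last.

    Returns ``(raw DataBlock in detector space, flats, darks, true_params)``
    where ``true_params`` echoes every injected artefact for recovery tests.
    """
    art = artefacts or ArtefactConfig()
    rng = np.random.default_rng(scan.seed)
    angles = scan.angles_deg()
    n_frames = len(angles)
    n_rows, n_det = scan.n_rows, scan.n_det
    if isinstance(phantom, Phantom):
        row_phantoms: list[Phantom] | None = None
        fov = phantom.field_of_view
    else:
        row_phantoms = list(phantom)
        if len(row_phantoms) != n_rows:
            raise TomoError(
                f"phantom stack has {len(row_phantoms)} entries for "
                f"{n_rows} detector rows"
            )
        fov = row_phantoms[0].field_of_view
    spacing = scan.det_spacing
    if spacing is None:
        spacing = fov / n_det

    if art.tilt_deg != 0.0 and n_rows == 1:
        warnings.warn("in-plane tilt is unobservable with a single detector row")

    jitter = np.zeros(n_frames)
    if art.jitter_px != 0.0:
        jitter = rng.uniform(-art.jitter_px, art.jitter_px, size=n_frames)

    tan_tilt = np.tan(np.deg2rad(art.tilt_deg))
    row_centre = (n_rows - 1) / 2.0
    row_cor = (np.arange(n_rows) - row_centre) * tan_tilt  # extra COR per row

    # Exact transmission per frame: rays shifted by COR + tilt(row) + jitter.
    theta = np.deg2rad(angles)[:, None, None]
    centre = (n_det - 1) / 2.0
    offsets = art.cor_offset_px + jitter[:, None, None] + row_cor[None, :, None]
    t = (np.arange(n_det)[None, None, :] - centre - offsets) * spacing
    line_integrals = np.zeros((n_frames, n_rows, n_det))
    if row_phantoms is None:
        for e in phantom.ellipses:
            line_integrals += _ellipse_projection(e, theta, t)
    else:
        for y, ph in enumerate(row_phantoms):
            for e in ph.ellipses:
                line_integrals[:, y, :] += _ellipse_projection(
                    e, theta[:, 0, :], t[:, y, :]
                )
    transmission = np.exp(-line_integrals)

    profile = _beam_profile(n_rows, n_det)
    gains = np.ones(n_det) if art.stripe_gains is None else np.asarray(art.stripe_gains)
    flat_signal = scan.i0 * profile * gains[None, :]
    clean = transmission * flat_signal[None, :, :]

    def _counts(expected: np.ndarray, n: int) -> np.ndarray:
        stack = np.broadcast_to(expected, (n,) + expected.shape).astype(float)
        if scan.noise_on:
            stack = rng.poisson(stack).astype(float)
            stack += rng.poisson(scan.dark_level, size=stack.shape)
        else:
            stack = stack + scan.dark_level
        return stack

    flats = _counts(flat_signal, scan.n_flats) if scan.n_flats else np.empty((0, n_rows, n_det))
    darks = (
        _counts(np.zeros((n_rows, n_det)), scan.n_darks)
        if scan.n_darks
        else np.empty((0, n_rows, n_det))
    )

    if scan.noise_on:
        frames = rng.poisson(clean).astype(float)
        frames += rng.poisson(scan.dark_level, size=frames.shape)
    else:
        frames = clean + scan.dark_level

    # Post-hoc artefacts: zingers, dead pixels, vertical drift.
    post = ArtefactConfig(
        zinger_rate=art.zinger_rate,
        zinger_amp=art.zinger_amp,
        dead_pixels=art.dead_pixels,
        dead_value=art.dead_value,
        vertical_drift_px=art.vertical_drift_px,
    )
    frames, post_truth = inject_artefacts(frames, post, seed=scan.seed + 1)

    true_params = {
        "cor_offset_px": art.cor_offset_px,
        "tilt_deg": art.tilt_deg,
        "jitter_px": jitter.tolist(),
        "stripe_gains": gains.tolist(),
        "zinger_pixels": post_truth["zinger_pixels"],
        "dead_pixels": [list(p) for p in art.dead_pixels],
        "vertical_drift_px": post_truth["vertical_drift_px"],
        "angles_deg": angles.tolist(),
        "i0": scan.i0,
        "dark_level": scan.dark_level,
        "det_spacing": spacing,
        "seed": scan.seed,
    }

    block = DataBlock(
        values=frames,
        space=Space.DETECTOR,
        axes=PROJECTION_AXES,
        angles_deg=angles,
        pixel_size=spacing,
        meta={
            "title": "simulated parallel-beam absorption scan",
            "flats": flats,
            "darks": darks,
            "true_params": true_params,
        },
    )
    return block, flats, darks, true_params


def _shift_rows_linear(frame: np.ndarray, shift: float, axis: int) -> np.ndarray:
    """Shift a 2-D frame by a subpixel amount along one axis, edge-clamped."""
    n = frame.shape[axis]
    coords = np.arange(n) - shift
    coords = np.clip(coords, 0, n - 1)
    lo = np.floor(coords).astype(int)
    hi = np.minimum(lo + 1, n - 1)
    w = coords - lo
    if axis == 1:
        return frame[:, lo] * (1 - w)[None, :] + frame[:, hi] * w[None, :]
    return frame[lo, :] * (1 - w)[:, None] + frame[hi, :] * w[:, None]


def inject_artefacts(
    frames: np.ndarray,
    artefacts: ArtefactConfig,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Corrupt a clean count stack (frames, rows, cols) in place-order:
    stripe gains, horizontal jitter, vertical drift, zingers, dead pixels.

    Deterministic given ``seed``; the all-off config is the identity.
    Returns the corrupted stack and a record of what was injected.
    """
    frames = np.asarray(frames, dtype=float)
    if not np.all(np.isfinite(frames)):
        raise TomoError("inject_artefacts requires finite input counts")
    n_frames, n_rows, n_det = frames.shape
    rng = np.random.default_rng(seed)
    out = frames.copy()

    if artefacts.stripe_gains is not None:
        out *= np.asarray(artefacts.stripe_gains)[None, None, :]

    jitter = np.zeros(n_frames)
    if artefacts.jitter_px != 0.0:
        jitter = rng.uniform(-artefacts.jitter_px, artefacts.jitter_px, n_frames)
        for i in range(n_frames):
            out[i] = _shift_rows_linear(out[i], jitter[i], axis=1)

    drift = artefacts.vertical_drift_px
    if drift is not None:
        drift = np.asarray(drift, dtype=float)
        if len(drift) != n_frames:
            raise TomoError(
                f"vertical_drift_px has length {len(drift)}, expected {n_frames}"
            )
        for i in range(n_frames):
            if drift[i] != 0.0:
                out[i] = _shift_rows_linear(out[i], drift[i], axis=0)

    zinger_pixels: list[list[int]] = []
    if artefacts.zinger_rate > 0.0:
        mask = rng.random(out.shape) < artefacts.zinger_rate
        out[mask] *= artefacts.zinger_amp
        zinger_pixels = np.argwhere(mask).tolist()

    for r, c in artefacts.dead_pixels:
        if not (0 <= r < n_rows and 0 <= c < n_det):
            raise TomoError(f"dead pixel ({r}, {c}) outside frame ({n_rows}, {n_det})")
        out[:, r, c] = artefacts.dead_value

    truth = {
        "jitter_px": jitter.tolist(),
        "vertical_drift_px": None if drift is None else np.asarray(drift).tolist(),
        "zinger_pixels": zinger_pixels,
        "dead_pixels": [list(p) for p in artefacts.dead_pixels],
    }
    return out, truth


def shepp_like_phantom(field_of_view: float = 1.0) -> Phantom:
    """A small head-like test object: skull shell, brain, two inclusions.

    Not the classical published parameter set — just a convenient asymmetric
    multi-density object for exercising reconstruction and diagnostics.
    """
    f = field_of_view
    return Phantom(
        [
            Ellipse((0.0, 0.0), (0.42 * f, 0.36 * f), 0.0, 1.0),
            Ellipse((0.0, 0.0), (0.38 * f, 0.32 * f), 0.0, -0.6),
            Ellipse((0.1 * f, 0.08 * f), (0.07 * f, 0.04 * f), 30.0, 0.4),
            Ellipse((-0.08 * f, -0.1 * f), (0.05 * f, 0.05 * f), 0.0, 0.5),
        ],
        field_of_view=f,
    )


def sphere_phantom_stack(
    n_rows: int,
    radius: float = 0.35,
    centre: tuple[float, float] = (0.08, 0.0),
    rho: float = 1.0,
    field_of_view: float = 1.0,
) -> list[Phantom]:
    """Per-row cross-sections of an off-centre sphere: a genuinely 3-D
    object whose projections vary with detector row.

    The sphere spans the vertical field of view; rows outside it see an
    empty phantom.  Use with :func:`simulate_scan` when vertical structure
    matters (vertical-movement diagnostics, tilt with realistic objects).
    """
    f = field_of_view
    rows = []
    for y in range(n_rows):
        z = (y - (n_rows - 1) / 2.0) / n_rows * f
        r2 = (radius * f) ** 2 - z**2
        if r2 <= 0:
            rows.append(Phantom([], field_of_view=f))
        else:
            r = np.sqrt(r2)
            rows.append(
                Phantom(
                    [Ellipse((centre[0] * f, centre[1] * f), (r, r), 0.0, rho)],
                    field_of_view=f,
                )
            )
    return rows


def off_centre_phantom(field_of_view: float = 1.0) -> Phantom:
    """Two well-separated discs, deliberately asymmetric.

    Useful for registration-based diagnostics, where a centred symmetric
    object would make the 0°/180° flip comparison degenerate.
    """
    f = field_of_view
    return Phantom(
        [
            Ellipse((0.12 * f, 0.05 * f), (0.1 * f, 0.14 * f), 20.0, 1.0),
            Ellipse((-0.15 * f, -0.08 * f), (0.08 * f, 0.06 * f), -10.0, 0.7),
        ],
        field_of_view=f,
    )
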
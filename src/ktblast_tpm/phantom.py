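"""Dynamic short-axis left-ventricle phantom with velocity-encoded image formation.

The phantom is an annular myocardium around a (black-blood suppressed) blood
pool on a static-tissue background.  Ground-truth motion is prescribed by two
smooth periodic waveforms — radial (positive toward the blood-pool centroid,
i.e. systolic contraction positive) and longitudinal (through-plane, positive
toward the apex).  Each waveform is a sum of two opposite-signed raised-cosine
(Hann) pulses, one systolic and one diastolic, plus a baseline constant that
makes the cycle integral of velocity exactly zero (periodic displacement).

Velocity encoding follows the simple referenced 4-point scheme of tissue
phase mapping: a reference segment plus one segment per spatial direction,
each velocity component mapped to image phase as ``pi * v / VENC``.  A linear
background phase plane (eddy-current surrogate) is applied to the
velocity-encoded segments only; the reference segment carries zero phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

import numpy as np

__all__ = [
    "MotionModel",
    "PhantomGeometry",
    "PhantomCine",
    "EncodedCine",
    "velocity_waveform",
    "build_phantom",
    "encode_velocity",
    "DEFAULT_MAGNITUDES",
]

Direction = Literal["radial", "longitudinal"]

#: Relative magnitudes of the tissue classes in the (noise-free) modulus image.
DEFAULT_MAGNITUDES: Mapping[str, float] = {
    "myocardium": 1.0,
    "static": 0.7,
    "blood": 0.05,  # black-blood saturation leaves a small residual
    "air": 0.1,
}


@dataclass
class MotionModel:
    """Peak velocities (cm/s) and timing (fractions of the cardiac cycle).

    Systolic and diastolic peaks must carry opposite signs per direction.
    Default amplitudes are of the order of healthy in-vivo myocardial
    velocities; they are generator defaults, not measured ground truth.
    """

    peak_radial_sys: float = 3.5
    peak_radial_dias: float = -3.0
    peak_long_sys: float = 8.0
    peak_long_dias: float = -7.0
    t_sys_peak: float = 0.15
    t_dias_peak: float = 0.55
    pulse_width: float = 0.18

    def __post_init__(self) -> None:
        if not 0 < self.pulse_width < 0.5:
            raise ValueError("pulse_width must lie in (0, 0.5) cycle fractions")
        for s, d in ((self.peak_radial_sys, self.peak_radial_dias),
                     (self.peak_long_sys, self.peak_long_dias)):
            if s * d > 0:
                raise ValueError("systolic and diastolic peaks must have opposite signs")
        for t in (self.t_sys_peak, self.t_dias_peak):
            if not 0 <= t < 1:
                raise ValueError("peak times must lie in [0, 1)")
        # non-overlapping pulses keep the peak values exact by construction
        gap = abs((self.t_dias_peak - self.t_sys_peak + 0.5) % 1.0 - 0.5)
        if gap < self.pulse_width:
            raise ValueError("systolic and diastolic pulses overlap")

    def peaks(self, direction: Direction) -> tuple[float, float]:
        if direction == "radial":
            return self.peak_radial_sys, self.peak_radial_dias
        if direction == "longitudinal":
            return self.peak_long_sys, self.peak_long_dias
        raise ValueError(f"unknown direction {direction!r}")


def _hann_pulse(t_frac: np.ndarray, center: float, width: float) -> np.ndarray:
    """Periodic unit-amplitude raised-cosine pulse centred at ``center``."""
    d = (np.asarray(t_frac, dtype=float) - center + 0.5) % 1.0 - 0.5
    return np.where(np.abs(d) < width / 2, 0.5 * (1.0 + np.cos(2 * np.pi * d / width)), 0.0)


def _baseline_constant(p_sys: float, p_dias: float, width: float) -> float:
    # Solve for C with pulse amplitudes a = peak - C so that the cycle mean
    # (a_sys + a_dias) * width/2 + C vanishes while peaks stay exact.
    return -width * (p_sys + p_dias) / (2.0 * (1.0 - width))


def velocity_waveform(
    t_frac: float | np.ndarray,
    m: MotionModel,
    direction: Direction,
    venc_cm_s: float = 30.0,
) -> np.ndarray:
    """Ground-truth velocity (cm/s) at cycle fraction(s) ``t_frac``.

    Smooth (C1), periodic, with exactly one systolic and one diastolic
    extremum at the configured times and an exactly zero cycle integral.
    """
    p_sys, p_dias = m.peaks(direction)
    if max(abs(p_sys), abs(p_dias)) >= venc_cm_s:
        raise ValueError("configured peak velocity reaches or exceeds VENC")
    c = _baseline_constant(p_sys, p_dias, m.pulse_width)
    a_sys, a_dias = p_sys - c, p_dias - c
    t = np.asarray(t_frac, dtype=float)
    v = (
        a_sys * _hann_pulse(t, m.t_sys_peak, m.pulse_width)
        + a_dias * _hann_pulse(t, m.t_dias_peak, m.pulse_width)
        + c
    )
    return v


def _radial_displacement_cm(m: MotionModel, rr_ms: float, n_grid: int = 8192):
    """Cumulative radial displacement (cm) over one cycle on a fine grid."""
    tg = np.arange(n_grid + 1) / n_grid
    v = velocity_waveform(tg, m, "radial")
    dt_s = (rr_ms / 1000.0) / n_grid
    disp = np.concatenate([[0.0], np.cumsum((v[1:] + v[:-1]) / 2.0) * dt_s])
    return tg, disp


@dataclass
class PhantomGeometry:
    """Annulus geometry in pixels; ``None`` radii scale with the matrix."""

    center: tuple[float, float] | None = None
    r_inner_px: float | None = None
    r_outer_px: float | None = None

    def resolved(self, matrix: tuple[int, int]) -> "PhantomGeometry":
        ny, nx = matrix
        c = self.center if self.center is not None else ((ny - 1) / 2.0, (nx - 1) / 2.0)
        scale = min(ny, nx)
        r_in = self.r_inner_px if self.r_inner_px is not None else 0.095 * scale
        r_out = self.r_outer_px if self.r_outer_px is not None else 0.16 * scale
        if not 0 < r_in < r_out:
            raise ValueError("need 0 < r_inner < r_outer")
        return PhantomGeometry(center=c, r_inner_px=r_in, r_outer_px=r_out)


@dataclass
class PhantomCine:
    """Ground-truth dynamic phantom: per-phase masks and 3-component velocity.

    ``velocity`` has shape (n_phases, 3, ny, nx) with components ordered
    (row, column, through-plane) in cm/s; the through-plane component is
    positive toward the apex.  ``static_mask`` is time-invariant and velocity
    is exactly zero there.
    """

    n_phases: int
    matrix: tuple[int, int]
    pixel_mm: tuple[float, float]
    myo_mask: np.ndarray
    blood_mask: np.ndarray
    static_mask: np.ndarray
    velocity: np.ndarray
    centroid: tuple[float, float]
    times_frac: np.ndarray
    rr_ms: float
    motion: MotionModel


def build_phantom(
    geometry: PhantomGeometry | None = None,
    motion: MotionModel | None = None,
    n_phases: int = 20,
    matrix: tuple[int, int] = (128, 128),
    times_frac: np.ndarray | None = None,
    rr_ms: float = 1000.0,
    pixel_mm: tuple[float, float] = (2.0, 2.0),
) -> PhantomCine:
    """Construct the dynamic annular phantom.

    The myocardial annulus translates radially with the integral of the
    radial waveform (wall thickness preserved); the per-pixel in-plane
    velocity is the radial waveform times the unit vector toward the blood
    pool centroid, and the through-plane component is the longitudinal
    waveform, uniform over the annulus.
    """
    if n_phases < 2:
        raise ValueError("n_phases must be >= 2")
    if motion is None:
        motion = MotionModel()
    geom = (geometry or PhantomGeometry()).resolved(matrix)
    ny, nx = matrix
    if times_frac is None:
        times_frac = np.arange(n_phases) / n_phases
    times_frac = np.asarray(times_frac, dtype=float)
    if times_frac.shape != (n_phases,):
        raise ValueError("times_frac must have length n_phases")

    rows = np.arange(ny)[:, None] * np.ones((1, nx))
    cols = np.ones((ny, 1)) * np.arange(nx)[None, :]
    cy, cx = geom.center
    rho = np.hypot(rows - cy, cols - cx)
    with np.errstate(invalid="ignore", divide="ignore"):
        u_row = np.where(rho > 0, (cy - rows) / np.maximum(rho, 1e-12), 0.0)
        u_col = np.where(rho > 0, (cx - cols) / np.maximum(rho, 1e-12), 0.0)

    tg, disp_cm = _radial_displacement_cm(motion, rr_ms)
    disp_px_t = np.interp(times_frac, tg, disp_cm) * 10.0 / pixel_mm[0]

    r_out_max = geom.r_outer_px + np.max(np.abs(disp_px_t)) + 0.5
    ring_out = r_out_max + 6.0
    if ring_out >= min(cy, cx, ny - 1 - cy, nx - 1 - cx):
        raise ValueError("phantom geometry (annulus + static ring) overflows the matrix")
    static_mask = (rho >= r_out_max + 2.0) & (rho <= ring_out)

    myo = np.zeros((n_phases, ny, nx), dtype=bool)
    blood = np.zeros_like(myo)
    vel = np.zeros((n_phases, 3, ny, nx), dtype=float)
    v_rad = velocity_waveform(times_frac, motion, "radial")
    v_long = velocity_waveform(times_frac, motion, "longitudinal")
    for t in range(n_phases):
        # positive radial velocity = toward centroid = contraction
        r_in = geom.r_inner_px - disp_px_t[t]
        r_out = geom.r_outer_px - disp_px_t[t]
        myo[t] = (rho >= r_in) & (rho <= r_out)
        blood[t] = rho < r_in - 1.0
        vel[t, 0][myo[t]] = v_rad[t] * u_row[myo[t]]
        vel[t, 1][myo[t]] = v_rad[t] * u_col[myo[t]]
        vel[t, 2][myo[t]] = v_long[t]
        myo[t] &= ~static_mask
        blood[t] &= ~static_mask

    vel[:, :, static_mask] = 0.0
    if not static_mask.any():
        raise ValueError("static mask is empty")
    return PhantomCine(
        n_phases=n_phases,
        matrix=(ny, nx),
        pixel_mm=pixel_mm,
        myo_mask=myo,
        blood_mask=blood,
        static_mask=static_mask,
        velocity=vel,
        centroid=(cy, cx),
        times_frac=times_frac,
        rr_ms=rr_ms,
        motion=motion,
    )


@dataclass
class EncodedCine:
    """Complex image stacks of the 4-point velocity-encoded acquisition.

    ``images`` has shape (4, n_phases, ny, nx); encoding order is
    ('reference', 'row', 'column', 'through').  Pixel magnitude is identical
    across the four encodings at fixed phase and pixel (before noise).
    ``background_coeffs`` = (offset, slope_row, slope_col) in radians (per
    pixel for the slopes), applied to the velocity-encoded segments only.
    """

    images: np.ndarray
    venc_cm_s: float
    background_coeffs: tuple[float, float, float]
    encoding_order: tuple[str, ...] = ("reference", "row", "column", "through")


def encode_velocity(
    ph: PhantomCine,
    venc_cm_s: float = 30.0,
    background_coeffs: tuple[float, float, float] = (0.0, 0.0, 0.0),
    magnitudes: Mapping[str, float] | None = None,
) -> EncodedCine:
    """Form the 4-point referenced velocity-encoded complex images.

    Reference segment: phase 0.  Encoding segment e in (row, col, through):
    phase = background plane + pi * v_e / VENC.  Magnitudes come from the
    tissue class maps with the blood pool suppressed (black blood).
    Velocities at or beyond VENC raise (aliasing is an error, not a wrap).
    """
    mags = dict(DEFAULT_MAGNITUDES)
    if magnitudes:
        mags.update(magnitudes)
    if np.max(np.abs(ph.velocity)) >= venc_cm_s:
        raise ValueError("phantom velocity reaches or exceeds VENC (aliasing)")
    ny, nx = ph.matrix
    rows = np.arange(ny)[:, None]
    cols = np.arange(nx)[None, :]
    b0, b_row, b_col = background_coeffs
    plane = b0 + b_row * rows + b_col * cols

    images = np.zeros((4, ph.n_phases, ny, nx), dtype=complex)
    for t in range(ph.n_phases):
        mag = np.full((ny, nx), mags["air"], dtype=float)
        mag[ph.static_mask] = mags["static"]
        mag[ph.myo_mask[t]] = mags["myocardium"]
        mag[ph.blood_mask[t]] = mags["blood"]
        images[0, t] = mag
        for e in range(3):
            phase = plane + np.pi * ph.velocity[t, e] / venc_cm_s
            images[e + 1, t] = mag * np.exp(1j * phase)
    return EncodedCine(images=images, venc_cm_s=venc_cm_s, background_coeffs=tuple(background_coeffs))
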
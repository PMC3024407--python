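"""From reconstructed complex images to myocardial velocity curves and features.

Chain: phase-difference velocity maps (reference vs encoded segment),
linear background-phase correction on static tissue, mask-mean radial and
longitudinal velocity curves, periodic cubic-spline resampling to a dense
uniform grid, zero-integral shift, and peak-feature extraction
(v_p,sys, v_p,dias, delta_v = v_p,sys - v_p,dias, t_dias).

Sign conventions: radial velocity is positive toward the blood-pool
centroid (systolic contraction positive); longitudinal velocity is positive
toward the apex.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .phantom import PhantomCine

__all__ = [
    "VelocityCurve",
    "CurveFeatures",
    "phase_to_velocity",
    "correct_background",
    "extract_curves",
    "resample_spline",
    "zero_shift",
    "find_peaks",
    "quantify_cine",
]


@dataclass
class VelocityCurve:
    """Mask-mean velocity time series, optionally spline-resampled.

    ``t_ms``/``v_cm_s`` are the per-phase samples; ``dense_t_ms``/``dense_v``
    the uniform dense grid after `resample_spline` (step ``dt_ms``).
    """

    direction: str
    t_ms: np.ndarray
    v_cm_s: np.ndarray
    dense_t_ms: np.ndarray | None = None
    dense_v: np.ndarray | None = None
    dt_ms: float | None = None


@dataclass
class CurveFeatures:
    """Peak features of one velocity curve."""

    v_p_sys: float
    v_p_dias: float
    delta_v: float
    t_dias_ms: float
    t_sys_ms: float


def phase_to_velocity(ref: np.ndarray, enc: np.ndarray, venc_cm_s: float) -> np.ndarray:
    """Phase-difference velocity map, cm/s: v = angle(enc * conj(ref)) / pi * venc.

    Pixels where either magnitude is exactly zero have no defined phase and
    are flagged NaN (excluded from downstream mask means).
    """
    ref = np.asarray(ref)
    enc = np.asarray(enc)
    if ref.shape != enc.shape:
        raise ValueError("reference and encoded images must share a shape")
    v = np.angle(enc * np.conj(ref)) / np.pi * venc_cm_s
    invalid = (np.abs(ref) == 0) | (np.abs(enc) == 0)
    return np.where(invalid, np.nan, v)


def correct_background(
    v: np.ndarray, static_mask: np.ndarray
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Subtract a least-squares plane fitted over static tissue.

    The plane is offset + slope_row * row + slope_col * col, fitted to the
    values of ``v`` on ``static_mask`` and subtracted everywhere.  Returns
    the corrected image and the coefficients (in the units of ``v``).
    """
    v = np.asarray(v, dtype=float)
    mask = np.asarray(static_mask, dtype=bool)
    if mask.sum() < 3:
        raise ValueError("static mask needs at least 3 pixels")
    rows, cols = np.nonzero(mask)
    vals = v[rows, cols]
    good = np.isfinite(vals)
    rows, cols, vals = rows[good], cols[good], vals[good]
    A = np.column_stack([np.ones_like(rows, dtype=float), rows, cols])
    if np.linalg.matrix_rank(A) < 3:
        raise ValueError("static mask pixels are collinear; plane fit degenerate")
    coeffs, *_ = np.linalg.lstsq(A, vals, rcond=None)
    ny, nx = v.shape
    plane = coeffs[0] + coeffs[1] * np.arange(ny)[:, None] + coeffs[2] * np.arange(nx)[None, :]
    return v - plane, (float(coeffs[0]), float(coeffs[1]), float(coeffs[2]))


def extract_curves(
    vfields: np.ndarray,
    myo_mask: np.ndarray,
    centroid: tuple[float, float],
    t_ms: np.ndarray | None = None,
    apex_sign: float = 1.0,
) -> tuple[VelocityCurve, VelocityCurve]:
    """Radial and longitudinal mask-mean velocity curves.

    ``vfields``: (n_phases, 3, ny, nx) with components (row, col, through).
    Radial value per pixel = in-plane velocity projected onto the unit
    vector pointing toward the centroid; longitudinal value = through-plane
    component times ``apex_sign``.  NaN pixels are excluded.
    """
    vfields = np.asarray(vfields)
    n_phases, _, ny, nx = vfields.shape
    if t_ms is None:
        t_ms = np.arange(n_phases, dtype=float)
    cy, cx = centroid
    rows = np.arange(ny)[:, None] * np.ones((1, nx))
    cols = np.ones((ny, 1)) * np.arange(nx)[None, :]
    rho = np.hypot(rows - cy, cols - cx)
    with np.errstate(invalid="ignore", divide="ignore"):
        u_row = np.where(rho > 0, (cy - rows) / np.maximum(rho, 1e-12), 0.0)
        u_col = np.where(rho > 0, (cx - cols) / np.maximum(rho, 1e-12), 0.0)

    v_rad = np.empty(n_phases)
    v_long = np.empty(n_phases)
    for t in range(n_phases):
        m = myo_mask[t] & (rho > 0)
        if not m.any():
            raise ValueError(f"empty myocardial mask at phase {t}")
        proj = vfields[t, 0] * u_row + vfields[t, 1] * u_col
        v_rad[t] = np.nanmean(proj[m])
        v_long[t] = apex_sign * np.nanmean(vfields[t, 2][m])
    return (
        VelocityCurve("radial", np.asarray(t_ms, float), v_rad),
        VelocityCurve("longitudinal", np.asarray(t_ms, float), v_long),
    )


def resample_spline(c: VelocityCurve, dt_ms: float, period_ms: float | None = None) -> VelocityCurve:
    """Periodic cubic-spline resampling onto a uniform dense grid.

    ``period_ms`` defaults to n * sample spacing (the acquisition window,
    assuming uniform phase intervals).  The dense grid covers one period
    starting at the first sample time.
    """
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    t, v = np.asarray(c.t_ms, float), np.asarray(c.v_cm_s, float)
    if len(t) < 4:
        raise ValueError("need at least 4 phases for cubic-spline resampling")
    if period_ms is None:
        spacing = np.diff(t)
        if not np.allclose(spacing, spacing[0]):
            raise ValueError("period_ms required for non-uniform sampling")
        period_ms = len(t) * spacing[0]
    spline = CubicSpline(
        np.append(t, t[0] + period_ms), np.append(v, v[0]), bc_type="periodic"
    )
    n_dense = int(round(period_ms / dt_ms))
    dense_t = t[0] + np.arange(n_dense) * dt_ms
    return replace(c, dense_t_ms=dense_t, dense_v=spline(dense_t), dt_ms=float(dt_ms))


def zero_shift(c: VelocityCurve) -> VelocityCurve:
    """Shift the curve so the cycle integral (dense-grid mean) is zero.

    Physiologically the accumulated displacement over the cycle vanishes;
    the residual mean is a non-linear background-phase contribution and is
    removed as a constant.  Idempotent.
    """
    if c.dense_v is None:
        raise ValueError("resample the curve before zero-shifting")
    shift = float(np.mean(c.dense_v))
    return replace(c, v_cm_s=c.v_cm_s - shift, dense_v=c.dense_v - shift)


def find_peaks(
    c: VelocityCurve,
    systole_window: tuple[float, float] | None = None,
    diastole_window: tuple[float, float] | None = None,
) -> CurveFeatures:
    """Systolic/diastolic peak velocities and time to the diastolic peak.

    v_p,sys is the signed extremum of largest magnitude inside the systole
    window; v_p,dias the opposite-signed extremum inside the diastole
    window; delta_v = v_p,sys - v_p,dias.  Default windows split the dense
    grid in half.  Ties break to the earliest time.
    """
    if c.dense_v is None:
        raise ValueError("resample the curve before peak extraction")
    t, v = c.dense_t_ms, c.dense_v
    t_mid = t[0] + (t[-1] - t[0]) / 2.0
    if systole_window is None:
        systole_window = (t[0], t_mid)
    if diastole_window is None:
        diastole_window = (t_mid, t[-1] + (c.dt_ms or 0.0))
    sys_sel = (t >= systole_window[0]) & (t < systole_window[1])
    dia_sel = (t >= diastole_window[0]) & (t < diastole_window[1])
    if not sys_sel.any() or not dia_sel.any():
        raise ValueError("empty peak-search window")

    vs = v[sys_sel]
    ts = t[sys_sel]
    i_sys = int(np.argmax(np.abs(vs)))  # argmax returns the earliest tie
    v_p_sys = float(vs[i_sys])

    vd = v[dia_sel]
    td = t[dia_sel]
    if v_p_sys > 0:
        i_dias = int(np.argmin(vd))
    elif v_p_sys < 0:
        i_dias = int(np.argmax(vd))
    else:
        i_dias = 0
    v_p_dias = float(vd[i_dias]) if v_p_sys != 0 else 0.0
    t_dias = float(td[i_dias])
    return CurveFeatures(
        v_p_sys=v_p_sys,
        v_p_dias=v_p_dias,
        delta_v=v_p_sys - v_p_dias,
        t_dias_ms=t_dias,
        t_sys_ms=float(ts[i_sys]),
    )


def quantify_cine(
    images: np.ndarray,
    ph: PhantomCine,
    venc_cm_s: float,
    t_ms: np.ndarray,
    dt_ms: float = 0.01,
    background_correction: bool = True,
) -> dict[str, VelocityCurve]:
    """Full quantification chain for a reconstructed 4-encoding image series.

    Returns dense, zero-shifted radial and longitudinal `VelocityCurve`s
    keyed by direction.  Masks and centroid come from the phantom (standing
    in for segmentation of in-vivo data).
    """
    n_enc, n_phases = images.shape[:2]
    if n_enc != 4:
        raise ValueError("expected 4 encoding segments (reference + 3 directions)")
    vfields = np.empty((n_phases, 3, *images.shape[2:]))
    for t in range(n_phases):
        for e in range(3):
            v = phase_to_velocity(images[0, t], images[e + 1, t], venc_cm_s)
            if background_correction:
                v, _ = correct_background(v, ph.static_mask)
            vfields[t, e] = v
    rad, lon = extract_curves(vfields, ph.myo_mask, ph.centroid, t_ms=t_ms)
    out = {}
    for c in (rad, lon):
        out[c.direction] = zero_shift(resample_spline(c, dt_ms))
    return out
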
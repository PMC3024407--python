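"""Timing arithmetic of a segmented, navigator-gated tissue phase mapping protocol.

The acquisition model is a cardiac-triggered, velocity-encoded gradient-echo
cine: each heartbeat acquires one segment of ``klines_per_segment`` phase-encode
lines (plus startup echoes) per cardiac phase, preceded by a black-blood
saturation module, with a respiratory navigator at the start of the cycle.
Velocity encoding along the three spatial directions plus a reference segment
is interleaved over consecutive heartbeats (``n_encodings = 4``).

k-t undersampling with factor ``R`` reduces the number of phase-encode
segments per encoding by ``R`` but adds a fixed training-stage overhead, so
the relative speed gain shrinks as ``R`` grows.  The number of reconstructed
cardiac phases is constrained to a multiple of ``R`` so that every region of
k-space experiences the same undersampling factor.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

__all__ = [
    "ProtocolParams",
    "phase_interval",
    "max_heart_phases",
    "phases_for_factor",
    "nominal_scan_beats",
    "nominal_scan_time",
    "protocol_table",
]


@dataclass
class ProtocolParams:
    """Sequence constants of the tissue phase mapping protocol.

    Defaults correspond to a 3 T segmented gradient-echo TPM protocol:
    TE/TR = 4.7/7.1 ms, flip angle 15 deg, acquisition matrix 172x168
    (frequency x phase encode), 3 k-lines per segment with one startup echo,
    12 ms saturation module, 15.5 ms navigator + 5 ms feedback, 90 %
    acquisition window, VENC = 30 cm/s, 11 training lines for the k-t prior.
    """

    tr_ms: float = 7.1
    te_ms: float = 4.7
    flip_deg: float = 15.0
    n_freq: int = 172
    n_pe: int = 168
    klines_per_segment: int = 3
    startup_echoes: int = 1
    sat_module_ms: float = 12.0
    nav_ms: float = 15.5
    nav_feedback_ms: float = 5.0
    acq_window_fraction: float = 0.9
    rr_ms: float = 1000.0
    venc_cm_s: float = 30.0
    n_encodings: int = 4
    training_lines: int = 11
    training_overhead_beats: int = 13
    prep_beats: int = 1
    kt_factor: int = 1

    def __post_init__(self) -> None:
        if self.tr_ms <= 0 or self.rr_ms <= 0:
            raise ValueError("TR and RR must be positive durations")
        for name in ("te_ms", "sat_module_ms", "nav_ms", "nav_feedback_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("klines_per_segment", "startup_echoes", "training_lines",
                     "training_overhead_beats", "prep_beats"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_freq < 1 or self.n_pe < 1 or self.n_encodings < 1:
            raise ValueError("matrix sizes and encoding count must be >= 1")
        if not 0 < self.acq_window_fraction <= 1:
            raise ValueError("acq_window_fraction must lie in (0, 1]")
        if self.kt_factor < 1:
            raise ValueError("kt_factor must be >= 1 (1 = non-accelerated)")
        if self.venc_cm_s <= 0:
            raise ValueError("venc_cm_s must be positive")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown protocol keys: {sorted(unknown)}")
        return cls(**d)

    def to_config(self, path: str | Path) -> None:
        """Write a flat key: value config file (YAML subset)."""
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_config(cls, path: str | Path) -> "ProtocolParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def phase_interval(p: ProtocolParams) -> float:
    """Duration of one cardiac phase in ms.

    One segment of ``klines_per_segment`` lines plus startup echoes at TR
    each, preceded by the saturation module.  Independent of the k-t factor:
    undersampling removes whole segments (heartbeats), not lines within a
    phase.
    """
    return (p.klines_per_segment + p.startup_echoes) * p.tr_ms + p.sat_module_ms


def max_heart_phases(p: ProtocolParams) -> int:
    """Maximum number of cardiac phases fitting in the gated acquisition window."""
    interval = phase_interval(p)
    usable = p.acq_window_fraction * p.rr_ms - p.nav_ms - p.nav_feedback_ms
    if usable <= 0:
        raise ValueError("usable acquisition window is non-positive")
    if interval <= 0:
        raise ValueError("phase interval is non-positive")
    return int(math.floor(usable / interval))

def phases_for_factor(max_phases: int, R: int) -> int:
    """Largest phase count <= ``max_phases`` that is a multiple of ``R``.

    Ensures the same undersampling factor in all regions of k-space.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if max_phases < R:
        raise ValueError(f"max_phases={max_phases} < R={R}")
    return R * (max_phases // R)


def nominal_scan_beats(p: ProtocolParams, R: int | None = None) -> int:
    """Number of heartbeats of the nominal (100 % gating efficiency) scan.

    Non-accelerated: every encoding acquires all ``ceil(n_pe / klines)``
    segments, plus preparation beats.  Accelerated: each encoding acquires
    every R-th segment, plus the constant training-stage overhead.
    """
    if R is None:
        R = p.kt_factor
    if R < 1:
        raise ValueError("R must be >= 1")
    k = p.klines_per_segment
    if R == 1:
        return p.n_encodings * math.ceil(p.n_pe / k) + p.prep_beats
    return p.n_encodings * (p.n_pe // (k * R)) + p.training_overhead_beats


def nominal_scan_time(beats: int, rr_ms: float) -> float:
    """Nominal scan duration in seconds for a given heartbeat count."""
    if beats < 0:
        raise ValueError("beats must be >= 0")
    return beats * rr_ms / 1000.0


def protocol_table(
    p: ProtocolParams | None = None,
    R_list: Sequence[int] | Iterable[int] = range(1, 8),
    rr_ms: float | None = None,
) -> pd.DataFrame:
    """Protocol sweep over k-t factors: phases and nominal scan time per R.

    Columns: ``kt_factor`` ('no' for R = 1), ``heart_phases``,
    ``scan_time_s``.  With the default protocol at RR = 1000 ms this yields
    (no, 21, 225), (2, 20, 125), (3, 21, 85), (4, 20, 69), (5, 20, 57),
    (6, 18, 49), (7, 21, 45).
    """
    if p is None:
        p = ProtocolParams()
    rr = p.rr_ms if rr_ms is None else rr_ms
    p_rr = ProtocolParams.from_dict({**p.to_dict(), "rr_ms": rr})
    mp = max_heart_phases(p_rr)
    rows = []
    for R in R_list:
        beats = nominal_scan_beats(p_rr, R)
        rows.append(
            {
                "kt_factor": "no" if R == 1 else R,
                "heart_phases": phases_for_factor(mp, R),
                "scan_time_s": nominal_scan_time(beats, rr),
            }
        )
    return pd.DataFrame(rows, columns=["kt_factor", "heart_phases", "scan_time_s"])
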
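"""Three-phase decomposition of a suture-tension trace.

After knotting, suture tension relaxes in three phases: a *rapid cutting
phase* (RCP) lasting one minute in which the suture cuts into the tissue and
tension drops fastest (peak tension P0 down to P1), a *constant declining
phase* (CDP) of slower, constant-rate relative decline attributed to plastic
tissue deformation, and a final *plateau phase* (PP) whose residual tension
Pplat reflects the remaining structural stability of the tissue.

This module measures the phase landmarks directly from the trace:

* ``P0``   — maximum force over the first 5 s, at full acquisition rate;
* ``P1``   — mean force over a ±5 s window around the 1-minute mark (the RCP
  is *defined* as exactly one minute; no transition detector is used);
* ``Pplat`` — mean force over the trailing 60 s of the record.

The half-tension time (first crossing of P0/2) is reported in minutes with a
censoring flag: a trace that never falls to half its peak within the record
yields the record length as a lower bound, matching the "> 60 min"
convention of per-tissue summary tables.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .trace_io import TensionTrace, TraceValidationError

__all__ = [
    "PhaseMetrics",
    "detect_p0",
    "segment_phases",
    "half_tension_time",
    "P0_WINDOW_S",
    "P1_WINDOW_S",
    "PLATEAU_WINDOW_S",
    "DEFAULT_RECORD_S",
]

#: Window (s, from record start) over which the peak tension P0 is taken.
P0_WINDOW_S = 5.0

#: Window (s) around the 1-minute mark over which P1 is averaged.
P1_WINDOW_S = (55.0, 65.0)

#: Trailing window (s) over which the plateau tension is averaged.
PLATEAU_WINDOW_S = 60.0

#: Full nominal record length (s); shorter records get no plateau estimate.
DEFAULT_RECORD_S = 3600.0


@dataclass(frozen=True)
class PhaseMetrics:
    """Per-suture phase landmarks and derived statistics.

    ``rcp_loss_pct`` is the percentage of peak tension lost during the rapid
    cutting phase, ``100 * (p0 - p1) / p0``; ``plateau_ratio_pct`` is
    ``100 * pplat / p0``.  ``half_time_min`` is the first P0/2 crossing in
    minutes; when ``half_time_censored`` it equals the record length and is
    a lower bound.  ``pplat`` and ``plateau_ratio_pct`` are NaN when the
    record does not span the full configured length.
    """

    suture_id: str
    tissue: str
    p0: float
    p1: float
    pplat: float
    rcp_loss_pct: float
    plateau_ratio_pct: float
    half_time_min: float
    half_time_censored: bool
    flags: Tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "suture_id": self.suture_id,
            "tissue": self.tissue,
            "p0_n": self.p0,
            "p1_n": self.p1,
            "pplat_n": self.pplat,
            "rcp_loss_pct": self.rcp_loss_pct,
            "plateau_ratio_pct": self.plateau_ratio_pct,
            "half_time_min": self.half_time_min,
            "half_time_censored": self.half_time_censored,
            "flags": ";".join(self.flags),
        }


def detect_p0(trace: TensionTrace, window_s: float = P0_WINDOW_S) -> float:
    """Peak tension at the beginning: max force over the first ``window_s``.

    Evaluated at the trace's own (full acquisition) rate — the peak is a
    pointwise extremum and must not be smoothed away by decimation.
    """
    if window_s <= 0:
        raise TraceValidationError("P0 window must be positive")
    if trace.duration_s < window_s:
        raise TraceValidationError(
            f"trace spans {trace.duration_s:g} s < P0 window {window_s:g} s"
        )
    mask = trace.times <= trace.times[0] + window_s
    if not mask.any():
        raise TraceValidationError("empty P0 window")
    return float(trace.forces[mask].max())


def half_tension_time(trace: TensionTrace, p0: float) -> Tuple[float, bool]:
    """First time (minutes) at which force falls to half the peak ``p0``.

    Linear interpolation between the bracketing samples; the earliest
    crossing wins.  Returns ``(record length in minutes, True)`` when the
    threshold is never reached — a censored lower bound.
    """
    if p0 <= 0:
        raise TraceValidationError("p0 must be > 0")
    threshold = p0 / 2.0
    below = trace.forces <= threshold
    if not below.any():
        return trace.duration_s / 60.0, True
    i = int(np.argmax(below))
    if i == 0:
        return float(trace.times[0]) / 60.0, False
    t_lo, t_hi = trace.times[i - 1], trace.times[i]
    f_lo, f_hi = trace.forces[i - 1], trace.forces[i]
    if f_lo == f_hi:
        t_cross = t_hi
    else:
        t_cross = t_lo + (f_lo - threshold) * (t_hi - t_lo) / (f_lo - f_hi)
    return float(t_cross) / 60.0, False


def segment_phases(
    trace: TensionTrace,
    record_s: float = DEFAULT_RECORD_S,
    monotone_tol: float = 0.02,
) -> PhaseMetrics:
    """Decompose a trace into its three phases and compute landmark metrics.

    Requires at least 61 s of record so that both P0 and P1 exist.  The
    plateau is only measured when the trace spans the full ``record_s``
    (60 minutes by default); otherwise ``pplat`` is NaN and the metrics
    carry a ``"pplat_unavailable"`` flag.  A trace whose 1-minute tension
    exceeds its peak beyond ``monotone_tol`` newtons is flagged
    ``"non_monotone"`` but still summarised.
    """
    if trace.duration_s < 61.0:
        raise TraceValidationError(
            f"trace spans {trace.duration_s:g} s < 61 s needed for P0 and P1"
        )
    flags = []
    p0 = detect_p0(trace)
    t = trace.times
    f = trace.forces
    lo, hi = P1_WINDOW_S
    p1_mask = (t >= lo) & (t <= hi)
    p1 = float(f[p1_mask].mean())
    if p1 > p0 + monotone_tol:
        flags.append("non_monotone")
    if trace.duration_s + 1e-6 >= record_s:
        tail_mask = t >= t[0] + trace.duration_s - PLATEAU_WINDOW_S - 1e-9
        pplat = float(f[tail_mask].mean())
        plateau_ratio_pct = 100.0 * pplat / p0
    else:
        flags.append("pplat_unavailable")
        pplat = float("nan")
        plateau_ratio_pct = float("nan")
    rcp_loss_pct = 100.0 * (p0 - p1) / p0
    if rcp_loss_pct < 0.0 or rcp_loss_pct > 100.0:
        flags.append("rcp_loss_clipped")
        rcp_loss_pct = float(np.clip(rcp_loss_pct, 0.0, 100.0))
    if np.isfinite(plateau_ratio_pct) and (
        plateau_ratio_pct < 0.0 or plateau_ratio_pct > 100.0
    ):
        flags.append("plateau_ratio_clipped")
        plateau_ratio_pct = float(np.clip(plateau_ratio_pct, 0.0, 100.0))
    half_time, censored = half_tension_time(trace, p0)
    return PhaseMetrics(
        suture_id=trace.suture_id,
        tissue=trace.tissue,
        p0=p0,
        p1=p1,
        pplat=pplat,
        rcp_loss_pct=rcp_loss_pct,
        plateau_ratio_pct=plateau_ratio_pct,
        half_time_min=half_time,
        half_time_censored=censored,
        flags=tuple(flags),
    )
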
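"""Stretched-exponential relaxation fit for the constant declining phase.

The tension between the 1-minute transition (P1) and the final plateau is
modelled as

    y(t) = a * exp(-b * t**c) + d

with ``t`` in minutes from the start of the fit window, so that

* ``a`` — amplitude, the estimated ``P1 - Pplat`` (the model equals
  ``a + d`` at ``t = 0``);
* ``b`` — decay rate per minute (the "negative gradient");
* ``c`` — time exponent; ``c = 1`` (the default, and what a constant
  per-minute relative decline implies) gives pure exponential decay of the
  gap above the plateau;
* ``d`` — the estimated plateau tension.

With ``c = 1`` the gap above the plateau loses the constant fraction
``1 - exp(-b)`` every minute; :func:`decline_per_minute` reports that as a
percentage, which is the tissue-level summary quantity of interest.

Fit quality is summarised by ``r_fit``, the plain Pearson correlation
between the fitted and the measured series over the fit window.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Tuple

import numpy as np
from scipy.optimize import brentq, least_squares

from .phase_analysis import detect_p0
from .trace_io import TensionTrace, TraceValidationError, resample_trace

__all__ = [
    "RelaxationFit",
    "HalfTime",
    "model_eval",
    "initial_guess",
    "fit_relaxation",
    "decline_per_minute",
    "half_time_from_fit",
    "DEFAULT_ANALYSIS_HZ",
]

#: Decimation rate for fitting; the model varies on a minutes scale, so a
#: 1 Hz grid (3,540 points over the default window) is ample.
DEFAULT_ANALYSIS_HZ = 1.0

_B_MIN, _B_MAX = 1e-4, 10.0
_C_MIN, _C_MAX = 0.2, 3.0
_EPS_A = 1e-6


@dataclass(frozen=True)
class RelaxationFit:
    """Fitted relaxation parameters plus fit quality and provenance."""

    suture_id: str
    tissue: str
    a: float
    b: float
    c: float
    d: float
    r_fit: float
    window: Tuple[float, float]
    converged: bool
    n_points: int
    flags: Tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "suture_id": self.suture_id,
            "tissue": self.tissue,
            "a_n": self.a,
            "b_per_min": self.b,
            "c": self.c,
            "d_n": self.d,
            "r_fit": self.r_fit,
            "window_start_s": self.window[0],
            "window_end_s": self.window[1],
            "converged": self.converged,
            "n_points": self.n_points,
            "flags": ";".join(self.flags),
        }


def model_eval(a: float, b: float, c: float, d: float, t):
    """Evaluate ``d + a * exp(-b * t**c)`` at ``t`` minutes (``t >= 0``)."""
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ValueError("model time must be >= 0 (minutes from window start)")
    out = d + a * np.exp(-b * np.power(arr, c))
    return float(out) if np.isscalar(t) or arr.ndim == 0 else out


class GuessResult(NamedTuple):
    params: Tuple[float, float, float, float]
    flat: bool


def initial_guess(times_min: np.ndarray, forces: np.ndarray) -> GuessResult:
    """Data-driven starting point ``(a0, b0, c0, d0)`` for the optimizer.

    ``d0`` is the mean of the last decile of forces (the emerging plateau),
    ``a0`` the first-point force above that plateau, ``c0 = 1``, and ``b0``
    the log-gap slope between the first point and the point nearest the
    middle of the window, floored at 1e-3/min.  A non-decaying window
    (``a0 <= 0``) yields a flat-curve guess with the ``flat`` flag set.
    """
    times_min = np.asarray(times_min, dtype=float)
    forces = np.asarray(forces, dtype=float)
    if len(times_min) < 10 or times_min[-1] - times_min[0] < 10.0:
        raise TraceValidationError(
            "initial guess needs >= 10 points spanning >= 10 minutes"
        )
    tail = max(len(forces) // 10, 1)
    d0 = float(forces[-tail:].mean())
    a0 = float(forces[0]) - d0
    if a0 <= _EPS_A:
        return GuessResult((_EPS_A, 1e-3, 1.0, max(d0, 0.0)), True)
    mid = int(np.argmin(np.abs(times_min - 0.5 * (times_min[0] + times_min[-1]))))
    gap_mid = float(forces[mid]) - d0
    if gap_mid > 0 and times_min[mid] > times_min[0]:
        b0 = np.log(a0 / gap_mid) / (times_min[mid] - times_min[0])
        b0 = float(max(b0, 1e-3))
    else:
        b0 = 1.0  # mid-window already at plateau: decay is fast
    return GuessResult((a0, b0, 1.0, max(d0, 0.0)), False)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def fit_relaxation(
    trace: TensionTrace,
    window: Optional[Tuple[float, float]] = None,
    free_c: bool = False,
    analysis_hz: float = DEFAULT_ANALYSIS_HZ,
) -> RelaxationFit:
    """Bounded least-squares fit of the relaxation model over ``window``.

    The default window is [60 s, record end] — the constant declining phase
    and plateau.  The trace is block-mean decimated to ``analysis_hz``
    before fitting.  Bounds: ``a in (0, 2*P0]``, ``b in [1e-4, 10]``,
    ``d in [0, P1]``; ``c`` is fixed at 1 unless ``free_c``, then
    ``c in [0.2, 3]``.  Convergence: relative cost change below 1e-10 or the
    iteration budget; a non-converged fit returns its best iterate with
    ``converged=False``.
    """
    if window is None:
        window = (60.0, float(trace.times[-1]))
    start, end = window
    if start < trace.times[0] or end > trace.times[-1] + 1.0 / trace.sampling_hz:
        raise TraceValidationError(
            f"window [{start:g}, {end:g}] s outside record "
            f"[{trace.times[0]:g}, {trace.times[-1]:g}] s"
        )
    work = trace
    if trace.sampling_hz > analysis_hz * (1 + 1e-9):
        work = resample_trace(trace, analysis_hz)
    mask = (work.times >= start) & (work.times <= end)
    if mask.sum() < 10:
        raise TraceValidationError(
            f"only {int(mask.sum())} points in fit window; need >= 10"
        )
    t_min = (work.times[mask] - start) / 60.0
    y = work.forces[mask]
    p0_peak = detect_p0(trace)
    near_start = (work.times >= start - 5.0) & (work.times <= start + 5.0)
    p1_level = float(work.forces[near_start].mean()) if near_start.any() else float(y[0])

    (a0, b0, c0, d0), flat = initial_guess(t_min, y)
    flags = ("flat_guess",) if flat else ()

    a_hi = max(2.0 * p0_peak, a0 * 1.001, 2 * _EPS_A)
    d_hi = max(p1_level, d0 * 1.001, 1e-12)
    if free_c:
        lower = [1e-9, _B_MIN, _C_MIN, 0.0]
        upper = [a_hi, _B_MAX, _C_MAX, d_hi]
        x0 = [a0, b0, c0, d0]
    else:
        lower = [1e-9, _B_MIN, 0.0]
        upper = [a_hi, _B_MAX, d_hi]
        x0 = [a0, b0, d0]
    x0 = np.clip(x0, lower, upper)

    def residuals(x):
        if free_c:
            a, b, c, d = x
        else:
            a, b, d = x
            c = 1.0
        return d + a * np.exp(-b * np.power(t_min, c)) - y

    result = least_squares(
        residuals,
        x0,
        bounds=(lower, upper),
        method="trf",
        ftol=1e-10,
        xtol=1e-12,
        gtol=1e-12,
        max_nfev=500 * (len(x0) + 1),
    )
    if free_c:
        a, b, c, d = result.x
    else:
        a, b, d = result.x
        c = 1.0
    fitted = d + a * np.exp(-b * np.power(t_min, c))
    r_fit = _pearson(fitted, y)
    return RelaxationFit(
        suture_id=trace.suture_id,
        tissue=trace.tissue,
        a=float(a),
        b=float(b),
        c=float(c),
        d=float(d),
        r_fit=r_fit,
        window=(float(start), float(end)),
        converged=bool(result.status > 0),
        n_points=int(mask.sum()),
        flags=flags,
    )


def decline_per_minute(fit: RelaxationFit) -> float:
    """Percent of the above-plateau tension gap lost per minute.

    For ``c = 1`` this is exactly ``100 * (1 - exp(-b))`` — constant in
    time.  For ``c != 1`` the decline is no longer constant and the
    geometric-mean per-minute gap decline over the fit window is reported:
    ``100 * (1 - (gap(T)/gap(0))**(1/T))`` with ``T`` the window length in
    minutes.
    """
    if fit.a <= 0:
        raise ValueError("non-positive gap amplitude; decline undefined")
    if fit.c == 1.0:
        return 100.0 * (1.0 - np.exp(-fit.b))
    t_end = (fit.window[1] - fit.window[0]) / 60.0
    if t_end <= 0:
        raise ValueError("degenerate fit window; decline undefined")
    gap0 = fit.a
    gap1 = fit.a * np.exp(-fit.b * t_end**fit.c)
    if gap1 <= 0:
        raise ValueError("non-positive gap at window end; decline undefined")
    return 100.0 * (1.0 - (gap1 / gap0) ** (1.0 / t_end))


class HalfTime(NamedTuple):
    """Half-tension crossing derived from a fit (minutes from knotting)."""

    time_min: float
    censored: bool
    at_boundary: bool = False


def half_time_from_fit(fit: RelaxationFit, p0: float) -> HalfTime:
    """Time (minutes from knotting) at which the *fitted* model crosses P0/2.

    The fitted plateau ``d`` decides censoring: when ``d >= p0/2`` the model
    never crosses and the window end is returned as a censored lower bound.
    When the threshold already exceeds the model's window-start value
    (``p0/2 >= a + d``) the crossing happened during the rapid cutting
    phase; the window start is returned with ``at_boundary=True`` and the
    measured-trace crossing should take precedence.  Otherwise the crossing
    is closed-form for ``c = 1`` and solved by bracketed root-finding for
    free ``c``.
    """
    if p0 <= 0:
        raise ValueError("p0 must be > 0")
    offset_min = fit.window[0] / 60.0
    threshold = p0 / 2.0
    if fit.d >= threshold:
        return HalfTime(fit.window[1] / 60.0, True)
    gap = threshold - fit.d
    if gap >= fit.a:
        return HalfTime(offset_min, False, at_boundary=True)
    if fit.c == 1.0:
        t = np.log(fit.a / gap) / fit.b
    else:
        def objective(t):
            return fit.a * np.exp(-fit.b * t**fit.c) - gap

        t_hi = 1.0
        while objective(t_hi) > 0:
            t_hi *= 2.0
            if t_hi > 1e9:  # pragma: no cover - unreachable for valid fits
                raise RuntimeError("failed to bracket the half-tension crossing")
        t = brentq(objective, 0.0, t_hi, rtol=1e-6)
    return HalfTime(float(t) + offset_min, False)
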
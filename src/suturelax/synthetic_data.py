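"""Seeded generator for suture-tension traces with realistic tissue structure.

No public data set of in-loop suture-tension recordings exists, so every
downstream stage is exercised against synthetic cohorts that emulate the
measurement setting the analysis was designed for: 6 sutures per organ in
5 organ types (liver, skin, stomach, muscle, small intestine), 60-minute
records sampled at 250 Hz by a force sensor with 0.077 g resolution.

The noiseless mean curve of a synthetic suture is piecewise:

* rapid cutting phase, ``t in [0, 60 s]``:
  ``y(t) = P1 + (P0 - P1) * exp(-t / tau_rcp)`` with ``P1 = P0*(1 - rcp_loss)``
  — the first minute of cutting-through damage, collapsed into a single
  exponential transient (the literature gives the phase no internal shape);
* constant declining phase and plateau, ``t > 60 s``:
  ``y(t) = d + a * exp(-b * (t - 60)/60)`` with ``d`` the plateau tension,
  ``a = P1 - d`` and ``b = -ln(1 - decline_per_min)`` so that the gap above
  the plateau loses a constant fraction per minute.

Gaussian sensor noise is added per raw sample, then forces are quantized to
the sensor resolution and clipped at zero.

Tissue profiles carry both the *absolute* tension columns (P0, P1, Pplat)
and the *relative* rows (RCP loss %, plateau/P0 %).  Published per-tissue
tables of this kind report means of per-suture ratios, which are not
mutually consistent with ratios of the mean tensions (liver: 0.9/2.6 = 35%
vs a printed plateau ratio of 40%), so the generator supports two
parameterization modes — ``"absolute"`` draws the three tension levels,
``"relative"`` draws P0 plus the two ratios — and each consumer states
which mode it exercises.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional

import numpy as np
from scipy.stats import norm

from .trace_io import TISSUES, TensionTrace, gforce_to_newton
from .cohort_stats import CollagenMeasurement

__all__ = [
    "TissueProfile",
    "SutureParams",
    "SensorConfig",
    "GenerationError",
    "builtin_profiles",
    "sample_suture_params",
    "synthesize_trace",
    "simulate_cohort",
    "DEFAULT_QUANTIZATION_STEP_N",
    "DEFAULT_TAU_RCP_S",
]

#: Sensor force resolution, 0.077 g expressed in newtons.
DEFAULT_QUANTIZATION_STEP_N = gforce_to_newton(0.077)

#: Rapid-phase time constant (s); exp(-60/10) = 0.25% residual at 1 min.
DEFAULT_TAU_RCP_S = 10.0

#: Observed range of applied peak tension across all sutures of the study
#: setting (N); P0 draws are confined to it.
P0_RANGE_N = (0.7, 5.9)

#: Minimum fraction of P0 lost during the constant declining phase.  The
#: three-phase description presupposes an observable decline between the
#: 1-minute transition and the plateau (per-tissue mean gaps are 24-32% of
#: P0); this loose floor excludes physically degenerate sutures whose
#: plateau coincides with P1.
MIN_CDP_LOSS_FRAC = 0.05


class GenerationError(RuntimeError):
    """Degenerate profile or parameter set that cannot yield a valid trace."""


@dataclass(frozen=True)
class TissueProfile:
    """Per-tissue distribution parameters for trace generation.

    Tension levels in newtons, ratios as fractions in (0, 1), collagen as
    µg collagen per mg total protein.  ``cdp_decline_per_min`` is the
    constant fractional per-minute decline of the above-plateau gap during
    the constant declining phase (no spread is modelled for it: the source
    table prints it without an SD).
    """

    tissue: str
    p0_mean: float
    p0_sd: float
    p1_mean: float
    p1_sd: float
    pplat_mean: float
    pplat_sd: float
    rcp_loss_mean: float
    rcp_loss_sd: float
    cdp_decline_per_min: float
    plateau_ratio_mean: float
    plateau_ratio_sd: float
    collagen_mean: float
    collagen_sd: float

    def __post_init__(self) -> None:
        means = (
            self.p0_mean, self.p1_mean, self.pplat_mean, self.rcp_loss_mean,
            self.plateau_ratio_mean, self.collagen_mean,
        )
        sds = (
            self.p0_sd, self.p1_sd, self.pplat_sd, self.rcp_loss_sd,
            self.plateau_ratio_sd, self.collagen_sd,
        )
        if any(m <= 0 for m in means):
            raise GenerationError(f"{self.tissue}: all means must be > 0")
        if any(s < 0 for s in sds):
            raise GenerationError(f"{self.tissue}: SDs must be >= 0")
        if not 0 < self.rcp_loss_mean < 1 or not 0 < self.plateau_ratio_mean < 1:
            raise GenerationError(f"{self.tissue}: ratio means must lie in (0, 1)")
        if not 0 <= self.cdp_decline_per_min < 1:
            raise GenerationError(f"{self.tissue}: decline must lie in [0, 1)")

    def with_zero_sds(self) -> "TissueProfile":
        """Degenerate copy with every SD set to 0 (deterministic draws)."""
        return replace(
            self, p0_sd=0.0, p1_sd=0.0, pplat_sd=0.0, rcp_loss_sd=0.0,
            plateau_ratio_sd=0.0, collagen_sd=0.0,
        )


# Per-tissue reference profiles: mean ± SD of peak (P0), 1-minute (P1) and
# plateau (Pplat) tension in N; fractional first-minute loss; per-minute CDP
# decline; plateau/P0 ratio; collagen/protein content in µg/mg.
_BUILTIN = (
    TissueProfile("liver", 2.6, 1.6, 1.6, 1.1, 0.9, 0.7,
                  0.34, 0.19, 0.08, 0.40, 0.18, 25.0, 4.0),
    TissueProfile("skin", 2.2, 1.0, 1.8, 0.9, 1.3, 0.6,
                  0.16, 0.10, 0.08, 0.60, 0.09, 45.0, 11.0),
    TissueProfile("stomach", 2.9, 1.8, 2.3, 1.1, 1.3, 0.3,
                  0.18, 0.10, 0.15, 0.55, 0.19, 49.0, 14.0),
    TissueProfile("muscle", 2.0, 0.7, 1.4, 0.6, 0.9, 0.4,
                  0.27, 0.17, 0.15, 0.46, 0.09, 43.0, 4.0),
    TissueProfile("small_intestine", 1.7, 0.6, 1.4, 0.5, 0.9, 0.4,
                  0.17, 0.07, 0.10, 0.51, 0.11, 44.0, 8.0),
)


def builtin_profiles() -> dict:
    """Return the five built-in tissue profiles, keyed by tissue label."""
    return {p.tissue: p for p in _BUILTIN}


@dataclass(frozen=True)
class SensorConfig:
    """Acquisition model of the in-loop force sensor."""

    sampling_hz: float = 250.0
    quantization_step_n: float = DEFAULT_QUANTIZATION_STEP_N
    noise_sd_n: float = 0.02
    duration_s: float = 3600.0

    def __post_init__(self) -> None:
        if self.sampling_hz <= 0 or self.quantization_step_n <= 0:
            raise GenerationError("sampling rate and quantization must be > 0")
        if self.noise_sd_n < 0:
            raise GenerationError("noise SD must be >= 0")
        if self.duration_s < 61:
            raise GenerationError("records must span at least 61 s")


@dataclass(frozen=True)
class SutureParams:
    """Realized generator parameters for one suture."""

    tissue: str
    p0: float
    rcp_loss: float
    decline_per_min: float
    plateau: float
    tau_rcp: float = DEFAULT_TAU_RCP_S
    mode: str = "relative"
    suture_id: str = ""

    @property
    def p1(self) -> float:
        """Tension at the 1-minute transition, ``P0 * (1 - rcp_loss)``."""
        return self.p0 * (1.0 - self.rcp_loss)

    def validate(self) -> None:
        if self.p0 <= 0:
            raise GenerationError("p0 must be > 0")
        if not 0 < self.rcp_loss < 1:
            raise GenerationError("rcp_loss must lie in (0, 1)")
        if not 0 <= self.decline_per_min < 1:
            raise GenerationError("decline_per_min must lie in [0, 1)")
        if not 0 < self.plateau < self.p1:
            raise GenerationError(
                f"plateau {self.plateau:g} N must lie in (0, P1={self.p1:g} N)"
            )
        if self.tau_rcp <= 0:
            raise GenerationError("tau_rcp must be > 0")


_MIN_TRUNC_MASS = 1e-12


def _draw_truncated(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    lo: float,
    hi: float,
    extra_hi: float = np.inf,
) -> float:
    """Normal draw truncated *symmetrically* about the mean.

    The truncation interval is ``mean ± min(mean - lo, hi - mean)``, cutting
    equal probability mass from both tails so the mean of the truncated
    distribution equals ``mean`` exactly.  ``extra_hi`` imposes an
    additional one-sided ordering constraint (e.g. P1 < P0); when it bites,
    the draw is conditioned on it (this is the only source of bias and
    applies to the subordinate parameter, never to P0).  Sampling is by
    inverse CDF, so one uniform variate is consumed per parameter and no
    admissible interval can exhaust a retry budget; an interval carrying
    essentially no probability mass marks a degenerate profile.
    """
    if not lo < mean < hi:
        raise GenerationError(
            f"mean {mean:g} outside invariant range ({lo:g}, {hi:g})"
        )
    if sd == 0:
        if mean >= extra_hi:
            raise GenerationError(
                f"degenerate draw {mean:g} violates upper constraint {extra_hi:g}"
            )
        return mean
    half = min(mean - lo, hi - mean)
    a = mean - half
    b = min(mean + half, extra_hi)
    if b <= a:
        # ordering constraint cuts below the symmetric window: fall back to
        # the full invariant range under the constraint
        a, b = lo, min(hi, extra_hi)
        if b <= a:
            raise GenerationError(
                f"empty admissible interval (range=({lo:g}, {hi:g}), "
                f"upper={extra_hi:g})"
            )
    alpha = norm.cdf((a - mean) / sd)
    beta = norm.cdf((b - mean) / sd)
    if beta - alpha < _MIN_TRUNC_MASS:
        raise GenerationError(
            f"degenerate profile: admissible interval ({a:g}, {b:g}) carries "
            f"no probability mass for N({mean:g}, {sd:g})"
        )
    u = rng.uniform(alpha, beta)
    x = mean + sd * float(norm.ppf(u))
    margin = 1e-9 * (b - a)
    return float(min(max(x, a + margin), b - margin))


def sample_suture_params(
    profile: TissueProfile,
    mode: str = "relative",
    rng: Optional[np.random.Generator] = None,
    tau_rcp: float = DEFAULT_TAU_RCP_S,
) -> SutureParams:
    """Draw one suture's realized parameters from a tissue profile.

    ``mode="absolute"`` draws the three tension levels (P0, P1, Pplat) and
    derives the first-minute loss from them; ``mode="relative"`` draws P0
    plus the ratio rows (RCP loss, plateau/P0).  Either way P0 is drawn
    first and unconditionally, so its sampling distribution is unbiased;
    ordering constraints (P1 < P0, Pplat < P1, plateau ratio < 1 - loss)
    are enforced by conditional re-draw of the subordinate quantity.
    """
    if rng is None:
        rng = np.random.default_rng()
    p0 = _draw_truncated(rng, profile.p0_mean, profile.p0_sd, *P0_RANGE_N)
    if mode == "absolute":
        # P1 must leave room for a plateau below it and the minimal CDP loss
        p1 = _draw_truncated(
            rng, profile.p1_mean, profile.p1_sd,
            MIN_CDP_LOSS_FRAC * p0, np.inf, extra_hi=p0,
        )
        pplat = _draw_truncated(
            rng, profile.pplat_mean, profile.pplat_sd, 0.0, np.inf,
            extra_hi=p1 - MIN_CDP_LOSS_FRAC * p0,
        )
        rcp_loss = (p0 - p1) / p0
        plateau = pplat
    elif mode == "relative":
        rcp_loss = _draw_truncated(
            rng, profile.rcp_loss_mean, profile.rcp_loss_sd, 0.0, 1.0
        )
        ratio = _draw_truncated(
            rng, profile.plateau_ratio_mean, profile.plateau_ratio_sd,
            0.0, 1.0, extra_hi=(1.0 - rcp_loss) - MIN_CDP_LOSS_FRAC,
        )
        plateau = ratio * p0
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'absolute' or 'relative'")
    params = SutureParams(
        tissue=profile.tissue,
        p0=p0,
        rcp_loss=rcp_loss,
        decline_per_min=profile.cdp_decline_per_min,
        plateau=plateau,
        tau_rcp=tau_rcp,
        mode=mode,
    )
    params.validate()
    return params


def mean_curve(params: SutureParams, times_s: np.ndarray) -> np.ndarray:
    """Noiseless tension at ``times_s`` (seconds from knot completion)."""
    params.validate()
    t = np.asarray(times_s, dtype=float)
    p1 = params.p1
    d = params.plateau
    a = p1 - d
    b = -np.log(1.0 - params.decline_per_min)
    y = np.empty_like(t)
    rcp = t <= 60.0
    y[rcp] = p1 + (params.p0 - p1) * np.exp(-t[rcp] / params.tau_rcp)
    y[~rcp] = d + a * np.exp(-b * (t[~rcp] - 60.0) / 60.0)
    return y


def synthesize_trace(
    params: SutureParams,
    sensor: SensorConfig = SensorConfig(),
    rng: Optional[np.random.Generator] = None,
    suture_id: Optional[str] = None,
) -> TensionTrace:
    """Generate one trace: mean curve + Gaussian noise, quantized, clipped.

    The rapid phase residual at the 1-minute joint,
    ``(P0 - P1) * exp(-60 / tau_rcp)``, must stay below 2% of P0 so the two
    curve pieces meet essentially continuously; the default ``tau_rcp`` of
    10 s guarantees that by a wide margin.
    """
    params.validate()
    residual = (params.p0 - params.p1) * np.exp(-60.0 / params.tau_rcp)
    if residual >= 0.02 * params.p0:
        raise GenerationError(
            f"tau_rcp={params.tau_rcp:g} s leaves a {residual:g} N discontinuity "
            f"at the 1-minute joint (>= 2% of P0)"
        )
    n = int(round(sensor.duration_s * sensor.sampling_hz))
    times = np.arange(n, dtype=float) / sensor.sampling_hz
    forces = mean_curve(params, times)
    if sensor.noise_sd_n > 0:
        if rng is None:
            rng = np.random.default_rng()
        forces = forces + rng.normal(0.0, sensor.noise_sd_n, size=n)
    q = sensor.quantization_step_n
    forces = np.clip(np.rint(forces / q) * q, 0.0, None)
    sid = suture_id if suture_id is not None else (params.suture_id or "synthetic")
    meta = {
        "mode": params.mode,
        "tau_rcp_s": f"{params.tau_rcp:g}",
        "quantization_step_n": f"{q:.6g}",
        "noise_sd_n": f"{sensor.noise_sd_n:g}",
    }
    return TensionTrace(
        suture_id=sid,
        tissue=params.tissue,
        times=times,
        forces=forces,
        sampling_hz=sensor.sampling_hz,
        meta=meta,
    )


def simulate_cohort(
    n_per_tissue: int = 6,
    mode: str = "relative",
    sensor: SensorConfig = SensorConfig(),
    seed: int = 0,
    profiles: Optional[Iterable[TissueProfile]] = None,
):
    """Simulate a full cohort across all tissue profiles.

    Returns ``(traces, truth, collagen)``: the generated traces, the
    ground-truth :class:`SutureParams` used for each (for recovery tests),
    and one collagen/protein measurement per suture drawn from the tissue's
    collagen distribution.  Fully reproducible from ``seed``.
    """
    if n_per_tissue < 1:
        raise ValueError("n_per_tissue must be >= 1")
    if profiles is None:
        profiles = _BUILTIN
    rng = np.random.default_rng(seed)
    traces, truth, collagen = [], [], []
    for profile in profiles:
        for i in range(n_per_tissue):
            sid = f"{profile.tissue}_{i + 1:02d}"
            params = sample_suture_params(profile, mode=mode, rng=rng)
            params = replace(params, suture_id=sid)
            traces.append(synthesize_trace(params, sensor, rng, suture_id=sid))
            truth.append(params)
            content = _draw_truncated(
                rng, profile.collagen_mean, profile.collagen_sd, 0.0, np.inf
            )
            collagen.append(
                CollagenMeasurement(suture_id=sid, tissue=profile.tissue,
                                    content=content)
            )
    return traces, truth, collagen
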
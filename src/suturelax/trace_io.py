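"""Plain-text I/O and resampling for suture-tension traces.

A trace records the force (in newtons) that a knotted suture loop exerts on
the enclosed tissue, sampled at a fixed rate from the moment the final knot
is completed.  The on-disk format is deliberately minimal and diff-able:

    # suture_id=liver_01
    # tissue=liver
    # sampling_hz=250
    # animal=rabbit_2
    time_s,force_N
    0,2.6
    0.004,2.5993
    ...

'#'-prefixed header lines carry ``key=value`` metadata (``tissue`` is
mandatory); the body is a two-column CSV with a ``time_s,force_N`` header.
Forces are always stored in newtons; grams-force only enters through the
sensor-resolution constant (see :func:`gforce_to_newton`).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "TISSUES",
    "STANDARD_GRAVITY",
    "TensionTrace",
    "TraceError",
    "TraceFormatError",
    "TraceValidationError",
    "gforce_to_newton",
    "read_trace",
    "write_trace",
    "resample_trace",
]

#: The five tissue types in which sutures were placed.
TISSUES = ("liver", "skin", "stomach", "muscle", "small_intestine")

#: Standard acceleration of gravity, m/s^2 (defines the kilogram-force).
STANDARD_GRAVITY = 9.80665


class TraceError(ValueError):
    """Base class for trace I/O and validation problems."""


class TraceFormatError(TraceError):
    """Malformed or incomplete trace file (missing/unknown metadata)."""


class TraceValidationError(TraceError):
    """Structurally parseable trace that violates a physical invariant."""


def gforce_to_newton(value: float) -> float:
    """Convert a force in grams-force to newtons (``value * 9.80665e-3``).

    The measurement set-up quotes its resolution in grams; everything else
    in the pipeline is in newtons.
    """
    return value * STANDARD_GRAVITY * 1e-3


@dataclass
class TensionTrace:
    """One suture's force-vs-time record with acquisition metadata.

    Parameters
    ----------
    suture_id
        Free-text identifier, unique within a cohort.
    tissue
        One of :data:`TISSUES`.
    times
        Sample times in seconds from knot completion, strictly increasing,
        starting in ``[0, 1)`` s.
    forces
        Tension in newtons, same length as ``times``, all finite and >= 0.
    sampling_hz
        Nominal acquisition rate.
    meta
        Free-form key/value annotations (animal id, sensor resolution, seed).
    """

    suture_id: str
    tissue: str
    times: np.ndarray
    forces: np.ndarray
    sampling_hz: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.forces = np.asarray(self.forces, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.tissue not in TISSUES:
            raise TraceFormatError(
                f"unknown tissue {self.tissue!r}; expected one of {TISSUES}"
            )
        if self.times.ndim != 1 or self.forces.ndim != 1:
            raise TraceValidationError("times and forces must be 1-D")
        if len(self.times) != len(self.forces):
            raise TraceValidationError(
                f"length mismatch: {len(self.times)} times vs "
                f"{len(self.forces)} forces"
            )
        if len(self.times) < 2:
            raise TraceValidationError("a trace needs at least 2 samples")
        if not np.all(np.diff(self.times) > 0):
            raise TraceValidationError("non-monotone time column")
        if not 0.0 <= self.times[0] < 1.0:
            raise TraceValidationError(
                f"first sample time {self.times[0]:g} s outside [0, 1) s"
            )
        if not np.all(np.isfinite(self.forces)):
            bad = int(np.flatnonzero(~np.isfinite(self.forces))[0])
            raise TraceValidationError(f"non-finite force at row {bad}")
        neg = np.flatnonzero(self.forces < 0)
        if neg.size:
            raise TraceValidationError(
                f"negative force {self.forces[neg[0]]:g} N at row {int(neg[0])}"
            )
        if not np.isfinite(self.sampling_hz) or self.sampling_hz <= 0:
            raise TraceValidationError("sampling_hz must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.times)

    @property
    def duration_s(self) -> float:
        """Nominal record length: covered span plus one sample period."""
        return float(self.times[-1] - self.times[0]) + 1.0 / self.sampling_hz

    def equals(self, other: "TensionTrace") -> bool:
        return (
            self.suture_id == other.suture_id
            and self.tissue == other.tissue
            and self.meta == other.meta
            and self.sampling_hz == other.sampling_hz
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.forces, other.forces)
        )


PathLike = Union[str, Path]


def read_trace(path: PathLike) -> TensionTrace:
    """Read a trace file written by :func:`write_trace`.

    Raises
    ------
    TraceFormatError
        If the ``tissue`` metadata key is missing or unknown.
    TraceValidationError
        For a non-monotone time column or negative forces (the error message
        names the offending row).
    """
    path = Path(path)
    meta: dict = {}
    with open(path, "r") as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, value = body.split("=", 1)
                meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        # round_trip parsing: files written at %.17g must read back bit-exact
        frame = pd.read_csv(fh, float_precision="round_trip")
    frame.columns = [c.strip() for c in frame.columns]
    if list(frame.columns) != ["time_s", "force_N"]:
        raise TraceFormatError(
            f"{path}: expected columns time_s,force_N, got {list(frame.columns)}"
        )
    tissue = meta.pop("tissue", None)
    if tissue is None:
        raise TraceFormatError(f"{path}: missing 'tissue' metadata header")
    suture_id = meta.pop("suture_id", path.stem)
    if "sampling_hz" in meta:
        sampling_hz = float(meta.pop("sampling_hz"))
    else:
        sampling_hz = 1.0 / float(np.median(np.diff(frame["time_s"].to_numpy())))
    return TensionTrace(
        suture_id=suture_id,
        tissue=tissue,
        times=frame["time_s"].to_numpy(),
        forces=frame["force_N"].to_numpy(),
        sampling_hz=sampling_hz,
        meta=meta,
    )


def write_trace(trace: TensionTrace, path: PathLike) -> Path:
    """Write ``trace`` so that :func:`read_trace` reproduces it exactly.

    Numeric columns use ``%.17g`` so float64 values round-trip bit-exactly.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# suture_id={trace.suture_id}\n")
        fh.write(f"# tissue={trace.tissue}\n")
        fh.write(f"# sampling_hz={trace.sampling_hz:.17g}\n")
        for key, value in trace.meta.items():
            fh.write(f"# {key}={value}\n")
        fh.write("time_s,force_N\n")
        np.savetxt(
            fh,
            np.column_stack([trace.times, trace.forces]),
            fmt="%.17g",
            delimiter=",",
        )
    return path


def resample_trace(trace: TensionTrace, target_hz: float) -> TensionTrace:
    """Block-mean decimation onto a uniform grid at ``target_hz``.

    Each output sample is the mean of the raw samples falling in one output
    period; its timestamp is the period's centre.  Decimation only — asking
    for a rate above the acquisition rate raises, because the pipeline never
    invents samples by interpolation.
    """
    if target_hz <= 0:
        raise TraceValidationError("target_hz must be positive")
    if target_hz > trace.sampling_hz * (1 + 1e-9):
        raise TraceValidationError(
            f"upsampling unsupported: target {target_hz:g} Hz > "
            f"acquisition {trace.sampling_hz:g} Hz"
        )
    t0 = trace.times[0]
    # Nudge guards against floor(k * hz / hz) landing one bin low.
    bins = np.floor((trace.times - t0) * target_hz + 1e-9).astype(np.int64)
    counts = np.bincount(bins)
    sums = np.bincount(bins, weights=trace.forces)
    keep = counts > 0
    forces = sums[keep] / counts[keep]
    times = t0 + (np.flatnonzero(keep) + 0.5) / target_hz
    meta = dict(trace.meta)
    meta["resampled_from_hz"] = f"{trace.sampling_hz:g}"
    return TensionTrace(
        suture_id=trace.suture_id,
        tissue=trace.tissue,
        times=times,
        forces=forces,
        sampling_hz=target_hz,
        meta=meta,
    )
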
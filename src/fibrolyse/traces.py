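"""Clot-firmness traces and ROTEM-style parameter extraction.

A rotational thromboelastometry (ROTEM) channel records clot firmness
(amplitude, mm) against time.  The parameters consumed by the fibrinolysis
classification rules are:

CT
    coagulation time: seconds from test start until the amplitude first
    reaches the 2 mm clot threshold.
A5
    amplitude 5 minutes after CT (early firmness / early lysis marker).
MCF
    maximum clot firmness reached during the run.
LI60
    lysis index at 60 min: percentage residual firmness 60 minutes after
    CT, relative to MCF.
ML
    maximum lysis: percentage drop from MCF to the lowest amplitude seen
    after MCF, over the full runtime (ML/2h on a 2-hour protocol).
breakdown time
    when the clot lyses completely (amplitude falls back below the clot
    threshold), in minutes; used to distinguish fulminant, intermediate
    and late lysis patterns.

Amplitudes between samples are obtained by linear interpolation, which is
how instrument exports at ~1 s resolution behave.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "ViscoelasticTrace",
    "TraceParameters",
    "NoClotError",
    "InsufficientRuntimeError",
    "CLOT_THRESHOLD_MM",
    "DEFAULT_RUNTIME_S",
    "compute_ct",
    "compute_mcf",
    "compute_a5",
    "compute_li60",
    "compute_ml",
    "compute_breakdown_time",
    "extract_parameters",
    "read_trace_csv",
    "write_extraction_report",
]

#: Clot-detection threshold (mm) defining CT and, symmetrically, total breakdown.
CLOT_THRESHOLD_MM = 2.0

#: Protocol runtime: measurements stopped after 120 min.
DEFAULT_RUNTIME_S = 7200.0


class NoClotError(ValueError):
    """The trace never reaches the clot-firmness threshold (flat-line run)."""


class InsufficientRuntimeError(ValueError):
    """The run ended before the requested read-out time (e.g. CT + 5 min)."""


@dataclass(frozen=True)
class ViscoelasticTrace:
    """A sampled clot-firmness curve.

    Parameters
    ----------
    times
        Sample times in seconds from test start, strictly increasing,
        ``times[0] >= 0``.
    amplitudes
        Clot firmness in mm at each sample, all ``>= 0``.
    runtime
        Total measurement duration in seconds (default 2 h).
    """

    times: np.ndarray
    amplitudes: np.ndarray
    runtime: float = DEFAULT_RUNTIME_S

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "amplitudes", a)
        if t.ndim != 1 or a.ndim != 1 or t.shape != a.shape or t.size < 2:
            raise ValueError("times and amplitudes must be 1-D, equal length >= 2")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if t[0] < 0:
            raise ValueError("times must start at or after 0")
        if np.any(a < 0):
            raise ValueError("amplitudes must be non-negative")
        if t[-1] > self.runtime + 1e-9:
            raise ValueError("samples extend beyond the stated runtime")

    def amplitude_at(self, t: float) -> float:
        """Linearly interpolated amplitude at time ``t`` (seconds)."""
        if t < self.times[0] or t > self.times[-1]:
            raise InsufficientRuntimeError(
                f"time {t:.1f} s outside sampled range "
                f"[{self.times[0]:.1f}, {self.times[-1]:.1f}] s"
            )
        return float(np.interp(t, self.times, self.amplitudes))


@dataclass(frozen=True)
class TraceParameters:
    """ROTEM parameters extracted from one trace.

    ``a5``/``li60`` are ``None`` when the run ended too early to read them;
    ``breakdown_time`` (minutes after CT) is ``None`` when the clot never
    breaks down within the run.
    """

    ct: float
    mcf: float
    ml: float
    a5: Optional[float] = None
    li60: Optional[float] = None
    breakdown_time: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ct < 0:
            raise ValueError("ct must be >= 0")
        if self.a5 is not None and not (0 <= self.a5 <= self.mcf + 1e-9):
            raise ValueError("a5 must lie in [0, mcf]")
        if self.li60 is not None and not (0 <= self.li60 <= 100):
            raise ValueError("li60 must lie in [0, 100]")
        if not (0 <= self.ml <= 100):
            raise ValueError("ml must lie in [0, 100]")
        if self.breakdown_time is not None and self.breakdown_time <= 0:
            raise ValueError("breakdown_time, when present, must be > 0")


def _first_upcross(trace: ViscoelasticTrace, threshold: float) -> Optional[float]:
    """First time the amplitude reaches ``threshold``, by linear interpolation."""
    a = trace.amplitudes
    t = trace.times
    if a[0] >= threshold:
        return float(t[0])
    idx = np.nonzero(a >= threshold)[0]
    if idx.size == 0:
        return None
    i = idx[0]
    # interpolate on the segment crossing the threshold
    frac = (threshold - a[i - 1]) / (a[i] - a[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def compute_ct(trace: ViscoelasticTrace, threshold: float = CLOT_THRESHOLD_MM) -> float:
    """Coagulation time: seconds from test start until firmness reaches ``threshold``.

    Raises
    ------
    NoClotError
        If the trace never reaches the threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    ct = _first_upcross(trace, threshold)
    if ct is None:
        raise NoClotError(f"amplitude never reaches {threshold:g} mm")
    return ct


def compute_mcf(trace: ViscoelasticTrace) -> float:
    """Maximum clot firmness (mm) over the run."""
    return float(np.max(trace.amplitudes))


def compute_a5(trace: ViscoelasticTrace, ct: float) -> float:
    """Amplitude (mm) 5 minutes after CT, linearly interpolated.

    Raises :class:`InsufficientRuntimeError` if the run ends before CT + 5 min.
    """
    return trace.amplitude_at(ct + 300.0)


def compute_li60(trace: ViscoelasticTrace, ct: float, mcf: float) -> float:
    """Lysis index at 60 min: 100 x amplitude(CT + 60 min) / MCF, in [0, 100].

    Residual firmness is taken relative to the run-maximum MCF, the
    standard ROTEM convention, which keeps LI60 and ML commensurate.
    """
    if mcf <= 0:
        raise ValueError("li60 undefined for mcf = 0")
    a = trace.amplitude_at(ct + 3600.0)
    return float(np.clip(100.0 * a / mcf, 0.0, 100.0))


def compute_ml(trace: ViscoelasticTrace, mcf: float) -> float:
    """Maximum lysis: percentage drop from MCF to the post-MCF minimum."""
    if mcf <= 0:
        raise ValueError("ml undefined for mcf = 0")
    i_max = int(np.argmax(trace.amplitudes))
    min_after = float(np.min(trace.amplitudes[i_max:]))
    return float(np.clip(100.0 * (mcf - min_after) / mcf, 0.0, 100.0))


def compute_breakdown_time(
    trace: ViscoelasticTrace,
    ct: float,
    breakdown_threshold: float = CLOT_THRESHOLD_MM,
    clock: str = "ct",
) -> Optional[float]:
    """Time of total clot breakdown, in minutes, or ``None`` if it never occurs.

    Total breakdown is the amplitude falling back below the clot threshold
    after MCF (symmetric with clot detection).  ``clock`` selects the zero
    point: ``"ct"`` (default, same clock as LI60) or ``"start"``.
    """
    if breakdown_threshold <= 0:
        raise ValueError("breakdown_threshold must be > 0")
    if clock not in ("ct", "start"):
        raise ValueError("clock must be 'ct' or 'start'")
    a = trace.amplitudes
    t = trace.times
    i_max = int(np.argmax(a))
    below = np.nonzero(a[i_max:] < breakdown_threshold)[0]
    if below.size == 0:
        return None
    i = i_max + below[0]
    if i == 0:  # never formed a clot in the first place
        return None
    # interpolate the downward crossing on the segment [i-1, i]
    frac = (a[i - 1] - breakdown_threshold) / (a[i - 1] - a[i])
    t_cross = t[i - 1] + frac * (t[i] - t[i - 1])
    origin = ct if clock == "ct" else 0.0
    return float((t_cross - origin) / 60.0)


def extract_parameters(
    trace: ViscoelasticTrace,
    clot_threshold: float = CLOT_THRESHOLD_MM,
    breakdown_clock: str = "ct",
) -> TraceParameters:
    """Extract all ROTEM parameters from a trace.

    ``a5``/``li60`` are left ``None`` (rather than raising) when the run is
    too short to read them; a flat-line trace raises :class:`NoClotError`.
    """
    ct = compute_ct(trace, clot_threshold)
    mcf = compute_mcf(trace)
    ml = compute_ml(trace, mcf)
    try:
        a5 = compute_a5(trace, ct)
    except InsufficientRuntimeError:
        a5 = None
    try:
        li60 = compute_li60(trace, ct, mcf)
    except InsufficientRuntimeError:
        li60 = None
    bt = compute_breakdown_time(trace, ct, clot_threshold, breakdown_clock)
    return TraceParameters(ct=ct, mcf=mcf, ml=ml, a5=a5, li60=li60, breakdown_time=bt)


def read_trace_csv(path: str | Path, runtime: Optional[float] = None) -> ViscoelasticTrace:
    """Read a 2-column trace CSV with header ``time_s,amplitude_mm``."""
    df = pd.read_csv(path)
    missing = {"time_s", "amplitude_mm"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    t = df["time_s"].to_numpy(float)
    if runtime is None:
        runtime = max(DEFAULT_RUNTIME_S, float(t[-1]))
    return ViscoelasticTrace(t, df["amplitude_mm"].to_numpy(float), runtime=runtime)


def write_extraction_report(
    params: Iterable[tuple[str, TraceParameters]], path: str | Path
) -> pd.DataFrame:
    """Write one CSV row per trace: id, CT, A5, MCF, LI60, ML, breakdown."""
    rows = [
        {
            "trace_id": trace_id,
            "ct_s": p.ct,
            "a5_mm": p.a5,
            "mcf_mm": p.mcf,
            "li60_pct": p.li60,
            "ml_pct": p.ml,
            "breakdown_min": p.breakdown_time,
        }
        for trace_id, p in params
    ]
    df = pd.DataFrame(
        rows,
        columns=["trace_id", "ct_s", "a5_mm", "mcf_mm", "li60_pct", "ml_pct", "breakdown_min"],
    )
    df.to_csv(path, index=False)
    return df
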
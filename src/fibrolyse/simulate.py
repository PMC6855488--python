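"""Synthetic clot-firmness traces and two-group cohorts.

No public per-subject raw data accompany the analysis this package
implements, so every pipeline stage is exercised on synthetic inputs with
the statistical structure the analysis assumes.

Trace kinetics
--------------
The clot-firmness amplitude follows a saturating-exponential formation
multiplied by a Weibull-type lysis survival:

    A(t) = MCF_true * (1 - exp(-k (t - t0)+)) * exp(-(lam (t - t0 - d)+)^g)

with lag ``t0`` (s), growth rate ``k`` (1/s), lysis onset ``d`` seconds
after ``t0``, lysis rate ``lam`` (1/s) and shape ``g`` (g = 1 is plain
exponential decay; g < 1 gives decelerating lysis, the shape real traces
show when most firmness loss happens in the first hour).  Additive
Gaussian noise is truncated at zero.  The form is an artifact choice
(instruments report traces, not models): the formation and lysis
parameters span all four severity regimes, from hypofibrinolytic plateaus
to fulminant total breakdown, and every extracted parameter has a closed
form, so parameter recovery can be tested exactly and target LI60/ML
pairs can be hit by inverting the model (:func:`params_for_li60`) — the
shape parameter is what makes pairs like (LI60 61 %, ML 47 %), where
lysis largely precedes the 60-minute read-out, reachable inside a 2-hour
run.

Cohort model
------------
:func:`simulate_cohort` draws per-subject coagulation panels for a
two-group case/control design (dogs with intracavitary effusion vs matched
effusion-free controls): normal A5, log-normal fibrinogen and D-dimer
(right-skewed, as their published median/IQR summaries imply), a
categorical 3-level FDPs assay, and LI60 as a mixture of a near-100 point
mass with an exponential left tail (most subjects barely lyse; a minority
lyse hard).  Group defaults reproduce the published group-level locations
and spreads; see :func:`effusion_group_spec` / :func:`control_group_spec`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .classify import FDPS_CATEGORIES, FIBRINOGEN_DETECTION_FLOOR, CoagulationPanel
from .traces import DEFAULT_RUNTIME_S, CLOT_THRESHOLD_MM, ViscoelasticTrace

__all__ = [
    "TraceModelParams",
    "GroupSpec",
    "simulate_trace",
    "model_amplitude",
    "analytic_ct",
    "params_for_li60",
    "simulate_cohort",
    "effusion_group_spec",
    "control_group_spec",
]


@dataclass(frozen=True)
class TraceModelParams:
    """Parameters of the formation x lysis trace model."""

    t0: float = 45.0  # clot-initiation lag, s
    k: float = 0.01  # firmness growth rate, 1/s
    mcf_true: float = 60.0  # asymptotic firmness, mm
    lysis_onset: Optional[float] = None  # s after t0; None = no lysis
    lysis_rate: float = 0.0  # 1/s
    lysis_shape: float = 1.0  # Weibull shape; 1 = exponential decay
    noise_sd: float = 0.0  # mm
    sample_interval: float = 1.0  # s
    runtime: float = DEFAULT_RUNTIME_S  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t0 < 0 or self.k <= 0 or self.mcf_true <= 0:
            raise ValueError("need t0 >= 0, k > 0, mcf_true > 0")
        if self.lysis_rate < 0 or self.noise_sd < 0 or self.sample_interval <= 0:
            raise ValueError("need lysis_rate, noise_sd >= 0 and sample_interval > 0")
        if self.lysis_shape <= 0:
            raise ValueError("lysis_shape must be > 0")
        if self.lysis_onset is not None and self.lysis_onset < 0:
            raise ValueError("lysis_onset must be >= 0 (seconds after t0)")


def model_amplitude(params: TraceModelParams, t: np.ndarray) -> np.ndarray:
    """Noise-free closed-form amplitude of the trace model at times ``t``."""
    t = np.asarray(t, float)
    formation = params.mcf_true * (1.0 - np.exp(-params.k * np.maximum(t - params.t0, 0.0)))
    if params.lysis_onset is None or params.lysis_rate == 0.0:
        return formation
    decay_t = np.maximum(t - params.t0 - params.lysis_onset, 0.0)
    return formation * np.exp(-((params.lysis_rate * decay_t) ** params.lysis_shape))


def analytic_ct(params: TraceModelParams, threshold: float = CLOT_THRESHOLD_MM) -> float:
    """Closed-form CT: first time the noise-free model reaches ``threshold``.

    Assumes lysis has not begun by CT (the generator's realistic regime).
    """
    if threshold >= params.mcf_true:
        raise ValueError("threshold at or above the model's asymptotic firmness")
    return params.t0 - np.log(1.0 - threshold / params.mcf_true) / params.k


def simulate_trace(params: TraceModelParams) -> ViscoelasticTrace:
    """Sample a trace on [0, runtime] at ``sample_interval``; seeded, reproducible."""
    t = np.arange(0.0, params.runtime + params.sample_interval / 2, params.sample_interval)
    t = t[t <= params.runtime]
    a = model_amplitude(params, t)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        a = a + rng.normal(0.0, params.noise_sd, size=a.shape)
    return ViscoelasticTrace(t, np.maximum(a, 0.0), runtime=params.runtime)


def params_for_li60(
    target_li60: float, target_ml: float, base: TraceModelParams = TraceModelParams()
) -> TraceModelParams:
    """Invert the trace model to hit target LI60 and ML values.

    The lysis onset is placed late enough that formation is essentially
    complete (>= 99.9 %), so the observed MCF is the amplitude at onset
    and afterwards A(t) ~= MCF * exp(-(lam dt)^g).  Writing d1 and d2 for
    the decay times at the LI60 read-out (CT + 60 min) and at the end of
    the run, the two targets give

        (lam d1)^g = -ln(LI60/100),   (lam d2)^g = -ln(1 - ML/100)

    whose ratio fixes the shape g = ln(R) / ln(d2/d1) with
    R = ln(1 - ML/100) / ln(LI60/100), and then the rate lam.  Targets
    with ML < 100 - LI60 (lysis at 60 min exceeding maximum lysis) are
    infeasible and raise; ML = 100 (total breakdown) has no finite-rate
    representation here, use an explicit fulminant parameter set instead.
    """
    if not 0 < target_li60 <= 100:
        raise ValueError("target_li60 must lie in (0, 100]")
    if not 0 <= target_ml < 100:
        raise ValueError("target_ml must lie in [0, 100); total breakdown has "
                         "no finite decay rate in this parameterization")
    if target_ml < 100 - target_li60:
        raise ValueError(
            f"infeasible: ML = {target_ml} < 100 - LI60 = {100 - target_li60}; "
            "lysis at 60 min cannot exceed maximum lysis"
        )
    if target_li60 == 100.0 and target_ml == 0.0:
        return replace(base, lysis_onset=None, lysis_rate=0.0)
    ct = analytic_ct(base)
    t1 = ct + 3600.0  # LI60 read-out (seconds from test start)
    if base.runtime <= t1:
        raise ValueError("runtime too short: LI60 read-out at or after run end")
    if target_li60 == 100.0:
        # decay confined to after the LI60 clock; plain exponential suffices
        lam = -np.log(1.0 - target_ml / 100.0) / (base.runtime - t1)
        return replace(
            base, lysis_onset=float(t1 - base.t0), lysis_rate=float(lam),
            lysis_shape=1.0,
        )
    onset = 7.0 / base.k  # formation >= 99.9 % complete at lysis onset
    if base.t0 + onset >= t1:
        raise ValueError("formation too slow: not complete before the LI60 clock")
    # a plateau after the LI60 read-out (ML exactly 100 - LI60) has no
    # finite Weibull shape; approximate with a hair of residual decay
    ml_eff = max(target_ml, 100.0 - target_li60 + 0.05)
    d1 = t1 - base.t0 - onset
    d2 = base.runtime - base.t0 - onset
    h1 = -np.log(target_li60 / 100.0)
    h2 = -np.log(1.0 - ml_eff / 100.0)
    shape = np.log(h2 / h1) / np.log(d2 / d1)
    lam = h1 ** (1.0 / shape) / d1
    return replace(
        base, lysis_onset=float(onset), lysis_rate=float(lam),
        lysis_shape=float(shape),
    )


# ---------------------------------------------------------------------------
# Cohort simulation


@dataclass(frozen=True)
class GroupSpec:
    """Distributional spec for one cohort arm.

    ``fibrinogen_median``/``ddimer_median`` are medians on the original
    scale with log-scale SDs (log-normal draws).  LI60 is drawn as
    100 - X with X a mixture: with probability ``li60_high_frac`` X is
    uniform on [0, ``li60_high_width``] (little to no lysis), otherwise X
    is exponential with scale ``li60_tail_scale`` (a left tail reaching
    the hyperfibrinolytic regime), truncated to keep LI60 in [0, 100].
    """

    name: str
    n: int
    a5_mean: float  # mm
    a5_sd: float
    li60_high_frac: float
    li60_high_width: float
    li60_tail_scale: float
    fibrinogen_median: float  # mg/dL
    fibrinogen_log_sd: float
    ddimer_median: float  # ug/mL
    ddimer_log_sd: float
    fdps_probs: tuple[float, float, float]
    bleeding_prob: float
    hct_mean: float = 47.0  # percent, non-bleeders
    hct_sd: float = 5.0
    hct_bleeding_mean: float = 32.0  # bleeders are anemic by construction
    hct_bleeding_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if abs(sum(self.fdps_probs) - 1.0) > 1e-9:
            raise ValueError("fdps_probs must sum to 1")
        for name in ("a5_sd", "li60_tail_scale", "fibrinogen_log_sd", "ddimer_log_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.bleeding_prob <= 1 or not 0 <= self.li60_high_frac <= 1:
            raise ValueError("probabilities must lie in [0, 1]")


def effusion_group_spec(n: int = 32, seed: int = 0) -> GroupSpec:
    """Spec emulating the effusion arm: A5 34.88 +/- 16.23 mm, fibrinogen
    median 177 mg/dL, D-dimer median 0.09 ug/mL, FDPs 9:11:12, bleeding
    13/32, and an LI60 tail reaching the published lower quartile (61 %)."""
    return GroupSpec(
        name="effusion", n=n, seed=seed,
        a5_mean=34.88, a5_sd=16.23,
        li60_high_frac=0.5, li60_high_width=5.0, li60_tail_scale=55.0,
        fibrinogen_median=177.0, fibrinogen_log_sd=0.66,
        ddimer_median=0.09, ddimer_log_sd=1.71,
        fdps_probs=(9 / 32, 11 / 32, 12 / 32),
        bleeding_prob=13 / 32,
    )


def control_group_spec(n: int = 32, seed: int = 1) -> GroupSpec:
    """Spec emulating the effusion-free control arm: A5 53.41 +/- 16.24 mm,
    fibrinogen median 371 mg/dL, D-dimer median 0.16 ug/mL, FDPs 16:8:8,
    bleeding 4/32, LI60 tightly packed near 99 %."""
    return GroupSpec(
        name="control", n=n, seed=seed,
        a5_mean=53.41, a5_sd=16.24,
        li60_high_frac=0.85, li60_high_width=3.0, li60_tail_scale=20.0,
        fibrinogen_median=371.0, fibrinogen_log_sd=0.54,
        ddimer_median=0.16, ddimer_log_sd=2.14,
        fdps_probs=(16 / 32, 8 / 32, 8 / 32),
        bleeding_prob=4 / 32,
    )


def _draw_panels(spec: GroupSpec) -> list[CoagulationPanel]:
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    a5 = np.clip(rng.normal(spec.a5_mean, spec.a5_sd, n), 1.0, 100.0)
    high = rng.random(n) < spec.li60_high_frac
    drop = np.where(
        high,
        rng.uniform(0.0, spec.li60_high_width, n),
        rng.exponential(spec.li60_tail_scale, n),
    )
    li60 = np.clip(100.0 - drop, 0.0, 100.0)
    # maximum lysis: at least the lysis already seen at 60 min, plus
    # whatever accrues over the second hour
    ml = np.clip((100.0 - li60) + rng.exponential(8.0, n), 0.0, 100.0)
    fib = np.maximum(
        rng.lognormal(np.log(spec.fibrinogen_median), spec.fibrinogen_log_sd, n),
        FIBRINOGEN_DETECTION_FLOOR,
    )
    dd = rng.lognormal(np.log(spec.ddimer_median), spec.ddimer_log_sd, n)
    fdps = rng.choice(len(FDPS_CATEGORIES), size=n, p=spec.fdps_probs)
    bleeding = rng.random(n) < spec.bleeding_prob
    hct = np.where(
        bleeding,
        rng.normal(spec.hct_bleeding_mean, spec.hct_bleeding_sd, n),
        rng.normal(spec.hct_mean, spec.hct_sd, n),
    )
    hct = np.clip(hct, 10.0, 65.0)
    # total breakdown (amplitude back below the clot threshold) occurs when
    # essentially all firmness is lost; time drawn across the three
    # pattern windows, weighted toward late lysis
    breakdown = np.full(n, np.nan)
    lysed = ml >= 97.0
    breakdown[lysed] = rng.uniform(15.0, 115.0, int(lysed.sum()))
    panels = []
    for i in range(n):
        panels.append(
            CoagulationPanel(
                subject_id=f"{spec.name}-{i + 1:03d}",
                group=spec.name,
                li60=float(round(li60[i], 1)),
                fibrinogen=float(round(fib[i], 0)),
                fdps_category=FDPS_CATEGORIES[int(fdps[i])],
                ddimer=float(round(dd[i], 3)),
                hct=float(round(hct[i], 1)),
                bleeding_event=bool(bleeding[i]),
                a5=float(round(a5[i], 1)),
                ml=float(round(ml[i], 1)),
                breakdown_time=None if np.isnan(breakdown[i]) else float(round(breakdown[i], 1)),
            )
        )
    return panels


def simulate_cohort(spec_group1: GroupSpec, spec_group2: GroupSpec) -> list[CoagulationPanel]:
    """Draw a full two-arm cohort of coagulation panels (seeded per arm)."""
    return _draw_panels(spec_group1) + _draw_panels(spec_group2)
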
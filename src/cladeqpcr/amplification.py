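"""Crossing-point (Cp) calling by the second-derivative-maximum method.

A qPCR amplification curve is baseline-corrected, smoothed, and its second
derivative with respect to cycle number is maximized; the abscissa of that
maximum is the Cp.  Cp is inversely proportional to the log of the initial
template amount, N0 = k(1+E)^-Cp, so all downstream quantification is
relative (k is never resolved).

Also here: the duplicate-agreement rule (replicates must agree within 0.25
cycles to be merged) and primer-efficiency estimation from a dilution
series (E = 10^(-1/slope) - 1, accepted when 95% <= E <= 105%).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.interpolate import make_interp_spline
from scipy.signal import savgol_filter
from scipy.stats import linregress

from .config import (
    DegenerateSeriesError,
    InsufficientDataError,
    RunConfig,
    ValidationError,
)

__all__ = [
    "AmplificationCurve",
    "CpCall",
    "EfficiencyFit",
    "call_cp",
    "merge_replicates",
    "estimate_efficiency",
]


@dataclass
class AmplificationCurve:
    """Cycle-indexed fluorescence for one well and target."""

    sample_id: str
    target: str
    well: str
    cycles: np.ndarray      # strictly increasing integers 1..n, no gaps
    fluorescence: np.ndarray  # RFU, same length
    truth: object | None = None  # generator ground truth, when simulated

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.cycles.shape != self.fluorescence.shape:
            raise ValidationError("cycles and fluorescence lengths differ")
        if self.cycles.size < 10:
            raise ValidationError("need at least 10 cycles")
        d = np.diff(self.cycles)
        if np.any(d != 1):
            raise ValidationError("cycles must be strictly increasing, no gaps")

    @property
    def n_cycles(self) -> int:
        return int(self.cycles.size)


@dataclass
class CpCall:
    """A called crossing point with QC flags.

    ``cp`` is NaN when censored (no amplification).  ``qc_flags`` may hold
    ``no_amplification``, ``late_cp`` and ``replicate_disagreement``.
    """

    sample_id: str
    target: str
    cp: float
    censored: bool = False
    second_derivative_peak_height: float = float("nan")
    qc_flags: set[str] = field(default_factory=set)
    replicate_delta: float | None = None

    @property
    def usable(self) -> bool:
        return not self.censored and "replicate_disagreement" not in self.qc_flags


@dataclass
class EfficiencyFit:
    """Standard-curve efficiency estimate for one primer set."""

    target: str
    slope: float          # cycles per log10 dilution (negative)
    efficiency: float     # fraction; 1.0 == 100%
    r_squared: float
    n_points: int
    within_acceptance: bool


def call_cp(
    curve: AmplificationCurve,
    *,
    smoothing_window: int = 7,
    smoothing_degree: int = 5,
    min_signal: float = 1.0,
    baseline_cycles: tuple[int, int] = (3, 12),
    late_cp_threshold: float = 40.0,
) -> CpCall:
    """Call the crossing point of one amplification curve.

    Pipeline: (1) fit a line to the early-cycle baseline window and subtract
    it; (2) if the corrected signal never exceeds ``min_signal`` RFU, censor
    with flag ``no_amplification``; (3) Savitzky-Golay smooth; (4) fit a
    quintic interpolating spline and maximize its second derivative on a
    0.01-cycle grid over the interior of the cycle range.  Calls at or past
    ``late_cp_threshold`` are flagged ``late_cp`` but kept.
    """
    if smoothing_window % 2 == 0 or smoothing_window < 5:
        raise ValidationError("smoothing_window must be odd and >= 5")
    if smoothing_window > curve.n_cycles:
        raise ValidationError("smoothing_window exceeds curve length")
    c = curve.cycles.astype(float)
    f = curve.fluorescence

    lo, hi = baseline_cycles
    mask = (curve.cycles >= lo) & (curve.cycles <= hi)
    if mask.sum() >= 2:
        coef = np.polyfit(c[mask], f[mask], 1)
        signal = f - np.polyval(coef, c)
    else:  # degenerate window: fall back to constant offset
        signal = f - f[:3].mean()

    if np.nanmax(signal) < min_signal:
        return CpCall(
            curve.sample_id, curve.target, float("nan"),
            censored=True, qc_flags={"no_amplification"},
        )

    # smoothing trades a small peak-position bias for noise suppression;
    # skip it when the signal carries no measurable noise so the caller
    # stays bias-free on clean curves.  Noise is estimated from a low
    # quantile of the absolute second differences: flat baseline/plateau
    # cycles populate that quantile, so curvature at the knee and the
    # exponential rise do not inflate it (0.3186 = |N(0,1)| 25% point).
    d2s = np.diff(signal, 2)
    q25 = float(np.quantile(np.abs(d2s - np.median(d2s)), 0.25))
    noise = q25 / (0.3186 * np.sqrt(6))
    if noise < 1e-4 * float(np.ptp(signal)):
        smooth = signal
    else:
        smooth = savgol_filter(signal, smoothing_window, smoothing_degree)
    spline = make_interp_spline(c, smooth, k=5)
    # interior grid: spline second derivatives are unreliable at the ends
    grid = np.arange(c[0] + 2.0, c[-1] - 2.0, 0.01)
    d2 = spline(grid, 2)
    i = int(np.argmax(d2))
    cp = float(grid[i])
    flags: set[str] = set()
    if cp >= late_cp_threshold:
        flags.add("late_cp")
    return CpCall(
        curve.sample_id, curve.target, cp,
        second_derivative_peak_height=float(d2[i]), qc_flags=flags,
    )


def call_cp_with_config(curve: AmplificationCurve, config: RunConfig) -> CpCall:
    """`call_cp` with every threshold drawn from a :class:`RunConfig`."""
    return call_cp(
        curve,
        smoothing_window=config.amp_smoothing_window,
        smoothing_degree=config.amp_smoothing_degree,
        min_signal=config.min_signal,
        baseline_cycles=(config.baseline_start, config.baseline_end),
        late_cp_threshold=config.late_cp_threshold,
    )


def merge_replicates(
    calls: Sequence[CpCall], max_delta: float = 0.25
) -> CpCall:
    """Merge technical replicates of one sample x target.

    Non-censored replicates agreeing within ``max_delta`` cycles (strictly
    less) merge to their arithmetic mean; otherwise the merged call carries
    ``replicate_disagreement`` and no Cp.  A single call passes through
    unchanged.  Censored replicates are dropped from the mean but their QC
    flags are kept.
    """
    if not calls:
        raise ValidationError("merge_replicates: empty call list")
    ids = {(c.sample_id, c.target) for c in calls}
    if len(ids) > 1:
        raise ValidationError(f"merge_replicates: mixed sample/target {ids}")
    if len(calls) == 1:
        return calls[0]

    flags = set().union(*(c.qc_flags for c in calls))
    live = [c for c in calls if not c.censored]
    sample_id, target = calls[0].sample_id, calls[0].target
    if not live:
        return CpCall(sample_id, target, float("nan"), censored=True,
                      qc_flags=flags | {"no_amplification"})
    cps = np.array([c.cp for c in live])
    delta = float(cps.max() - cps.min())
    if len(live) >= 2 and delta >= max_delta:
        return CpCall(sample_id, target, float("nan"),
                      qc_flags=flags | {"replicate_disagreement"},
                      replicate_delta=delta)
    heights = [c.second_derivative_peak_height for c in live
               if not np.isnan(c.second_derivative_peak_height)]
    return CpCall(
        sample_id, target, float(cps.mean()),
        second_derivative_peak_height=(
            float(np.mean(heights)) if heights else float("nan")
        ),
        qc_flags=flags, replicate_delta=delta if len(live) >= 2 else 0.0,
    )


def estimate_efficiency(
    dilution_cps: Iterable[tuple[float, float]],
    target: str = "",
    acceptance: tuple[float, float] = (0.95, 1.05),
) -> EfficiencyFit:
    """Fit a standard curve Cp ~ log10(dilution) and derive efficiency.

    ``dilution_cps`` holds (log10 relative concentration, Cp) pairs; at
    least three distinct dilution levels are required.  The least-squares
    slope must be negative (Cp rises as template is diluted); efficiency is
    E = 10^(-1/slope) - 1, and ``within_acceptance`` marks the 95-105%
    primer-design acceptance window.
    """
    pts = [(float(x), float(y)) for x, y in dilution_cps]
    levels = {x for x, _ in pts}
    if len(levels) < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct dilution levels, got {len(levels)}"
        )
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    fit = linregress(x, y)
    if fit.slope >= 0:
        raise DegenerateSeriesError(
            f"non-negative standard-curve slope {fit.slope:.3f}"
        )
    eff = 10.0 ** (-1.0 / fit.slope) - 1.0
    return EfficiencyFit(
        target=target,
        slope=float(fit.slope),
        efficiency=float(eff),
        r_squared=float(fit.rvalue**2),
        n_points=len(pts),
        within_acceptance=bool(acceptance[0] <= eff <= acceptance[1]),
    )
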
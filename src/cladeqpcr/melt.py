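"""Melt-curve analysis: -dF/dT profiles, Tm peak calling, taxon windows.

After amplification the product is slowly heated (65-95 degC) while
fluorescence is recorded; each amplicon species dissociates around its
melting temperature Tm, producing a peak in the negative first derivative
-dF/dT.  Single peaks denote a single amplification product (the
prerequisite for quantification); double peaks denote sequence
heterogeneity.  For the LL rbcL primer set the Tm separates the two genera
(LL Prochlorococcus 81-86 degC vs Synechococcus 88-89 degC), which turns
the melt profile into a cheap taxon classifier for cross-amplification.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

from .config import DEFAULT_TM_WINDOWS, TmWindows, ValidationError, logger

__all__ = [
    "MeltCurve",
    "MeltPeak",
    "MeltProfile",
    "derivative_profile",
    "call_peaks",
    "classify_taxon",
    "analyze_melt_curve",
    "heterogeneity_summary",
]


@dataclass
class MeltCurve:
    """Temperature-indexed fluorescence for one well and target."""

    sample_id: str
    target: str
    temperatures: np.ndarray  # degC, strictly increasing, spacing <= 0.5
    fluorescence: np.ndarray  # RFU
    truth: object | None = None  # generator ground truth, when simulated

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures.shape != self.fluorescence.shape:
            raise ValidationError("temperatures and fluorescence lengths differ")
        d = np.diff(self.temperatures)
        if self.temperatures.size < 3 or np.any(d <= 0):
            raise ValidationError("temperatures must be strictly increasing")
        if self.temperatures[-1] - self.temperatures[0] < 10.0:
            raise ValidationError("temperature span must be >= 10 degC")
        if np.max(d) > 0.5 + 1e-9:
            raise ValidationError("temperature grid spacing must be <= 0.5 degC")


@dataclass(frozen=True)
class MeltPeak:
    tm: float          # degC
    height: float      # -dF/dT units
    prominence: float  # same units
    is_major: bool = False


@dataclass
class MeltProfile:
    """Called peaks for one sample x target, major peak first."""

    sample_id: str
    target: str
    peaks: list[MeltPeak] = field(default_factory=list)
    taxon_call: str = "non_discriminative"
    taxon_flags: set[str] = field(default_factory=set)

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def profile_class(self) -> str:
        return {0: "none", 1: "single", 2: "double"}.get(self.n_peaks, "multi")

    @property
    def major(self) -> MeltPeak | None:
        return self.peaks[0] if self.peaks else None


def derivative_profile(
    curve: MeltCurve, smoothing_window: int = 21, smoothing_degree: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed -dF/dT on the interior temperature grid.

    Savitzky-Golay first derivative, negated; endpoints are trimmed by half
    a window where the filter degenerates to one-sided fits.  The default
    21-point window spans ~2 degC on the usual 0.1 degC grid — wide enough
    to suppress shot noise, narrow enough to keep 2 degC doublets apart.
    On short curves the window is clamped to a third of the grid.
    """
    if smoothing_window % 2 == 0 or smoothing_window < 5:
        raise ValidationError("smoothing_window must be odd and >= 5")
    n = curve.temperatures.size
    max_win = max(5, (n // 3) | 1)
    smoothing_window = min(smoothing_window, max_win)
    step = float(np.mean(np.diff(curve.temperatures)))
    dfdt = savgol_filter(
        curve.fluorescence, smoothing_window, smoothing_degree,
        deriv=1, delta=step,
    )
    half = smoothing_window // 2
    sl = slice(half, curve.temperatures.size - half)
    return curve.temperatures[sl], -dfdt[sl]


def call_peaks(
    temperatures: np.ndarray,
    neg_dfdt: np.ndarray,
    *,
    min_prominence_frac: float = 0.10,
    min_separation: float = 1.0,
    sample_id: str = "",
    target: str = "",
) -> MeltProfile:
    """Call Tm peaks from a -dF/dT profile.

    Local maxima at least ``min_separation`` degC apart are kept when their
    prominence reaches ``min_prominence_frac`` of the tallest peak's height.
    Tm is refined below grid resolution by quadratic interpolation through
    the three points around each maximum.  The tallest peak is major; ties
    break toward lower Tm.
    """
    t = np.asarray(temperatures, dtype=float)
    y = np.asarray(neg_dfdt, dtype=float)
    step = float(np.mean(np.diff(t)))
    distance = max(1, int(round(min_separation / step)))
    # pad ends with the profile minimum so a peak whose descent is cut off
    # by the acquisition window still gets its full prominence
    pad = y.min() - 1e-12
    ypad = np.concatenate([[pad], y, [pad]])
    idx, props = find_peaks(ypad, distance=distance, prominence=0.0)
    idx = idx - 1
    inb = (idx >= 0) & (idx < y.size)
    idx, props = idx[inb], {k: v[inb] for k, v in props.items()}
    profile = MeltProfile(sample_id, target)
    if idx.size == 0:
        return profile
    tallest = float(y[idx].max())
    if tallest <= 0:
        return profile
    keep = props["prominences"] >= min_prominence_frac * tallest
    idx, prom = idx[keep], props["prominences"][keep]
    if idx.size == 0:
        return profile

    peaks = []
    for i, p in zip(idx, prom):
        tm, h = float(t[i]), float(y[i])
        if 0 < i < y.size - 1:  # quadratic vertex through the three points
            y0, y1, y2 = y[i - 1], y[i], y[i + 1]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                off = 0.5 * (y0 - y2) / denom
                tm += off * step
                h = float(y1 - 0.25 * (y0 - y2) * off)
        peaks.append(MeltPeak(tm=tm, height=h, prominence=float(p)))
    # major first: sort by height descending, ties toward lower Tm
    peaks.sort(key=lambda pk: (-pk.height, pk.tm))
    profile.peaks = [replace(pk, is_major=(i == 0)) for i, pk in enumerate(peaks)]
    return profile


def classify_taxon(
    profile: MeltProfile,
    windows: Mapping[str, TmWindows] = DEFAULT_TM_WINDOWS,
) -> MeltProfile:
    """Assign a taxon call from the major-peak Tm and the window config.

    Non-discriminative primer sets always return ``non_discriminative``.
    For discriminative sets the major peak's window decides; a multi-peak
    profile with at least one peak in each window is called ``ambiguous``
    with both taxa in ``taxon_flags`` (mixed presence).  No peaks, or a Tm
    in neither window, is ``ambiguous``.
    """
    w = windows.get(profile.target)
    if w is None or not w.discriminative:
        profile.taxon_call = "non_discriminative"
        profile.taxon_flags = set()
        return profile

    def in_window(tm: float, win: tuple[float, float]) -> bool:
        return win[0] <= tm <= win[1]

    hits = {
        name
        for pk in profile.peaks
        for name, win in (
            ("prochlorococcus", w.prochlorococcus),
            ("synechococcus", w.synechococcus),
        )
        if in_window(pk.tm, win)
    }
    if not profile.peaks:
        profile.taxon_call = "ambiguous"
        profile.taxon_flags = {"no_peaks"}
        return profile
    if {"prochlorococcus", "synechococcus"} <= hits:
        profile.taxon_call = "ambiguous"
        profile.taxon_flags = {"prochlorococcus", "synechococcus"}
        return profile
    major = profile.major
    if in_window(major.tm, w.prochlorococcus):
        profile.taxon_call = "prochlorococcus"
    elif in_window(major.tm, w.synechococcus):
        profile.taxon_call = "synechococcus"
    else:
        profile.taxon_call = "ambiguous"
    profile.taxon_flags = hits
    return profile


def analyze_melt_curve(
    curve: MeltCurve,
    *,
    smoothing_window: int = 21,
    min_prominence_frac: float = 0.10,
    min_separation: float = 1.0,
    windows: Mapping[str, TmWindows] = DEFAULT_TM_WINDOWS,
) -> MeltProfile:
    """Full single-curve pipeline: derivative, peaks, taxon call."""
    t, d = derivative_profile(curve, smoothing_window)
    profile = call_peaks(
        t, d,
        min_prominence_frac=min_prominence_frac,
        min_separation=min_separation,
        sample_id=curve.sample_id, target=curve.target,
    )
    return classify_taxon(profile, windows)


def heterogeneity_summary(
    profiles: Sequence[MeltProfile],
    groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per target x group Tm heterogeneity statistics.

    ``groups`` maps sample_id -> group label (e.g. depth class); ``None``
    pools everything into one group ``all``.  Columns: n (profiles in the
    group), mean/sd of major-peak Tm, percentage of profiles with >= 2
    peaks, and percentage of major peaks lying more than 2 sd from the
    group-mean Tm.  Groups with fewer than two peak-bearing profiles are
    skipped (sd undefined).
    """
    rows = []
    key = lambda p: (p.target, "all" if groups is None
                     else groups.get(p.sample_id, "all"))
    table: dict[tuple[str, str], list[MeltProfile]] = {}
    for p in profiles:
        table.setdefault(key(p), []).append(p)
    for (target, group), profs in sorted(table.items()):
        n = len(profs)
        majors = np.array([p.major.tm for p in profs if p.major is not None])
        if majors.size < 2:
            logger.info(
                "heterogeneity_summary: skipping %s/%s (<2 peak-bearing "
                "profiles)", target, group,
            )
            continue
        mean, sd = float(majors.mean()), float(majors.std(ddof=1))
        n_double = sum(p.n_peaks >= 2 for p in profs)
        n_far = int(np.sum(np.abs(majors - mean) > 2 * sd)) if sd > 0 else 0
        rows.append({
            "target": target, "group": group, "n": n,
            "tm_mean": mean, "tm_sd": sd,
            "pct_double_peaks": 100.0 * n_double / n,
            "pct_nonaverage_major_peaks": 100.0 * n_far / n,
        })
    return pd.DataFrame(
        rows, columns=["target", "group", "n", "tm_mean", "tm_sd",
                       "pct_double_peaks", "pct_nonaverage_major_peaks"],
    )


def profiles_to_frame(profiles: Iterable[MeltProfile]) -> pd.DataFrame:
    """Long-form table of melt calls (one row per sample x target)."""
    rows = []
    for p in profiles:
        rows.append({
            "sample_id": p.sample_id,
            "target": p.target,
            "n_peaks": p.n_peaks,
            "tm_major": p.peaks[0].tm if p.peaks else float("nan"),
            "tm_minor": p.peaks[1].tm if p.n_peaks >= 2 else float("nan"),
            "profile_class": p.profile_class,
            "taxon_call": p.taxon_call,
        })
    return pd.DataFrame(
        rows, columns=["sample_id", "target", "n_peaks", "tm_major",
                       "tm_minor", "profile_class", "taxon_call"],
    )
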
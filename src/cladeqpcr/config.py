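"""Shared configuration, thresholds, Tm windows and error types.

Every tunable threshold of the pipeline lives in :class:`RunConfig` so a
whole analysis is reproducible from one flat key=value file plus a seed.
Output writers stamp ``config_hash`` and ``seed`` into each file header.
"""
from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping

logger = logging.getLogger("cladeqpcr")
if not logger.handlers:  # library default: stderr at INFO, no double handlers
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(name)s %(levelname)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


class ValidationError(ValueError):
    """An input object violates a structural invariant (names the field)."""


class ParseError(ValueError):
    """A file could not be parsed into valid records (names line/column)."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested computation."""


class DegenerateSeriesError(ValueError):
    """A dilution series with non-negative slope (no amplification trend)."""


@dataclass(frozen=True)
class TmWindows:
    """Per-primer-set melting-temperature windows for taxon discrimination.

    Only primer sets whose amplicons melt at genus-specific temperatures are
    ``discriminative``; for those the two windows must not overlap.  The gap
    between windows acts as an explicit ambiguity buffer.
    """

    prochlorococcus: tuple[float, float]
    synechococcus: tuple[float, float]
    discriminative: bool = False

    def __post_init__(self) -> None:
        for name in ("prochlorococcus", "synechococcus"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValidationError(f"TmWindows.{name}: interval not ordered")
        if self.discriminative:
            a, b = self.prochlorococcus, self.synechococcus
            if max(a[0], b[0]) < min(a[1], b[1]):
                raise ValidationError(
                    "TmWindows: discriminative windows must be disjoint"
                )


#: Default Tm windows.  Only the LL rbcL amplicon separates the two genera:
#: LL Prochlorococcus melts at 81-86 degC, Synechococcus at 88-89 degC; the
#: band 86-87.5 degC is an explicit ambiguous buffer.  All other primer sets
#: are non-discriminative (their amplicons melt at overlapping temperatures).
DEFAULT_TM_WINDOWS: Mapping[str, TmWindows] = {
    "rbcL-LL": TmWindows((81.0, 86.0), (87.5, 90.0), discriminative=True),
}

DEPTH_CLASSES = ("3m", "DCM", "DCM+40")
TARGETS = ("rnpB-HL", "rbcL-HL", "psbA-HL", "rnpB-LL", "rbcL-LL", "psbA-LL")


@dataclass
class RunConfig:
    """All pipeline thresholds in one place.

    Cycle-domain parameters are in cycles, temperatures in degC, signal
    levels in RFU (relative fluorescence units; the instrument scale is
    arbitrary).
    """

    # Cp calling
    baseline_start: int = 3          # first cycle of baseline linear fit
    baseline_end: int = 12           # last cycle of baseline linear fit
    amp_smoothing_window: int = 7    # Savitzky-Golay window (cycles, odd)
    amp_smoothing_degree: int = 5    # Savitzky-Golay polynomial degree
    min_signal: float = 1.0          # RFU above baseline to accept amplification
    late_cp_threshold: float = 40.0  # cp >= this is flagged late_cp (kept)
    replicate_max_delta: float = 0.25  # duplicate acceptance rule (cycles)
    # efficiency acceptance window (fractions; 0.95 = 95%)
    efficiency_min: float = 0.95
    efficiency_max: float = 1.05
    # melt analysis
    melt_smoothing_window: int = 21  # Savitzky-Golay window (points, odd)
    peak_min_prominence_frac: float = 0.10  # relative to tallest peak
    peak_min_separation: float = 1.0        # degC between called peaks
    # statistics
    alpha: float = 0.05
    # reproducibility / output
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self) -> None:
        if self.amp_smoothing_window % 2 == 0 or self.amp_smoothing_window < 5:
            raise ValidationError("amp_smoothing_window must be odd and >= 5")
        if self.melt_smoothing_window % 2 == 0 or self.melt_smoothing_window < 5:
            raise ValidationError("melt_smoothing_window must be odd and >= 5")
        if self.amp_smoothing_degree >= self.amp_smoothing_window:
            raise ValidationError("amp_smoothing_degree must be < window")
        if not 0 < self.baseline_start < self.baseline_end:
            raise ValidationError("baseline cycle range must be ordered, > 0")
        if self.replicate_max_delta <= 0:
            raise ValidationError("replicate_max_delta must be > 0")
        if not 0 < self.efficiency_min < self.efficiency_max:
            raise ValidationError("efficiency window must be ordered, > 0")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.peak_min_separation <= 0 or self.peak_min_prominence_frac <= 0:
            raise ValidationError("peak thresholds must be > 0")

    # -- flat key=value persistence -------------------------------------
    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from a flat ``key = value`` text file ('#' starts a comment)."""
        kwargs: dict[str, object] = {}
        types = {f.name: f.type for f in fields(cls)}
        casts = {"int": int, "float": float, "str": str}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in types:
                raise ParseError(f"{path}:{lineno}: unknown key {key!r}")
            try:
                kwargs[key] = casts[types[key]](value)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad value for {key}: {exc}")
        return cls(**kwargs)  # type: ignore[arg-type]

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    def config_hash(self) -> str:
        """Short stable digest of every threshold (excluding seed/outdir)."""
        skip = {"seed", "outdir"}
        blob = ";".join(
            f"{f.name}={getattr(self, f.name)!r}"
            for f in sorted(fields(self), key=lambda f: f.name)
            if f.name not in skip
        )
        return hashlib.sha1(blob.encode()).hexdigest()[:10]


def clade_of(target: str) -> str:
    """'rbcL-LL' -> 'LL'."""
    gene, _, clade = target.partition("-")
    if clade not in ("HL", "LL"):
        raise ValidationError(f"target {target!r}: expected '<gene>-HL|LL'")
    return clade


def gene_of(target: str) -> str:
    """'rbcL-LL' -> 'rbcL'."""
    return target.partition("-")[0]
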
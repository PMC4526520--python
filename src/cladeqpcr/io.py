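"""CSV readers/writers for the canonical long-format instrument dialect.

One dialect is defined for every table the pipeline consumes or emits
(instrument exports vary by firmware; a converter hook —
:func:`register_converter` — is left for vendor formats):

* amplification: well,sample_id,target,cycle,fluorescence
* melt:          well,sample_id,target,temperature,fluorescence
* Cp summary:    target,depth_class,mean,sd,n
* metadata:      survey (sample_id,station,coordinates,date,depth_class,
  depth_m,local_time) or experiment (sample_id,strain,treatment,time,
  replicate), optionally material {cDNA,gDNA}

Every writer stamps a ``# cladeqpcr config_hash=<h> seed=<s>`` header;
readers skip '#' comment lines, so write-then-read round-trips exactly.
"""
from __future__ import annotations

import re
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .amplification import AmplificationCurve, CpCall
from .config import ParseError, RunConfig, ValidationError
from .melt import MeltCurve

__all__ = [
    "read_amplification_csv",
    "read_melt_csv",
    "read_cp_table",
    "read_metadata",
    "write_table",
    "read_table",
    "curves_to_frame",
    "melt_curves_to_frame",
    "cp_calls_to_frame",
    "parse_coordinates",
    "register_converter",
]

AMP_COLUMNS = ["well", "sample_id", "target", "cycle", "fluorescence"]
MELT_COLUMNS = ["well", "sample_id", "target", "temperature", "fluorescence"]
CP_TABLE_COLUMNS = ["target", "depth_class", "mean", "sd", "n"]

_CONVERTERS: dict[str, Callable[[Path], pd.DataFrame]] = {}


def register_converter(name: str, func: Callable[[Path], pd.DataFrame]) -> None:
    """Register a vendor-export converter producing the canonical dialect."""
    _CONVERTERS[name] = func


def _read_checked(path: str | Path, required: Sequence[str],
                  numeric: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ParseError(
                f"{path}: non-numeric value in column {col!r} at data row(s) "
                f"{[int(i) + 2 for i in bad[:5]]}"  # +2: header + 1-based
            )
        df[col] = coerced
    return df


def read_amplification_csv(path: str | Path) -> list[AmplificationCurve]:
    """Read long-format amplification data into per-well curves."""
    df = _read_checked(path, AMP_COLUMNS, ["cycle", "fluorescence"])
    dup = df.duplicated(subset=["well", "sample_id", "target", "cycle"])
    if dup.any():
        raise ParseError(
            f"{path}: duplicate well x sample_id x target x cycle at data "
            f"row(s) {[int(i) + 2 for i in df.index[dup][:5]]}"
        )
    curves = []
    for (well, sample_id, target), sub in df.groupby(
            ["well", "sample_id", "target"], sort=True):
        sub = sub.sort_values("cycle")
        try:
            curves.append(AmplificationCurve(
                sample_id=str(sample_id), target=str(target), well=str(well),
                cycles=sub["cycle"].to_numpy(dtype=int),
                fluorescence=sub["fluorescence"].to_numpy(),
            ))
        except ValidationError as exc:
            raise ParseError(f"{path}: curve {well}/{sample_id}/{target}: {exc}")
    return curves


def read_melt_csv(path: str | Path) -> list[MeltCurve]:
    """Read long-format melt data into per-well curves."""
    df = _read_checked(path, MELT_COLUMNS, ["temperature", "fluorescence"])
    curves = []
    for (well, sample_id, target), sub in df.groupby(
            ["well", "sample_id", "target"], sort=True):
        sub = sub.sort_values("temperature")
        try:
            curves.append(MeltCurve(
                sample_id=str(sample_id), target=str(target),
                temperatures=sub["temperature"].to_numpy(),
                fluorescence=sub["fluorescence"].to_numpy(),
            ))
        except ValidationError as exc:
            raise ParseError(f"{path}: curve {well}/{sample_id}/{target}: {exc}")
    return curves


def read_cp_table(path: str | Path) -> pd.DataFrame:
    """Read a Cp summary table (target, depth_class, mean, sd, n)."""
    df = _read_checked(path, ["target", "depth_class", "mean"], ["mean"])
    for col in ("sd", "n"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    dup = df.duplicated(subset=["target", "depth_class"])
    if dup.any():
        raise ParseError(f"{path}: duplicate target x depth_class rows")
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata; survey or experiment layout, not both.

    Survey rows carry station/depth fields, experiment rows carry
    strain/treatment/time fields.  A ``coordinates`` column in
    degrees-decimal-minutes form ('05 0.40 N. 26 1.59 W') is parsed into
    signed decimal ``latitude``/``longitude`` columns.
    """
    df = _read_checked(path, ["sample_id"], [])
    has_survey = "station" in df.columns or "depth_class" in df.columns
    has_exp = "strain" in df.columns or "treatment" in df.columns
    if has_survey and has_exp:
        raise ParseError(f"{path}: mixed survey and experiment metadata")
    if not has_survey and not has_exp:
        raise ParseError(f"{path}: neither survey nor experiment fields present")
    if "coordinates" in df.columns:
        lat, lon = zip(*(parse_coordinates(s) for s in df["coordinates"]))
        df["latitude"], df["longitude"] = lat, lon
    df.attrs["kind"] = "survey" if has_survey else "experiment"
    return df


_COORD_RE = re.compile(
    r"^\s*(\d+)\s+(\d+(?:\.\d+)?)\s*([NS])\.?\s+(\d+)\s+(\d+(?:\.\d+)?)\s*([EW])\.?\s*$"
)


def parse_coordinates(text: str) -> tuple[float, float]:
    """Parse 'DD MM.MM N. DD MM.MM W' degrees-decimal-minutes to signed degrees."""
    m = _COORD_RE.match(str(text))
    if not m:
        raise ParseError(f"unparseable coordinates {text!r}")
    lat = int(m.group(1)) + float(m.group(2)) / 60.0
    if m.group(3) == "S":
        lat = -lat
    lon = int(m.group(4)) + float(m.group(5)) / 60.0
    if m.group(6) == "W":
        lon = -lon
    return lat, lon


# --------------------------------------------------------------------------
# writing (with provenance header)
# --------------------------------------------------------------------------
def write_table(df: pd.DataFrame, path: str | Path,
                config: RunConfig | None = None) -> Path:
    """Write a CSV with a provenance header (config hash + seed)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cfg = config or RunConfig()
    with open(path, "w") as fh:
        fh.write(f"# cladeqpcr config_hash={cfg.config_hash()} seed={cfg.seed}\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back any table written by :func:`write_table`."""
    return pd.read_csv(path, comment="#")


# --------------------------------------------------------------------------
# frame conversions (for the emit side of the generators/pipeline)
# --------------------------------------------------------------------------
def curves_to_frame(curves: Iterable[AmplificationCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for cyc, f in zip(c.cycles, c.fluorescence):
            rows.append({"well": c.well, "sample_id": c.sample_id,
                         "target": c.target, "cycle": int(cyc),
                         "fluorescence": f})
    return pd.DataFrame(rows, columns=AMP_COLUMNS)


def melt_curves_to_frame(curves: Iterable[MeltCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        well = f"{c.sample_id}:{c.target}"
        for t, f in zip(c.temperatures, c.fluorescence):
            rows.append({"well": well, "sample_id": c.sample_id,
                         "target": c.target, "temperature": t,
                         "fluorescence": f})
    return pd.DataFrame(rows, columns=MELT_COLUMNS)


def cp_calls_to_frame(calls: Iterable[CpCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append({
            "sample_id": c.sample_id, "target": c.target, "cp": c.cp,
            "censored": c.censored,
            "qc_flags": ";".join(sorted(c.qc_flags)),
            "replicate_delta": c.replicate_delta,
        })
    return pd.DataFrame(rows, columns=["sample_id", "target", "cp",
                                       "censored", "qc_flags",
                                       "replicate_delta"])
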
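"""Relative quantification: delta-Cp, fold changes, clade fractions.

All quantities are relative (the instrument detection constant k in
N0 = k(1+E)^-Cp never cancels out of an absolute count, so no copy numbers
are emitted).  Normalization is against the rnpB reference gene:

    dCp = Cp_ref - Cp_target          (higher dCp = more target per cell)
    relative expression = 2^dCp
    fold(a, b) = 2^(dCp_a - dCp_b)
    rbcL/psbA ratio = 2^(dCp_rbcL - dCp_psbA)

Treating rnpB as a proxy for metabolically active cells, the HL share of
the total population follows from the two clade-specific rnpB Cps:

    r = 2^(Cp_LL - Cp_HL),  fraction_HL = r / (1 + r)

(assuming equal per-cell rnpB expression and equal primer efficiency
across clades; a generalized (1+E)^Cp form is available for E != 1).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .config import DEPTH_CLASSES, ValidationError, gene_of, logger

__all__ = [
    "CladeFraction",
    "FoldChange",
    "delta_cp",
    "fold_change",
    "rbcl_psba_ratio",
    "clade_fraction",
    "build_quant_table",
    "survey_report",
]


@dataclass(frozen=True)
class FoldChange:
    """A base-2 copy-number ratio between two conditions."""

    context: str
    value: float
    log2_value: float


@dataclass(frozen=True)
class CladeFraction:
    """HL share of total cells inferred from clade-specific rnpB Cps."""

    sample_id: str
    cp_rnpb_hl: float
    cp_rnpb_ll: float
    fraction_hl: float
    assumes_equal_efficiency: bool = True

    @property
    def fraction_ll(self) -> float:
        return 1.0 - self.fraction_hl


def delta_cp(cp_ref: float, cp_target: float) -> float:
    """dCp = Cp_ref - Cp_target; NaN (censored) inputs propagate as NaN."""
    if cp_ref is None or cp_target is None:
        return float("nan")
    return float(cp_ref) - float(cp_target)


def fold_change(dcp_a: float, dcp_b: float, context: str = "") -> FoldChange:
    """Copy ratio 2^(dCp_a - dCp_b) between conditions a and b."""
    log2_value = float(dcp_a) - float(dcp_b)
    return FoldChange(context=context, value=2.0 ** log2_value,
                      log2_value=log2_value)


def rbcl_psba_ratio(dcp_rbcl: float, dcp_psba: float,
                    context: str = "rbcL/psbA") -> FoldChange:
    """Copy ratio between the two target genes within one sample."""
    return fold_change(dcp_rbcl, dcp_psba, context=context)


def clade_fraction(
    cp_hl: float,
    cp_ll: float,
    efficiency_hl: float = 1.0,
    efficiency_ll: float = 1.0,
    sample_id: str = "",
) -> CladeFraction:
    """HL fraction of total cells from the two clade-specific rnpB Cps.

    With N0 proportional to (1+E)^-Cp for each clade and a common detection
    constant, r = (1+E_hl)^-Cp_HL / (1+E_ll)^-Cp_LL and fraction_HL is
    r/(1+r).  At equal 100% efficiencies this reduces to r = 2^(Cp_LL -
    Cp_HL).  fraction_HL + fraction_LL = 1 by construction.
    """
    if math.isnan(cp_hl) or math.isnan(cp_ll):
        return CladeFraction(sample_id, cp_hl, cp_ll, float("nan"),
                             assumes_equal_efficiency=(
                                 efficiency_hl == efficiency_ll))
    log_r = (cp_ll * math.log(1.0 + efficiency_ll)
             - cp_hl * math.log(1.0 + efficiency_hl))
    # r/(1+r) computed as a logistic for numerical stability at extreme Cp
    frac = 1.0 / (1.0 + math.exp(-log_r))
    return CladeFraction(
        sample_id, cp_hl, cp_ll, frac,
        assumes_equal_efficiency=(efficiency_hl == efficiency_ll),
    )


def build_quant_table(
    cp_calls: pd.DataFrame,
    melt_profiles: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-sample, per-clade quantification with inclusion filters.

    ``cp_calls`` is the merged-replicate table (sample_id, target, cp,
    censored, qc_flags[, replicate_delta]).  One output row per sample x
    clade with dCp per gene, relative expression, the rbcL/psbA ratio, the
    HL clade fraction, and ``included`` — true only when every constituent
    target passed replicate QC, was not censored, and (when melt profiles
    are supplied) melted as a single peak.  Exclusions carry a reason; no
    record is silently dropped.
    """
    required = {"sample_id", "target", "cp"}
    if not required <= set(cp_calls.columns):
        raise ValidationError(
            f"cp_calls missing columns {sorted(required - set(cp_calls.columns))}"
        )
    calls = cp_calls.copy()
    if "censored" not in calls:
        calls["censored"] = calls["cp"].isna()
    if "qc_flags" not in calls:
        calls["qc_flags"] = ""
    calls["qc_flags"] = calls["qc_flags"].fillna("")

    melt_class: Mapping[tuple[str, str], str] = {}
    if melt_profiles is not None:
        melt_class = {
            (r.sample_id, r.target): r.profile_class
            for r in melt_profiles.itertuples()
        }

    rows = []
    for sample_id, sub in calls.groupby("sample_id", sort=True):
        by_target = {r.target: r for r in sub.itertuples()}

        def cp_of(target):
            r = by_target.get(target)
            if r is None or r.censored or np.isnan(r.cp):
                return float("nan")
            return float(r.cp)

        def target_ok(target):
            r = by_target.get(target)
            if r is None:
                return False, "missing_target"
            if r.censored:
                return False, "no_amplification"
            if "replicate_disagreement" in str(r.qc_flags):
                return False, "replicate_disagreement"
            if melt_profiles is not None:
                cls = melt_class.get((sample_id, target))
                if cls is None:
                    return False, "missing_melt_profile"
                if cls != "single":
                    return False, "single_peak_rule"
            return True, ""

        frac = clade_fraction(cp_of("rnpB-HL"), cp_of("rnpB-LL"),
                              sample_id=sample_id)
        for clade in ("HL", "LL"):
            ref, rbcl, psba = (f"rnpB-{clade}", f"rbcL-{clade}",
                               f"psbA-{clade}")
            if not any(t in by_target for t in (ref, rbcl, psba)):
                continue
            dcp_rbcl = delta_cp(cp_of(ref), cp_of(rbcl))
            dcp_psba = delta_cp(cp_of(ref), cp_of(psba))
            included, reasons = True, []
            for t in (ref, rbcl, psba):
                ok, reason = target_ok(t)
                if not ok:
                    included = False
                    reasons.append(f"{t}:{reason}")
            if not included:
                logger.debug("quant: %s/%s excluded (%s)",
                             sample_id, clade, ",".join(reasons))
            rows.append({
                "sample_id": sample_id,
                "clade": clade,
                "delta_cp_rbcL": dcp_rbcl,
                "delta_cp_psbA": dcp_psba,
                "rel_rbcL": 2.0 ** dcp_rbcl,
                "rel_psbA": 2.0 ** dcp_psba,
                "ratio": rbcl_psba_ratio(dcp_rbcl, dcp_psba).value,
                "included": included,
                "excluded_reason": ";".join(reasons),
                "fraction_HL": frac.fraction_hl,
            })
    return pd.DataFrame(
        rows, columns=["sample_id", "clade", "delta_cp_rbcL",
                       "delta_cp_psbA", "rel_rbcL", "rel_psbA", "ratio",
                       "included", "excluded_reason", "fraction_HL"],
    )


def survey_report(cp_summary: pd.DataFrame) -> dict:
    """Headline survey quantities from a Cp summary table.

    ``cp_summary`` has columns target, depth_class, mean[, sd, n] (one row
    per primer set x depth class).  Returns clade fractions per depth from
    the rnpB means, the depth fold contrasts for each gene/clade, and their
    integer-rounded headline forms.
    """
    need = {"target", "depth_class", "mean"}
    if not need <= set(cp_summary.columns):
        raise ValidationError(
            f"cp_summary missing columns {sorted(need - set(cp_summary.columns))}"
        )
    mean = {(r.target, r.depth_class): float(r.mean)
            for r in cp_summary.itertuples()}
    n_col = {(r.target, r.depth_class): int(r.n)
             for r in cp_summary.itertuples()} if "n" in cp_summary else {}

    def dcp(gene: str, clade: str, depth: str) -> float:
        return delta_cp(mean[(f"rnpB-{clade}", depth)],
                        mean[(f"{gene}-{clade}", depth)])

    fractions = {
        depth: clade_fraction(mean[("rnpB-HL", depth)],
                              mean[("rnpB-LL", depth)],
                              sample_id=depth).fraction_hl
        for depth in DEPTH_CLASSES
        if ("rnpB-HL", depth) in mean and ("rnpB-LL", depth) in mean
    }
    folds = {
        "HL_rbcL_3m_vs_DCM+40": fold_change(
            dcp("rbcL", "HL", "3m"), dcp("rbcL", "HL", "DCM+40")).value,
        "HL_psbA_3m_vs_DCM+40": fold_change(
            dcp("psbA", "HL", "3m"), dcp("psbA", "HL", "DCM+40")).value,
        "LL_rbcL_DCM_vs_3m": fold_change(
            dcp("rbcL", "LL", "DCM"), dcp("rbcL", "LL", "3m")).value,
        "LL_rbcL_DCM+40_vs_3m": fold_change(
            dcp("rbcL", "LL", "DCM+40"), dcp("rbcL", "LL", "3m")).value,
    }
    return {
        "fraction_hl": fractions,
        "fraction_hl_pct": {d: 100.0 * f for d, f in fractions.items()},
        "fraction_hl_pct_rounded": {d: round(100.0 * f)
                                    for d, f in fractions.items()},
        "depth_folds": folds,
        "depth_folds_rounded": {k: round(v) for k, v in folds.items()},
        "n": n_col,
    }
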
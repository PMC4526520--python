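"""Synthetic qPCR signal and study-design generators with known ground truth.

Three layers of fidelity:

* single signals — :func:`simulate_amplification` (45-cycle sigmoid
  fluorescence curves with an exact analytic crossing point) and
  :func:`simulate_melt` (65-95 degC two-state melting transitions whose
  -dF/dT peaks sit exactly at the component Tm values);
* the oceanographic survey — :func:`simulate_survey` draws per-station,
  per-depth, per-primer-set Cp values (with duplicate technical
  replicates) around the published survey summary statistics, plus melt
  curves whose LL rbcL Tm mixture emulates Synechococcus cross-
  amplification in surface water;
* the pollutant-exposure experiment — :func:`simulate_exposure` generates
  paired treatment/control delta-Cp data for the 2 strains x 2 pollutant
  mixtures x 2 exposure times x 3 replicates design, with configurable
  true fold effects per gene.

Amplification model.  Per-cycle copy numbers follow the saturating update

    N_{c+1} = (1 + E0) N_c / (1 + E0 N_c / K),

i.e. the effective per-cycle efficiency decays from E0 toward zero as the
template approaches the plateau capacity K.  This recurrence has the exact
closed form N_c = K / (1 + B (1+E0)^-c) with B = (K - N0)/N0 — a logistic
in cycle number — so the second-derivative maximum of the noiseless curve
is available analytically:

    Cp* = [ln B - ln(2 + sqrt(3))] / ln(1 + E0),

and a d-fold template ratio shifts Cp by exactly log(d)/log(1+E0).  That
closed form is the ground-truth oracle for the numerical Cp caller.

All stochastic entry points require a seed; identical seeds give
bit-identical output.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .amplification import AmplificationCurve
from .config import DEPTH_CLASSES, TARGETS, ValidationError
from .melt import MeltCurve

__all__ = [
    "AmplificationModelParams",
    "MeltComponent",
    "SurveyDesignSpec",
    "ExposureDesignSpec",
    "SurveyDataset",
    "simulate_amplification",
    "simulate_melt",
    "simulate_survey",
    "simulate_exposure",
    "DEFAULT_SURVEY_CP",
]

# Field-survey Cp summary statistics (mean, sd, n) per primer set and depth
# class: the 62-station / three-depth circumnavigation dataset that the
# survey generator reproduces by default.  Cp in cycles.
DEFAULT_SURVEY_CP: Mapping[tuple[str, str], tuple[float, float, int]] = {
    ("rnpB-HL", "3m"): (20.98, 2.34, 61),
    ("rnpB-HL", "DCM"): (22.65, 2.73, 61),
    ("rnpB-HL", "DCM+40"): (26.17, 2.57, 60),
    ("rbcL-HL", "3m"): (21.09, 2.35, 61),
    ("rbcL-HL", "DCM"): (24.05, 2.80, 61),
    ("rbcL-HL", "DCM+40"): (28.71, 2.33, 60),
    ("psbA-HL", "3m"): (16.87, 2.38, 61),
    ("psbA-HL", "DCM"): (19.85, 2.71, 61),
    ("psbA-HL", "DCM+40"): (23.64, 2.31, 60),
    ("rnpB-LL", "3m"): (26.00, 3.09, 61),
    ("rnpB-LL", "DCM"): (18.80, 1.58, 61),
    ("rnpB-LL", "DCM+40"): (20.67, 2.25, 60),
    ("rbcL-LL", "3m"): (31.83, 3.14, 61),
    ("rbcL-LL", "DCM"): (23.22, 2.63, 61),
    ("rbcL-LL", "DCM+40"): (24.84, 2.72, 60),
    ("psbA-LL", "3m"): (25.07, 3.85, 61),
    ("psbA-LL", "DCM"): (17.38, 2.51, 61),
    ("psbA-LL", "DCM+40"): (20.02, 2.85, 60),
}

# Typical field amplicon Tm (degC) per primer set; Prochlorococcus products.
DEFAULT_TM_BY_TARGET: Mapping[str, float] = {
    "rnpB-HL": 80.9,
    "rbcL-HL": 83.8,
    "psbA-HL": 81.7,
    "rnpB-LL": 86.7,
    "rbcL-LL": 84.4,
    "psbA-LL": 85.3,
}
SYN_RBCL_TM = 88.6  # Synechococcus rbcL-LL amplicon Tm (within 88-89 degC)


# --------------------------------------------------------------------------
# amplification curves
# --------------------------------------------------------------------------
@dataclass
class AmplificationModelParams:
    """Ground-truth parameters of one simulated amplification curve.

    ``n0`` initial template copies (0 is the no-template control),
    ``efficiency`` maximal per-cycle gain E0 in (0, 1], ``plateau`` the
    saturation capacity K in copies, ``fluorescence_per_copy`` the
    (arbitrary) optical gain in RFU/copy, plus a linear baseline drift and
    additive Gaussian noise.
    """

    n0: float
    efficiency: float = 1.0
    plateau: float = 1e9
    fluorescence_per_copy: float = 3e-8
    baseline_intercept: float = 2.0
    baseline_slope: float = 0.01
    noise_sd: float = 0.0
    n_cycles: int = 45
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n0 < 0:
            raise ValidationError("n0 must be >= 0")
        if not 0 < self.efficiency <= 1:
            raise ValidationError("efficiency must be in (0, 1]")
        if self.plateau <= self.n0:
            raise ValidationError("plateau must exceed n0")
        if self.n_cycles < 10:
            raise ValidationError("n_cycles must be >= 10")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    def copies(self) -> np.ndarray:
        """Noiseless per-cycle copy numbers on cycles 1..n (closed form)."""
        c = np.arange(1, self.n_cycles + 1, dtype=float)
        if self.n0 == 0:
            return np.zeros_like(c)
        growth = (1.0 + self.efficiency) ** c
        return (self.plateau * self.n0 * growth
                / (self.plateau + self.n0 * (growth - 1.0)))

    def analytic_cp(self) -> float:
        """Exact second-derivative-maximum abscissa of the noiseless curve."""
        if self.n0 == 0:
            return float("nan")
        b = (self.plateau - self.n0) / self.n0
        return float(
            (math.log(b) - math.log(2.0 + math.sqrt(3.0)))
            / math.log(1.0 + self.efficiency)
        )


def simulate_amplification(
    params: AmplificationModelParams,
    sample_id: str = "sim",
    target: str = "rnpB-HL",
    well: str = "A1",
) -> AmplificationCurve:
    """Generate one amplification curve; ground truth rides along."""
    c = np.arange(1, params.n_cycles + 1, dtype=float)
    baseline = params.baseline_intercept + params.baseline_slope * c
    f = baseline + params.fluorescence_per_copy * params.copies()
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        f = f + rng.normal(0.0, params.noise_sd, size=f.size)
    return AmplificationCurve(
        sample_id=sample_id, target=target, well=well,
        cycles=np.arange(1, params.n_cycles + 1), fluorescence=f,
        truth=params,
    )


# --------------------------------------------------------------------------
# melt curves
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class MeltComponent:
    """One amplicon species: a two-state melting transition.

    ``tm`` is the midpoint (degC), ``width`` the transition half-width
    (degC), ``amplitude`` the fluorescence released over the full
    transition (RFU).  The remaining-duplex fraction at temperature T is
    sigmoid((tm - T)/width), so -dF/dT peaks exactly at ``tm``.
    """

    tm: float
    width: float = 0.5
    amplitude: float = 10.0

    def __post_init__(self) -> None:
        if not 65.0 < self.tm < 95.0:
            raise ValidationError("tm must be in (65, 95) degC")
        if self.width <= 0:
            raise ValidationError("width must be > 0")
        if self.amplitude <= 0:
            raise ValidationError("amplitude must be > 0")


def simulate_melt(
    components: Sequence[MeltComponent],
    t_start: float = 65.0,
    t_end: float = 95.0,
    step: float = 0.1,
    noise_sd: float = 0.0,
    seed: int | None = None,
    *,
    background_intercept: float = 20.0,
    background_slope: float = -0.05,
    sample_id: str = "sim",
    target: str = "rbcL-LL",
) -> MeltCurve:
    """Generate one melt curve as a sum of two-state transitions.

    F(T) = sum_i amplitude_i * sigmoid((tm_i - T)/width_i) + a monotone
    linear background + Gaussian noise.  Zero components gives background
    only (the melt caller then reports no peaks).
    """
    if step <= 0:
        raise ValidationError("step must be > 0")
    if t_start >= t_end:
        raise ValidationError("empty temperature range")
    t = np.arange(t_start, t_end + step / 2, step)
    f = background_intercept + background_slope * (t - t_start)
    for comp in components:
        f = f + comp.amplitude * expit((comp.tm - t) / comp.width)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_sd, size=f.size)
    return MeltCurve(
        sample_id=sample_id, target=target,
        temperatures=t, fluorescence=f, truth=tuple(components),
    )


# --------------------------------------------------------------------------
# survey design
# --------------------------------------------------------------------------
@dataclass
class SurveyDesignSpec:
    """Design of a simulated station x depth x primer-set survey.

    Per-class Cp means/sds default to the published field summary.  For
    LL rbcL melt profiles, per-depth fractions control Synechococcus-like
    Tm draws (``syn_fraction``: pure Synechococcus product) and mixed
    double-peak samples (``mixed_fraction``: one product per genus).
    Defaults put the cross-amplification in surface water only, with a
    mixed-sample rate matching the observed 26.2% surface double-peak rate.
    """

    stations: int = 61
    cp_summary: Mapping[tuple[str, str], tuple[float, float, int]] = field(
        default_factory=lambda: dict(DEFAULT_SURVEY_CP)
    )
    syn_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"3m": 0.25, "DCM": 0.0, "DCM+40": 0.0}
    )
    mixed_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"3m": 0.262, "DCM": 0.0, "DCM+40": 0.0}
    )
    replicate_sd: float = 0.08   # cycles; < 0.125 so duplicates pass the QC
    tm_sd: float = 0.2           # degC jitter of single-species Tm draws
    melt_noise_sd: float = 0.05  # RFU on melt curves
    fidelity: str = "cp"         # "cp" (direct Cp draws) or "curve"
    include_melt: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stations < 1:
            raise ValidationError("stations must be >= 1")
        for m in (self.syn_fraction, self.mixed_fraction):
            for depth, frac in m.items():
                if not 0.0 <= frac <= 1.0:
                    raise ValidationError(f"fraction for {depth} not in [0,1]")
        for (target, depth), (mean, sd, _n) in self.cp_summary.items():
            if sd < 0:
                raise ValidationError(f"sd for {target}/{depth} must be >= 0")
        if self.replicate_sd < 0:
            raise ValidationError("replicate_sd must be >= 0")
        if self.fidelity not in ("cp", "curve"):
            raise ValidationError("fidelity must be 'cp' or 'curve'")


@dataclass
class SurveyDataset:
    """Simulated survey: measurements plus ground truth."""

    cp_measurements: pd.DataFrame   # sample_id,station,depth_class,target,replicate,cp
    melt_curves: list[MeltCurve]
    truth: pd.DataFrame             # sample_id,...,true_cp,true_taxon,true_tms
    metadata: pd.DataFrame          # sample_id,station,depth_class
    amplification_curves: list[AmplificationCurve] = field(default_factory=list)


def _truncated_normal(rng, mean, sd, lo, hi, max_tries=1000):
    """One draw from N(mean, sd) truncated to (lo, hi] by rejection."""
    if sd == 0:
        return float(np.clip(mean, lo + 1e-9, hi))
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lo < x <= hi:
            return float(x)
    return float(np.clip(mean, lo + 1e-9, hi))


def _curve_params_for_cp(cp: float, seed: int) -> AmplificationModelParams:
    """Invert the analytic crossing point: parameters whose Cp* equals cp."""
    plateau = 1e9
    b = (2.0 + math.sqrt(3.0)) * 2.0 ** cp  # efficiency 1: ln(1+E)=ln 2
    n0 = plateau / (1.0 + b)
    return AmplificationModelParams(
        n0=n0, efficiency=1.0, plateau=plateau, noise_sd=0.05, seed=seed
    )


def simulate_survey(spec: SurveyDesignSpec) -> SurveyDataset:
    """Draw a full survey dataset with duplicate replicates and melt curves.

    Cp draws are normal per (target, depth) class, truncated to (0, 45];
    each sample is measured twice with ``replicate_sd`` technical noise.
    LL rbcL melt curves mix Prochlorococcus-like (81-86 degC) and
    Synechococcus-like (88-89 degC) components per the design fractions;
    all other targets melt at their typical single Tm.
    """
    rng = np.random.default_rng(spec.seed)
    cp_rows, truth_rows, meta_rows = [], [], []
    melt_curves: list[MeltCurve] = []
    amp_curves: list[AmplificationCurve] = []

    for station in range(1, spec.stations + 1):
        for depth in DEPTH_CLASSES:
            sample_id = f"st{station:02d}-{depth}"
            meta_rows.append(
                {"sample_id": sample_id, "station": station,
                 "depth_class": depth}
            )
            for target in TARGETS:
                if (target, depth) not in spec.cp_summary:
                    continue
                mean, sd, _n = spec.cp_summary[(target, depth)]
                true_cp = _truncated_normal(rng, mean, sd, 0.0, 45.0)

                # taxon / melt composition
                taxon, tms = "prochlorococcus", [DEFAULT_TM_BY_TARGET[target]]
                if target == "rbcL-LL":
                    u = rng.uniform()
                    p_mix = spec.mixed_fraction.get(depth, 0.0)
                    p_syn = spec.syn_fraction.get(depth, 0.0)
                    if u < p_mix:
                        taxon = "mixed"
                        tms = [_truncated_normal(rng, 84.4, 1.0, 81.0, 86.0),
                               _truncated_normal(rng, SYN_RBCL_TM, spec.tm_sd,
                                                 88.0, 89.0)]
                    elif u < p_mix + p_syn:
                        taxon = "synechococcus"
                        tms = [_truncated_normal(rng, SYN_RBCL_TM, spec.tm_sd,
                                                 88.0, 89.0)]
                    else:
                        tms = [_truncated_normal(rng, 84.4, 1.0, 81.0, 86.0)]
                else:
                    tms = [float(rng.normal(tms[0], spec.tm_sd))]

                truth_rows.append({
                    "sample_id": sample_id, "station": station,
                    "depth_class": depth, "target": target,
                    "true_cp": true_cp, "true_taxon": taxon,
                    "true_tms": ";".join(f"{x:.3f}" for x in tms),
                })
                for rep in (1, 2):
                    cp_obs = true_cp + (
                        rng.normal(0.0, spec.replicate_sd)
                        if spec.replicate_sd > 0 else 0.0
                    )
                    cp_rows.append({
                        "sample_id": sample_id, "station": station,
                        "depth_class": depth, "target": target,
                        "replicate": rep, "cp": cp_obs,
                    })
                    if spec.fidelity == "curve":
                        params = _curve_params_for_cp(
                            cp_obs, seed=int(rng.integers(2**31))
                        )
                        amp_curves.append(simulate_amplification(
                            params, sample_id=sample_id, target=target,
                            well=f"{sample_id}:{target}:{rep}",
                        ))
                if spec.include_melt:
                    comps = [MeltComponent(tm=tm) for tm in tms]
                    melt_curves.append(simulate_melt(
                        comps, noise_sd=spec.melt_noise_sd,
                        seed=int(rng.integers(2**31)),
                        sample_id=sample_id, target=target,
                    ))

    return SurveyDataset(
        cp_measurements=pd.DataFrame(cp_rows),
        melt_curves=melt_curves,
        truth=pd.DataFrame(truth_rows),
        metadata=pd.DataFrame(meta_rows),
        amplification_curves=amp_curves,
    )


# --------------------------------------------------------------------------
# exposure design
# --------------------------------------------------------------------------
@dataclass
class ExposureDesignSpec:
    """Design of a simulated pollutant-exposure experiment.

    Full factorial: strains x treatments x times x replicates, paired
    treatment/control flasks.  ``fold_effects`` maps a gene (or a
    (gene, strain, time) cell for injected interactions) to the true
    treatment/control copy ratio; unlisted cells default to 1.  Treatment
    delta-Cp is the paired control delta-Cp plus log2(effect) plus noise.
    Default effects reflect the study-scale outcome: rbcL suppressed to
    0.82 of control, psbA essentially unchanged (1.09).
    """

    strains: tuple[str, ...] = ("MED4", "MIT9313")
    treatments: tuple[str, ...] = ("PAH", "OClP")
    times: tuple[str, ...] = ("0.5h", "24h")
    replicates: int = 3
    fold_effects: Mapping = field(
        default_factory=lambda: {"rbcL": 0.82, "psbA": 1.09}
    )
    genes: tuple[str, ...] = ("rbcL", "psbA")
    control_dcp_mean: Mapping[str, float] = field(
        default_factory=lambda: {"rbcL": -0.1, "psbA": 4.1}
    )
    control_dcp_sd: float = 0.3  # cycles, between-flask biological variation
    noise_sd: float = 0.5        # cycles, on the treatment-vs-control shift
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValidationError("replicates must be >= 2")
        for key, eff in self.fold_effects.items():
            if eff <= 0:
                raise ValidationError(f"fold effect for {key} must be > 0")

    def effect(self, gene: str, strain: str, time: str) -> float:
        if (gene, strain, time) in self.fold_effects:
            return float(self.fold_effects[(gene, strain, time)])
        return float(self.fold_effects.get(gene, 1.0))


def simulate_exposure(spec: ExposureDesignSpec) -> pd.DataFrame:
    """Paired treatment/control delta-Cp draws for the factorial design.

    Returns one row per strain x treatment x time x replicate x gene with
    columns ``dcp_control``, ``dcp_treatment``, the derived per-pair
    ``fold`` = 2^(dcp_treatment - dcp_control), and the ground-truth
    ``true_fold``.  Pairing is by flask: treatment and control share the
    biological draw.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for strain in spec.strains:
        for treatment in spec.treatments:
            for time in spec.times:
                for rep in range(1, spec.replicates + 1):
                    for gene in spec.genes:
                        base = spec.control_dcp_mean.get(gene, 0.0)
                        dcp_c = base + (
                            rng.normal(0.0, spec.control_dcp_sd)
                            if spec.control_dcp_sd > 0 else 0.0
                        )
                        eff = spec.effect(gene, strain, time)
                        dcp_t = dcp_c + math.log2(eff) + (
                            rng.normal(0.0, spec.noise_sd)
                            if spec.noise_sd > 0 else 0.0
                        )
                        rows.append({
                            "strain": strain, "treatment": treatment,
                            "time": time, "replicate": rep, "gene": gene,
                            "dcp_control": dcp_c, "dcp_treatment": dcp_t,
                            "fold": 2.0 ** (dcp_t - dcp_c),
                            "true_fold": eff,
                        })
    return pd.DataFrame(rows)
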
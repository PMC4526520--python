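# Methods

## Scope and model

The package quantifies clade-specific gene expression of *Prochlorococcus*
(high-light HL and low-light LL ecotypes) from SYBR-green qRT-PCR panels:
*rnpB* (reference), *rbcL* (carbon-fixation proxy) and *psbA* (photosystem
II proxy), one primer set per gene and clade. Everything downstream of the
raw fluorescence tables is implemented here; everything upstream (primer
design, extraction chemistry, sequencing) is out of scope.

All quantification is relative. Cp (crossing point) is tied to starting
template by N₀ = k(1+E)^(−Cp); the detection constant k is treated as
unidentifiable, so no absolute copy numbers are ever emitted. Base-2
exponentiation (E = 1) is used throughout, as the panel's primer sets are
accepted only inside the 95–105% efficiency window; `clade_fraction`
exposes the generalized (1+E)^Cp form for unequal efficiencies.

## Cp calling (second-derivative maximum)

1. Baseline: linear fit over the early-cycle window (default cycles 3–12),
   subtracted. Subtracting a line cannot move the second-derivative
   maximum; it only stabilizes the no-amplification test.
2. Censoring: if the corrected signal never exceeds `min_signal` (default
   1 RFU), the call is censored with flag `no_amplification`. Calls at
   ≥ 40 cycles are flagged `late_cp` but kept: weak LL signals in surface
   water are data, not failures.
3. Noise gate: noise is estimated from the 25% quantile of absolute second
   differences (flat baseline/plateau cycles populate that quantile; the
   knee does not). Below 10⁻⁴ of the signal range the curve is treated as
   noise-free and left unsmoothed; otherwise a Savitzky–Golay filter
   (window 7, degree 5) is applied. Degree 5 rather than the conventional
   3 because cubic smoothing biases the second-derivative peak of a
   45-cycle sigmoid by ≈ 0.2 cycles.
4. Peak: a quintic interpolating spline is fitted and its second
   derivative maximized on a 0.01-cycle grid over the interior of the
   cycle range. Spline refinement replaces 3-point quadratic
   interpolation, which leaves a 0.2–0.5-cycle bias at 1-cycle sampling.

On noiseless simulated curves the caller agrees with the generator's
closed-form crossing point to ≤ 0.07 cycles over N₀ ∈ [10², 10⁷] and
E ∈ [0.8, 1.0]; with 0.3% amplitude noise the call sd is ≈ 0.3 cycles.

Replicate QC: technical duplicates merge to their arithmetic mean when
they agree within 0.25 cycles (strictly), else the merged record carries
`replicate_disagreement` and no Cp. At sub-quarter-cycle agreement the
arithmetic-vs-geometric mean distinction is negligible.

Efficiency: least-squares slope of Cp on log₁₀ dilution,
E = 10^(−1/slope) − 1. The acceptance window [0.95, 1.05] is evaluated on
that scale. A dilution series should start well below the plateau
capacity; a top concentration within ~1% of plateau visibly bends the
standard curve.

## Melt analysis

The melt derivative −dF/dT is a Savitzky–Golay first derivative (degree 3)
over a 21-point window (~2.1 °C on the usual 0.1 °C grid), clamped to a
third of the grid on coarse curves. The wide window is deliberate: at
realistic noise a 0.7 °C derivative window passes shot noise as prominent
spurious peaks, while 2.1 °C keeps single-component Tm recovery exact,
resolves 2 °C doublets and still merges components ≤ 0.3 °C apart.

Peaks are local maxima at least 1 °C apart whose prominence reaches 10% of
the tallest peak's height (the relative threshold is a declared choice —
no instrument rule is published). Profile ends are padded with the profile
minimum before prominence measurement so peaks truncated by the 65–95 °C
acquisition window keep their full prominence. Tm is refined below grid
resolution by quadratic interpolation (the derivative peak is locally
symmetric, so this is unbiased, unlike the amplification case). The
tallest peak is major; ties break toward lower Tm.

Taxon windows: only LL *rbcL* discriminates the genera. LL
*Prochlorococcus* [81, 86] °C, *Synechococcus* [87.5, 90] °C, with
86–87.5 °C an explicit ambiguity buffer (the source ranges leave the
boundary open). A double profile with one peak per window is reported as
`ambiguous` with both taxa flagged — mixed presence, not a coin flip. All
other primer sets return `non_discriminative`; HL Tm variation reflects
strain-level heterogeneity, not genus.

Heterogeneity summaries report, per primer set × depth class: mean ± sd of
major-peak Tm, % profiles with ≥ 2 peaks, and % major peaks lying more
than 2 sd from the group mean. The single-peak-only quantification rule is
enforced as an `included` flag with a reason column, never by deleting
records.

## Quantification

ΔCp = Cp_ref − Cp_target per clade; relative expression 2^ΔCp; fold change
2^(ΔCp_a − ΔCp_b); *rbcL*/*psbA* ratio 2^(ΔCp_rbcL − ΔCp_psbA). The HL
fraction uses r = 2^(Cp_LL − Cp_HL), fraction = r/(1+r), computed as a
logistic for stability at extreme Cp differences. Two assumptions ride
along as flags: equal per-cell *rnpB* expression across clades, and equal
primer efficiency. Headline fractions and depth folds are computed from
class-mean Cps (this reproduces the published 97/6/2% and 5×/3× figures;
averaging per-sample fractions would weight stations differently).
Integer-rounded folds live only in the report layer; raw values are kept.

## Synthetic data

Amplification: per-cycle copies follow the saturating update
N_{c+1} = (1+E₀)N_c / (1 + E₀N_c/K) — per-cycle efficiency decays from E₀
toward zero as template approaches the plateau capacity K. This update was
chosen over the textbook Euler-logistic step N_{c+1} = N_c(1+E₀(1−N_c/K))
because its trajectory is *exactly* logistic in cycle number,
N_c = K/(1+B(1+E₀)^(−c)) with B = (K−N₀)/N₀, giving a closed-form crossing
point Cp* = [ln B − ln(2+√3)]/ln(1+E₀) and an exact d-fold spacing law
log(d)/log(1+E₀). (The Euler step's true second-derivative maximum sits
≈ 0.5 cycles away from the continuous-logistic formula, which would leave
the oracle ill-defined.) Fluorescence is a linear baseline plus a fixed
RFU-per-copy gain plus homoscedastic Gaussian noise; absolute RFU scale is
arbitrary, as on real instruments. N₀ = 0 is the no-template control.

Melt: each amplicon species is a two-state transition — remaining-duplex
fraction sigmoid((Tm−T)/w) — so −dF/dT peaks exactly at Tm. Default
transition half-width 0.5 °C (~1.8 °C FWHM, typical of intercalating-dye
melts; at 0.7 °C two equal components 2 °C apart are analytically
unimodal, which would make the stated resolution behavior unattainable for
any caller). Default grid 0.1 °C over 65–95 °C; monotone linear
background.

Survey: 61 stations × 3 depth classes (3 m, DCM, DCM+40) × 6 primer sets,
duplicate technical replicates (sd 0.08 cycles, so duplicates pass the
0.25-cycle rule), per-class Cp ~ Normal(mean, sd) truncated to (0, 45],
defaults = the published survey summary statistics. LL *rbcL* surface
samples carry *Synechococcus*-like Tm (88–89 °C) with probability 0.25 and
mixed double-peak products with probability 0.262, matching the observed
surface double-peak rate; ~half of surface LL *rbcL* products are then
non-*Prochlorococcus*, consistent with the sequenced-amplicon proportions.
The default "cp" fidelity draws Cp values directly; "curve" fidelity
generates full 45-cycle signals by inverting the closed-form crossing
point.

Exposure: 2 strains × 2 pollutant mixtures × 2 exposure times × 3 paired
treatment/control flasks. Treatment ΔCp = paired control ΔCp +
log₂(true fold) + noise (default 0.5 cycles); default true folds 0.82
(*rbcL*) and 1.09 (*psbA*) reflect the study-scale outcome. Interactions
are injected by keying a fold effect on (gene, strain, time).

What the generator does not emulate: sequence-dependent Tm, inhibitor
kinetics, probe chemistries other than intercalating dye,
heteroscedastic/multiplicative noise, between-station spatial correlation.
Passing tests therefore demonstrate correctness of the *analysis* under a
clean signal model, not robustness to every instrument artifact.

## Statistics

Depth contrasts: one-way ANOVA of relative expression across depth classes
per gene × clade (groups need ≥ 3 records), Kolmogorov–Smirnov normality
check on pooled standardized residuals, Tukey HSD post hoc
(statsmodels). The compact letter display assigns one letter per maximal
clique of the pairwise non-significance graph, lettered in order of lowest
group mean — deterministic, and exact for the handful of groups these
designs have. Zero-variance units are flagged degenerate rather than
tested.

Paired exposure tests: the test is the paired t on ΔCp (equivalently a
one-sample test of log₂ fold against zero, df = n−1); the reported summary
is the mean ± sd of per-pair folds 2^(ΔCp_T − ΔCp_C). Note the mean of
per-pair folds estimates the true ratio times the lognormal factor
exp(σ²ln²2/2), which the recovery tests account for.

Factorial GLM: OLS with all main effects and interactions of Treatment,
Strain, Time on the raw fold change (a log₂ option provides the
variance-stabilized alternative), type-II ANOVA table. On a balanced
design type II equals type I/III and the table is invariant to factor
ordering; the convention is recorded in the output metadata for the
imbalanced case. A constant response returns all F = 0 by convention.
Stars: * p<0.05, ** p<0.01, *** p<0.001; no correction beyond Tukey is
applied, matching the study design. Paired Wilcoxon signed-rank is
provided for cell-count style data; all-zero differences return p = 1.

Type-I calibration of all three tests is verified by simulation (500 null
replicates each) to fall in [0.03, 0.07] at α = 0.05.

## Problem sizes and determinism

Every stochastic entry point takes a seed and identical seeds give
bit-identical output. The test suite simulates at the study's own scale
(61 stations, 24-cell exposure designs, 200-pair recovery checks, 500-rep
calibration loops); the full suite runs in under two minutes on one core.

## Known limitations

- The efficiency-estimation method cited by the study is not fully
  specified there; the standard-curve slope formulation is used because
  the 95–105% acceptance window is expressed on that scale.
- The published pooled paired test has 22 pairs where the design suggests
  24; the package computes df from the pairs actually supplied and the
  acceptance script analyses the first 22 complete pairs to match.
- Tukey letters use exact clique enumeration — fine for ≤ ~10 groups, not
  meant for many-group designs.
- Clade fractions inherit the equal-expression / equal-efficiency
  assumptions; both are surfaced as output flags, not silently assumed.
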
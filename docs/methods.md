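# Methods

This note documents the models, estimators, numerical choices and synthetic
data underlying `capassays`, and what the test suite does and does not
establish about real data.

## Binding titrations

### Model

A fluorescence-quenching titration adds 1 µl aliquots of increasingly
concentrated cap-analog stock to 1.4 ml of 0.1 µM eIF4E and reads tryptophan
fluorescence after each addition (excitation 280 nm, emission 340 nm;
semi-micro cuvette with 4 mm absorption and 10 mm emission paths). Because
protein and dissociation constant are of comparable magnitude, the model is
the 1:1 ligand-depletion (tight-binding) form: the complex concentration
[cx] solves K_as([L]−[cx])(P_act−[cx]) = [cx], and

F([L]) = F(0) − [cx]·(ΔΦ + Φ_lig-free) + [L]·Φ_lig-free.

Parameters, units, defaults:

| parameter | meaning | units | default handling |
|---|---|---|---|
| K_as | association constant | µM⁻¹ | free; reported as K_D = 1000/K_as nM |
| P_act | active protein at t = 0 | µM | free, bounded to [0.2, 1.5]× nominal |
| F(0) | ligand-free fluorescence | a.u. | free |
| ΔΦ | apo − bound efficiency difference | a.u./µM | free, ≥ 0 |
| Φ_lig-free | free-ligand efficiency | a.u./µM | free, ≥ 0; fixable |

The closed form for [cx] is evaluated as the *small-root* variant
2·K·L·P / (b + √(b²−4K²LP)) with b = K(L+P)+1, which is algebraically
identical to the displayed difference form but avoids catastrophic
cancellation when [cx] ≪ [L]+P (verified against a companion-matrix
polynomial-root oracle to 10⁻¹⁰ relative over a wide log grid).

### Corrections

Per point i with cumulative volume V_i: ligand [L]_i = Σc_j·v_j/V_i, protein
P_i = P₀V₀/V_i. Corrected fluorescence
F_corr = F_obs · (V_i/V₀) · 10^((A_ex+A_em)/2) with A_ex = ε_ex·[L]·0.4 cm
and A_em = ε_em·[L]·1.0 cm. The inner-filter factor is the standard
geometric-mean correction; only the titrant's absorbance enters, since the
protein contribution is constant apart from dilution. Protein dilution is
handled by per-point P_i (the fit scales its P_act estimate by the known
dilution profile); a fixed-P mode is available and differs by < 4% at this
protocol, consistent with the smallness of the total dilution.

### Fitting and pooling

Least squares via `lmfit` (trust-region reflective), multi-started from 12
log-spaced K_as values in [10⁻³, 10³] µM⁻¹; best SSR wins, ties to the
smaller K_as; step/gradient tolerances 10⁻¹⁰ (conventions). Standard errors
are the residual-variance-scaled inverse curvature at the optimum, validated
against a parametric bootstrap. Replicates are pooled by inverse variance
(w = 1/SE², SE_pool = √(1/Σw)) — the standard meta-analytic weighting —
falling back to an unweighted mean with a flag when SEs are unavailable.
K_D SE is propagated as SE_K/K².

### Identifiability and the recovery analysis mode

A Cramér–Rao analysis at the stated protocol with 2% relative photometric
noise shows that with **all five** parameters free the information content
bounds the relative SE of K_as at ≥ 14%: K_as, P_act and ΔΦ trade off along
a near-flat valley. Experimental practice resolves this by measuring the
free ligand's fluorescence in a ligand-only control titration. The recovery
pipeline (`pipeline.fit_binding_replicates`) therefore fixes Φ_lig-free at
its known (control-measured, here: generator ground-truth) value and weights
residuals by 1/F — the maximum-likelihood weighting when noise is
proportional to signal. In this mode the bound drops to ~3–6% and the
measured median recovery error is 4–5% across K_D 5–50 nM. `fit_titration`
itself defaults to the fully free, unweighted contract; both switches are
explicit arguments.

### Titration design

`synthetic.escalating_stocks` designs stock concentrations so the total
ligand after each 1 µl aliquot lands on a log grid from 0.1× K_D up to
max(20× K_D, 4× protein): for tight binders a K_D-proportioned ceiling would
never cross the stoichiometric point, leaving K unidentifiable. One third of
the points sit below 0.3× protein (pinning F(0) and the initial slope); the
remainder span the binding transition into saturation. The default 45
aliquots keep total dilution < 4%, matching spectrofluorometric practice.

## Nucleotide quantitation

amount [µmol] = mOD/(ε·path); linear in mOD, exact Beer–Lambert round trip.
Path defaults to 1 cm. Amounts are carried at full precision; the 3
significant-figure display rounding used in reports is left to callers.

## Densitometry

Baseline: asymmetric least squares (penalty λ on the second difference,
asymmetry p; defaults λ = 10⁸, p = 0.001, 10 iterations). The stiff default
is deliberate: gel baselines drift slowly, and a compliant baseline climbs
into band flanks and eats area (at λ = 10⁵ a 9-area band loses ~18% of its
integral; at 10⁸ the bias is < 1%). Peaks are `scipy.signal.find_peaks`
local maxima with prominence ≥ 5% of the trace's dynamic range; each band is
integrated by trapezoid between its flanking valley minima (robust to
band-width variation, unlike fixed windows). Negative residual baseline is
clipped at zero inside the integration window. Saturated flat-top bands can
be flagged via an optional saturation level.

Capping efficiency is the capped band's share of capped+uncapped area.
Decapping susceptibility normalizes each timepoint's capped fraction to the
t = 0 fraction — so incomplete initial capping does not inflate apparent
decapping — and reports 1 − remaining at the 30-minute query point, clipped
to [0, 1] (a warning is raised when noise pushes remaining above 1). The
query time must be an observed timepoint; no interpolation. Both statistics
are invariant to rescaling a whole lane.

## Expression

Medium is replaced at every reading, so each luminescence value reflects one
accumulation interval and the cumulative total is a plain sum over the
16/40/64/88 h schedule; replicates missing a scheduled timepoint are dropped
with a warning. Normalization divides each replicate's total by the *mean*
of the reference cap's totals within the same cell line (per-batch default,
poolable via `by=None`), so the reference reports exactly 1 with SD equal to
its coefficient of variation. No background subtraction by default.

## Pull-down differential analysis

Pipeline order is fixed: flag cleaning → log2 + per-channel median
subtraction (zeros treated as missing; missing values never imputed) →
completeness filter (≥ 2 razor+unique peptides, all 9 reporter values) →
testing. Cleaning and normalization commute when nothing is flagged.

The test statistic per protein is d = (mean_A − mean_B)/(s + s0) with s the
Welch standard error √(v_A/3 + v_B/3) and s0 = 1 on the log2 scale; s0
damps the small-variance rows that dominate plain t-statistics. The null
distribution enumerates all 20 balanced 3-vs-3 relabelings of the six
relevant channels (10 distinct up to sign). The significance cutoff is the
smallest observed |d| whose estimated FDR — the median over relabelings of
the permuted exceedance count, divided by the observed exceedance count —
stays at or below the nominal level (0.02 default).

**Numerator floor.** With only 20 relabelings the median permuted count is
exactly 0 in the extreme tail for roughly half of all null datasets, which
would certify the top-ranked null rows at an estimated FDR of 0. The
numerator is therefore floored at 0.5 false positives. Consequence: a
cutoff can only be accepted when it calls at least 0.5/FDR rows (25 at
FDR 0.02), which is the procedure's minimum detectable set size. On null
simulations the floored procedure makes zero calls in 50/50 seeds.

**Power.** At the simulation conditions log2fc = 2, σ = 0.5, 3-vs-3,
s0 = 1, mean spike detection is ~0.84. This is a property of the statistic,
not the thresholding: an oracle threshold with clairvoyant false-discovery
control reaches only ~0.80, because with s0 = 1 the null d is heavy-tailed
(rows with small sample variance score ≈ their fold change, so the null
maximum over ~1000 rows overlaps the spike distribution). At a
TMT-more-typical σ = 0.25 the same pipeline detects ≥ 96% of such spikes.

Preferential binders of A over B are rows significant in "A vs B" with
positive log2 fold change (sign filter switchable); the intersection over
the two tetraphosphate-vs-reference comparisons and the fold-change-vs-
fold-change table reproduce the dot-plot comparison of the two resins. The
iBAQ screen flags rows at or above the 75th percentile, ties included,
missing iBAQ excluded from the percentile and flagged false.

The deposited study dataset (PRIDE PXD053198) is not redistributable here;
the acceptance check that reproduces its published 1302-group filter count
and ~91 AR-2-preferential binders runs only when `data/PXD053198/
proteinGroups.txt` is present. The counts are approximate reproduction
targets in any case, since the reference desktop tool's exact statistic
variant is unpublished.

## Synthetic data

Each generator forward-simulates the measurement its analysis stage inverts,
with ground truth returned alongside, so noiseless generation + analysis is
the identity up to solver tolerance:

- **Titrations** evaluate the binding model at the per-point diluted
  concentrations, then *divide* by the dilution and inner-filter factors the
  analysis will re-apply — correction and simulation are exact inverses by
  construction. Default noise: 2% relative Gaussian (plausible for a
  spectrofluorometer; such figures are rarely reported).
- **Lanes** are Gaussian bands (position, area, width) on a polynomial
  baseline; 1% relative noise default.
- **Decapping** is first order: cf(t) = cf(0)·e^(−kt) over 0/5/15/30/60 min,
  with capped+uncapped intensity conserved per lane before noise.
- **Plates** draw log-normal multiplicative noise (5% CV default) around
  level × time-shape × base signal over the 4-point schedule.
- **Protein groups** draw per-protein log2 baselines N(20, 2²) with channel
  noise σ = 0.5 log2 units, spike selected rows by a log2 fold change in the
  stated resin's channels, sample razor+unique peptide counts as
  2 + Poisson(3), flag background rows Bernoulli per QC category, and mask
  reporter values completely at random. MCAR is adequate because the
  completeness filter removes all incomplete rows before testing, making
  the missingness mechanism irrelevant downstream.

All generators are driven by a seeded `SimulationConfig`; identical configs
give bitwise-identical tables. The pipeline driver fans one global seed out
to per-stage seeds through `numpy` seed sequences.

What passing the synthetic suite shows: the estimators invert their own
forward models at realistic noise, with calibrated uncertainty and
controlled error rates. What it does not show: robustness to real-data
features the generators omit — fluorophore photobleaching and drift,
non-Gaussian band shapes and lane smearing, plate position effects,
reporter-ion ratio compression and interference, and structured (non-MCAR)
missingness.

## Problem sizes

Defaults were chosen so the whole suite runs in well under a minute of CPU:
titration recovery properties use 100 fits of 46-point curves; FDR null
calibration uses 50 seeded datasets of 1000 proteins; densitometry traces
are 1000 points. All are comfortably above the regime where the asymptotic
approximations involved (curvature SEs, percentile estimates) are stable.
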
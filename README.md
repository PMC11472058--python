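# capassays

Quantitative analysis of the assay panel used to characterize chemically
modified mRNA 5′-cap analogs (trinucleotides with altered oligophosphate
bridges): equilibrium cap–eIF4E binding constants from fluorescence-quenching
titrations, spectrophotometric nucleotide quantitation, gel-lane densitometry
for capping efficiency and decapping kinetics, normalized reporter-protein
expression, and differential pull-down proteomics with a moderated
permutation-FDR test. Every assay has a seeded synthetic-data generator, so
the complete pipeline is testable end to end without any external data.

It is written for biophysicists and RNA chemists who run these assays and
want the downstream numerics to be reproducible, and for analysts who need a
transparent reimplementation of the desktop-tool steps (curve fitting,
densitometry, Perseus-style differential testing).

## The models

**Binding.** eIF4E tryptophan fluorescence is quenched on cap binding. At
0.1 µM protein and dissociation constants of a few tens of nM the
free-ligand approximation fails, so the fit uses the ligand-depletion form.
Observed fluorescence at total ligand [L] and total active protein P_act:

    F([L]) = F(0) − [cx]·(ΔΦ + Φ_lig-free) + [L]·Φ_lig-free

with the complex concentration [cx] the physical root of
K_as([L]−[cx])(P_act−[cx]) = [cx]:

    [cx] = ([L]+P_act)/2 + (1 − √((K_as([L]−P_act)+1)² + 4·K_as·P_act)) / (2·K_as)

Raw readings are corrected for dilution (×V_i/V₀) and the inner-filter
effect (×10^((A_ex+A_em)/2)). Replicate K_as estimates are pooled by inverse
variance and reported as K_D = 1/K_as in nM.

**Quantitation.** amount [µmol] = mOD / (ε · path), with mOD = absorbance ×
volume (mL) and ε in L·mmol⁻¹·cm⁻¹.

**Densitometry.** A lane trace is baseline-corrected by asymmetric least
squares, peaks are detected by prominence and integrated between flanking
valleys. Capping efficiency = capped/(capped+uncapped) band areas; decapping
susceptibility at t = 1 − cf(t)/cf(0).

**Expression.** Per-replicate luminescence is summed over the 16/40/64/88 h
schedule and divided by the reference cap's mean total, giving the reference
1 ± CV by construction.

**Pull-down proteomics.** After removing decoy/site-only/contaminant groups,
log2 + per-channel median normalization, and the ≥2-razor-peptide /
9-complete-values filter, each 3-vs-3 resin comparison is scored with
d = Δmean/(s + s0) (s = Welch standard error, s0 = 1) and thresholded by a
permutation FDR over all 20 balanced relabelings at FDR = 0.02.

## Worked example

Simulate three replicate titrations of the reference cap-1 trinucleotide
(true K_D 42.1 nM) under the study protocol and recover the constant:

```python
from capassays.pipeline import fit_binding_replicates

pooled, fits = fit_binding_replicates(42.1, seeds=[1, 2, 3], noise_scale=0.02)
print(f"K_D = {pooled.kd_nM:.1f} ± {pooled.kd_se_nM:.1f} nM "
      f"(n = {pooled.n_replicates})")
```

prints

```
K_D = 43.2 ± 1.8 nM (n = 3)
```

i.e. the pooled dissociation constant recovered from noisy simulated data is
within one standard error of the 42.1 nM ground truth. The numbered scripts
under `analysis/` run the same loop for a whole panel of cap analogs
(`02_fit_binding.py`, which also reports the ~6-fold affinity gain of
tetraphosphate caps), nucleotide quantitation (`03`), densitometry (`04`),
expression (`05`), and the differential pull-down analysis (`06`), writing
their tables under `results/`. A `capassays` command-line tool exposes the
same stages (`capassays simulate`, `fit-binding`, `capping-efficiency`,
`decapping`, `expression`, `proteomics-diff`, `run`).

To analyse the deposited pull-down dataset rather than synthetic data, place
the MaxQuant `proteinGroups.txt` from PRIDE accession PXD053198 under
`data/PXD053198/` and run `capassays proteomics-diff` on it with the
`maxquant_proteingroups` dialect.

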
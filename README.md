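# eportraffic

Single-cell analysis of erythropoietin-receptor (EpoR) trafficking:
ODE model variants, cell-ensemble parameter estimation, AICc model
discrimination, profile-likelihood identifiability, and analysis of
cell-to-cell variability and its buffering by correlated transport
kinetics.

The package is aimed at quantitative cell biologists and modellers who
estimate receptor-trafficking rate constants from live-cell fluorescence
time courses of individual cells — membrane and vesicular receptor
(GFP-tagged) and labelled ligand (dye-tagged) — under a stimulation
protocol plus auxiliary photobleaching and cycloheximide experiments.

## The model

The basic network tracks six species (concentrations in nM, time in
minutes): intracellular free receptor `EpoR_i`, membrane free receptor
`EpoR_m`, membrane ligand-receptor complex `EpoR*_m`, the complex in a
recycling-endosome pool `EpoR*_RE`, and two cumulative pools of degraded
ligand (intracellular and exported). All reactions are first order;
extracellular ligand is constant (the depletion bound is ~3 % over 5 h):

    d[EpoR_i]/dt   = k_syn − k_deg·[EpoR_i] − k_ItoM·[EpoR_i] + k_MtoI·[EpoR_m] (+ B)
    d[EpoR_m]/dt   = k_ItoM·[EpoR_i] − k_MtoI·[EpoR_m] − k_on·[Epo]·[EpoR_m]
                     + k_off·[EpoR*_m] (+ A)
    d[EpoR*_m]/dt  = k_on·[Epo]·[EpoR_m] − k_off·[EpoR*_m] − k_MtoRE·[EpoR*_m]
    d[EpoR*_RE]/dt = k_MtoRE·[EpoR*_m] − (Σ exits)·[EpoR*_RE]

Four optional parts define the endosomal exits — A: recycling to the
membrane; B: recycling to the intracellular pool; C: degradation with
export of degraded ligand; D: degradation with intracellular
accumulation — giving 16 structural variants (7–11 kinetic parameters).
Reduced three-state models describe the photobleaching (5 parameters)
and cycloheximide (3 parameters) experiments.

A cell-ensemble model fits every cell jointly: `k_on`, `k_off` are
global, all trafficking rates and initial receptor concentrations are
cell specific, and penalty terms keep the mean and variance of each
log10 parameter consistent across the treatment groups. Models are
ranked by the corrected Akaike information criterion
`AICc = χ² + 2k + 2k(k+1)/(n−k−1)`; per-parameter confidence intervals
come from profile likelihood (Δχ² = 1).

Since stimulation holds the ligand constant, the system is linear and is
propagated exactly with matrix exponentials — no ODE solver tolerances
enter the fit.

## Worked example

```bash
eportraffic generate --seed 1 --out traj.csv --truth truth.json
# wrote 3876 rows for 33 cells to traj.csv

eportraffic fit-ensemble --data traj.csv --variant ACD --starts 25 \
    --seed 1 --out fit.json
```

The generated table holds 16 Epo-stimulated cells (5 observables), 10
photobleached and 7 cycloheximide-treated cells (2 observables each) on
the imaging grid 0–30 min every 5 min, then every 10 min to 300 min.
From Python:

```python
from eportraffic import GeneratorConfig, sample_cells
from eportraffic.synth import membrane_fraction
import numpy as np

cells = [c for c in sample_cells(GeneratorConfig(), seed=1) if c.condition == "epo"]
print(round(100 * np.mean([membrane_fraction(c.params) for c in cells]), 2))
# 7.33
```

i.e. on average ~7.3 % of each cell's receptor sits at the plasma
membrane before stimulation (the ensemble is calibrated around 7.6 %,
with cell-to-cell spread). Model selection over all 16 variants
(`eportraffic select-variant`) on the full default dataset recovers the
generating variant ACD (next-best: ABC), and
the covariance-removal experiment
(`eportraffic analyze --what covexp`) shows the buffering effect:
zeroing the covariances between the complex-transport rates and the
other parameters raises the CV of the 5-hour membrane-complex
concentration from ~0.44 to ~0.74.

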
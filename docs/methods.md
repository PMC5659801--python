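# Methods

## Model family

The Epo-stimulated cell is described by six ODEs over the species
`EpoR_i`, `EpoR_m`, `EpoR*_m`, `EpoR*_RE` and two cumulative
bookkeeping pools of degraded ligand (intracellular, exported). Every
reaction is first order; ligand binding is pseudo-first-order because
the extracellular ligand concentration is held constant — the amount of
ligand in the well exceeds cellular uptake by a factor of ~30
(`fraction_ligand_internalized`, ~3 % over 5 h). The two bookkeeping
states are retained in every variant (identically zero when the
corresponding parts are absent), so each of the 16 variants has exactly
six state equations; the variant only decides which exit reactions
leave the recycling-endosome pool. Events (ligand addition, the bleach
pulse, synthesis shut-off) are handled by restarting the propagation at
segment boundaries, never by discontinuous terms inside the right-hand
side.

Because the system is linear for a fixed stimulus, trajectories are
computed exactly with augmented-matrix exponentials (one `expm` per
piecewise-constant segment; regular grids reuse matrix powers). A
stiff LSODA path exists as an independent cross-check; the direct
linear steady-state solve agrees with long-time integration to 1e-8
relative error (tested). The matrix of the receptor subsystem is
Metzler, so the exact propagator preserves non-negativity by
construction.

Reduced three-state models describe the auxiliary experiments. The
bleach model adds a first-order loss moving fluorescent receptor from
both pools into a cumulative dark pool during a configurable pulse
window (default 0.5 min starting at t = 5 min, `k_bleach` per cell).
The CHX model removes synthesis from the treatment time on and tracks
cumulative degraded receptor. Bleached/degraded pools carry no
fluorescence signal.

## Observables and error model

Observables are linear in the states with one shared scaling factor per
observable (unit scales for synthetic data): membrane GFP is free plus
bound membrane receptor; vesicular GFP the intracellular pool; the
colocalized channel the endosomal complex; membrane dye the membrane
complex; cytoplasmic dye the endosomal complex plus intracellularly
accumulated degraded ligand (the dye survives proteolysis).

The measurement error is `sigma = sigma_rel * max(pred, floor) +
sigma_abs`. For fitting synthetic data the defaults are `sigma_rel =
0.1`, `sigma_abs = 0` and `floor` equal to 1 % of the per-observable
data maximum: the generator's noise is purely multiplicative, and an
additive error term of the kind appropriate for background-limited
microscopy data would mis-specify the likelihood, deflate chi-square
(~700 for ~1500 points) and bias AICc toward under-parameterized
variants. `sigma_abs_frac` remains a configuration knob for real data
with additive background. An observable whose data are identically
zero carries no information and receives a unit absolute error so its
residuals stay defined.

## Ensemble fitting

`k_on` and `k_off` are global (biophysical constants of the
ligand-receptor pair, by default fixed at 0.1 /nM/min and 0.1 /min and
not profiled); every trafficking rate and the two initial receptor
concentrations are cell specific. Optimization is bounded trust-region
least squares on log10 parameters (rates in [1e-6, 1e3], initial
concentrations in [1e-3, 1e3] nM), from Latin-hypercube multistarts.
All starts are evaluated; a configurable subset of the most promising
is refined under an evaluation budget and the leaders are polished to
convergence — at desk scale (25 starts) the defaults refine the best 8
and polish the top 3–5.

Distribution constraints add `w * [(mean_g - mean_g')^2 +
(var_g - var_g')^2]` over the log10 values of every parameter type
shared between two treatment groups (k_deg, k_ItoM, k_MtoI everywhere;
k_syn between stimulation and bleach). With `w = 0` and fixed globals
the joint optimum separates exactly across cells and each cell is
fitted independently; with `w > 0` the separable optimum seeds a joint
refinement with a sparse finite-difference Jacobian (hierarchical
two-stage fit). The default weight is 1.0. Note that with groups of
only a handful of cells the variance-matching term is driven by sample
variances of 2–5 values and can act perversely when one group contains
an outlier cell; conclusions that depend on the constraint should be
checked at realistic group sizes.

AICc uses the total number of fitted data points and the number of
free parameters (per-cell kinetics and initial concentrations, plus
globals/scales when these are released); the penalized objective stands
in for -2 log-likelihood, whose data-dependent constant cancels in
differences on the same dataset. Variant selection fits all 16
variants; the joint constrained refinement is spent on the top six
variants after the separable screen — the screen's AICc gaps beyond
that are orders of magnitude larger than what the refinement can move.
Bleach/CHX cell subproblems are identical across variants and are
fitted once.

The sequential parameter-fixing ladder greedily shares one parameter
type across all cells per step (smallest or largest AICc increase;
ties broken lexicographically), refitting warm-started after each
fixing; `k_syn` always stays cell specific to carry abundance
differences.

## Profile likelihood

Profiles step a parameter in log10 space with an adaptive step
targeting ~0.1 objective units per step (at most 50 steps per
direction), re-optimizing nuisance parameters warm-started from the
neighbouring grid point; threshold crossings are refined by root
finding. The interval is pointwise 1-sigma (delta chi-square = 1). A
profile that reaches a box bound below the threshold marks the
parameter open on that side (lower bound "includes zero", upper bound
"infinite"); such parameters are non-identifiable.

For decoupled ensembles the profile of a cell parameter reduces
exactly to the cell's own subproblem. For constraint-coupled ensembles
the default is a conditional profile: only the profiled cell's
parameters are re-optimized, the other cells stay at their best fit and
the penalty is re-evaluated. The full joint re-optimization is
available (`others="reoptimize"`) but is costly and, at desk scale,
dominated by multistart convergence noise; the conditional profile is
the package's default trade-off and is what the identifiability
comparisons report. In those comparisons both fits are anchored at a
converged optimum, and the constraint weight is raised to 10 because at
groups of 3–5 cells a weight of 1 contributes negligible curvature
relative to the 1-sigma threshold.

## Synthetic data generator

The generator emulates the study layout: 16 Epo-stimulated cells with
five observables, 10 photobleached and 7 CHX-treated cells with two
observables each, all sampled on the imaging grid (0–30 min every
5 min, then every 10 min to 300 min; 2720 stimulation-condition points).
Per-cell kinetic parameters are drawn from one multivariate log-normal
regardless of condition; initial states are each cell's own ligand-free
steady state; noise is i.i.d. multiplicative log-normal
(`sigma_rel = 0.1`). Per-cell volumes (log-normal, mean 5.47 pl,
CV 0.2) support amount-level statistics.

Default log10 medians (per min; k_syn in nM/min): k_syn 0.4, k_deg
0.01, k_ItoM 0.011, k_MtoI 0.144, k_MtoRE 0.25, k_REtoM 0.06,
k_deg_REtoEx 0.03, k_deg_REtoI 0.01, k_bleach 3.0; global k_on
0.1 /nM/min, k_off 0.1 /min (ligand Kd 1 nM); stimulation at 4.2 nM.
The k_MtoI/k_ItoM median ratio (13.11) is calibrated analytically so
the ensemble-mean membrane receptor fraction is 7.6 %. Spreads
(log10 SD 0.30–0.45) and the correlation structure — pairwise 0.9 among
the four transport rates, 0.95 between synthesis and degradation, 0.85
between degradation-with-export and the transport block, 0.3 for
degradation-with-accumulation — are calibrated jointly (log-sensitivity
analysis plus Monte Carlo at design time) so the emergent statistics
match the experimentally reported ones: kinetic-parameter CVs 0.78–1.4,
output-concentration CVs ~0.44 for both complex pools at 5 h, rising to
~0.74/0.85 when the complex-transport covariances are removed. These
values ship as the defaults and define the study conditions for all
tests.

What passing tests on this generator do *not* show: robustness to
imaging artefacts, segmentation errors, background fluorescence,
non-stationary noise, or model misspecification — the generator's cells
obey the fitted model class exactly.

## Problem sizes and numerical choices

Desk-scale experiments use 25 multistarts; variant-recovery experiments
run ten replicate studies of 6 + 4 + 3 cells; parameter-recovery runs
the full 33-cell default dataset with ~200 profiles. Finite-difference
control coefficients use central differences with a 1 % relative step.
The covariance-removal experiment samples 1000 parameter vectors
(bootstrap Monte-Carlo standard errors reported). Nearest-PSD repair
(eigenvalue clipping) is applied — and flagged — whenever covariance
estimation or surgery yields an indefinite matrix.

Two calibration-adjacent facts worth knowing. First, the control
coefficient of `k_syn` equals one exactly: the model is linear with
source `k_syn`, so every concentration is proportional to it; "all
coefficients below one" can only refer to the remaining rates. Second,
a pointwise 1-sigma profile interval has nominal coverage 68.3 %;
measured coverage of generating values on the default dataset is ~70 %,
i.e. the intervals behave like correctly calibrated 1-sigma intervals
rather than conservative ones.

## Known limitations

No ligand depletion, no spatial resolution, no stochastic kinetics, no
maturation/photophysics of the fluorophores. SBML import/export is not
provided. The global binding rates are treated as known constants
rather than estimated (they are practically non-identifiable from
these observables). Joint profile likelihood over a coupled ensemble
is supported but not the default; see above.
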
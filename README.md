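# perfbayes

Voxel-wise tracer-kinetic quantification of myocardial perfusion from
dynamic contrast-enhanced MRI, for researchers who want per-voxel
myocardial blood flow (MBF) maps with uncertainty instead of noisy point
estimates.

The package fits the two-compartment exchange model (2CXM)

    v_p dC_p/dt = F_p (C_AIF(t - τ0) - C_p) + PS (C_e - C_p)
    v_e dC_e/dt = PS (C_p - C_e),        C(t) = v_p C_p + v_e C_e

to concentration time-series two ways:

- **Multi-start bounded least squares** (`PerfusionNLLS`): L-BFGS-B under
  physiological box constraints, restarted from random initial points,
  reporting the lowest-cost successful fit — the standard baseline, with
  its characteristic failed fits and flow outliers faithfully accounted.
- **Hierarchical Bayesian MCMC** (`PerfusionMCMC`): Metropolis–Hastings
  with a conjugate Gibbs step for the noise variance, per-voxel
  hyperparameters `α` so the F_b and PS prior means adapt to healthy or
  ischaemic tissue (`F_b | α_b ~ N(α_b, 0.1)`, `α_b ~ U[0.001, 7]`), and
  an edge-preserving Laplace Markov-random-field prior on weighted
  parameter differences between 4-neighbour voxels. Posterior maps carry
  the median, the coefficient of variation, and the Gelman–Rubin R
  statistic across chains.

A simulation-phantom generator (6×6 slices mimicking rest, stress, and
stress with two disconnected perfusion defects; gamma-variate-based AIF
with recirculation; Rician noise at SNR 15) and a Monte-Carlo evaluation
harness (per-parameter NMSE, Mann–Whitney U comparisons, outlier and
failure accounting) complete the validation loop. See `docs/methods.md`
for the model, sampler and phantom details.

## Worked example

```python
from perfbayes import PerfusionMCMC, build_phantom, simulate_series

phantom = build_phantom("stress_defect")          # truth: F_b=3.5, defects at 1.0
sim = simulate_series(phantom, snr=15, seed=42)   # Rician noise, dt=0.012 min
model = PerfusionMCMC.from_synthetic(sim, n_steps=2000, burn_in=1000)
result = model.fit(seed=7, chains=2)
print(result.summary())
```

prints

```
2CXM hierarchical Bayesian fit
  chains: 2  steps: 2000  burn-in: 1000
  post-burn-in block acceptance: 0.248
  max R-hat over voxels/parameters: 1.2681
                 median    q25     q75     CoV
parameter
F_b (mL/min/mL)   3.362  3.163   3.456 0.07241
v_p             0.08196 0.0804 0.08383 0.06735
v_e               0.163 0.1611  0.1646 0.03534
PS (mL/min/mL)     0.95 0.9232  0.9702 0.07057
```

The slice-median flow (3.36 mL/min/mL) sits close to the healthy truth
of 3.5 with a 7% posterior coefficient of variation, and the flow map
`result.maps["fb"]` shows the two implanted defects recovered at their
true rest-level flow (≈ 1.05–1.09) against the healthy background:

```
[[3.03 3.19 3.38 3.34 3.34 3.39]
 [3.19 1.07 1.07 3.52 3.48 3.47]
 [3.18 1.07 1.06 3.46 3.39 3.19]
 [3.12 3.29 3.48 3.42 3.46 3.31]
 [3.45 3.53 3.65 3.38 1.05 3.46]
 [3.31 3.45 3.45 3.54 1.09 3.  ]]
```

The same data fitted with `PerfusionNLLS` shows the baseline's
speckle and occasional flow outliers that motivate the Bayesian
approach.

## Command line

```bash
perfbayes simulate --condition stress_defect --snr 15 --n-realisations 5 --seed 42 --out sims/
perfbayes fit-bayes --in sims/realisation_000.npz --steps 4000 --burn-in 1000 --chains 2 --seed 7 --out posterior
perfbayes fit-nlls  --in sims/realisation_000.npz --n-starts 100 --seed 7 --out fits
perfbayes evaluate  --n-realisations 5 --steps 2000 --seed 1 --out report/
perfbayes demo-costsurface --out scratch/costsurface.png
```

Every command writes a JSON manifest (resolved settings, seeds, package
version) beside its outputs. Dynamic series are stored as NPZ (or NIfTI)
with an explicit `(t, y, x)` axis-order tag; AIFs as two-column CSV;
study settings round-trip through YAML (`perfbayes.io.StudyConfig`).

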
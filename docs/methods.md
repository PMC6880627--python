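# Methods

## The model

Each voxel of a dynamic contrast-enhanced myocardial perfusion series is
modelled with the two-compartment exchange model (2CXM): a plasma
compartment of fractional volume `v_p` fed by the arterial input function
(AIF) at plasma flow `F_p`, exchanging tracer with an interstitial
compartment of fractional volume `v_e` at rate `PS`
(permeability–surface-area product):

    v_p dC_p/dt = F_p (C_AIF(t - tau0) - C_p) + PS (C_e - C_p)
    v_e dC_e/dt = PS (C_p - C_e)

The measured tissue concentration is `C = v_p C_p + v_e C_e`, equal to
`F_p (R_F * C_AIF(. - tau0))(t)` with the bi-exponential residue function
`R_F` obtained by eigen-decomposition of the 2×2 rate matrix (eigenvalues
are always real; the coincident-root case is handled by a symmetric
eigenvalue split far below sampling error). Units: minutes, mL/min/mL, mM.

**Haematocrit convention.** `F_p = F_b/(1 - Hct)` with `Hct = 0` by
default, i.e. `F_b` is read as a plasma-equivalent flow. This is not
cosmetic: at a stress flow of 3.5 mL/min/mL, applying `Hct = 0.45` gives
`F_p = 6.4` and a plasma transit time below one sample at `dt = 0.012`
min, pushing the model into the flow-limited regime where the Cramér–Rao
bound for `F_b` is ≈ 2.1 mL/min/mL — flow would be unrecoverable by any
estimator at SNR 15. With the plasma-equivalent reading the bound is
0.7 (stress) / 0.17 (rest), matching the accuracies this package
demonstrates. `hct` is a parameter everywhere for whole-blood use.

**Discretisation.** The fast 2CXM eigenvalue at stress is ~95/min, so
`R_F` decays by `e^{-1.1}` within a single sample; grid-level quadrature
(rectangle or trapezoid) is off by percent-level errors. The forward
operator instead convolves each exponential kernel with the
piecewise-linear interpolant of the AIF exactly (closed-form per-interval
integrals, evaluated as a first-order IIR recursion), matching a stiff
ODE integration of the compartment system to ~1e-10 relative error.
Sub-grid delays `tau0` linearly interpolate the shifted AIF; on-grid
delays are exact sample shifts.

## The simulation phantom

6×6-voxel slices with piecewise-constant truth maps: stress
`(F_b, v_p, v_e, PS) = (3.5, 0.08, 0.16, 1.0)`; rest lowers `F_b` to 1.0;
the stress-defect slice plants two 4-connectivity-disconnected low-flow
(`F_b = 1.0`) blocks (2×2 and 2×1, separated by healthy voxels) in a
healthy stress slice. Curves are sampled at `dt = 0.012` min (stress) /
`0.017` min (rest) over `T = 3` min, and corrupted with Rician noise
(magnitude of a complex Gaussian perturbation) with
`sigma = max(clean tissue curves)/SNR`, `SNR = 15`.

**The AIF** (`population_aif`) is a compact first-pass gamma-variate
bolus (shape 4, scale 0.02 min ≈ 5 s FWHM — a pre-dispersion
left-ventricular bolus from a power injection; peak 5 mM), plus a
delayed, 3×-dispersed second pass at 20% amplitude, plus a slowly
decaying equilibrium plateau (0.5 mM, 10 min decay). Both tail terms
matter: without them the blood and tissue concentrations decay to zero
long before 3 minutes and the Rician magnitude floor
(`E[|noise|] = sigma sqrt(pi/2)`) dominates ~60% of the samples — the
global least-squares optimum then sits at a false slow-washout parameter
set for every realisation. Without a compact first pass, flow information
is erased (CRLB analysis above). A plain first-pass-only gamma-variate
AIF remains available (`gamma_variate_aif`).

**What the phantom does not emulate:** imaging physics (saturation
prepulse, k-space truncation, signal nonlinearity), motion, bolus
dispersion differences between voxels, anatomically shaped myocardium,
and inflow artefacts. Passing tests therefore show correctness of the
estimators under the stated noise and kinetics, not robustness to the
full error structure of patient data.

## Least-squares baseline

Voxel-wise minimisation of the mean squared residual
`chi^2 = (1/N) sum_j (C_theta(t_j) - y_j)^2` with L-BFGS-B under box
constraints `0.001 ≤ F_b ≤ 6`, `0.001 ≤ v_p ≤ 0.3`, `0.001 ≤ v_e ≤ 0.4`,
`0.001 ≤ PS ≤ 4`, restarted from initial points drawn uniformly in the
box (1 or 100 starts). A start is successful when the optimiser converges
(relative cost decrease < 1e-8 within 1000 iterations) and no parameter
ends at a bound; the reported fit is the lowest-cost successful start,
or the flagged lowest-cost attempt if none succeeded. Each voxel draws
its starts from an RNG stream spawned from the master seed, independent
of iteration order. `tau0` is fixed externally (phantoms: the simulation
truth; in vivo a bolus-arrival estimate) — fitting it as a fifth
parameter was tested and found to multiply the rest-condition flow
scatter by an order of magnitude.

## Hierarchical Bayesian model

Per voxel i: Gaussian i.i.d. likelihood with voxel variance `sigma_i^2`;
priors `F_b | alpha_b ~ N(alpha_b, 0.1)`, `PS | alpha_PS ~ N(alpha_PS, 0.1)`,
`v_p ~ U(0, 0.3]`, `v_e ~ U(0, 0.4]`, `sigma^2 ~ Inv-Gamma(0.001, 0.001)`;
flat hyperpriors `alpha_b ~ U[0.001, 7]`, `alpha_PS ~ U[0.001, 5]` so the
prior mean adapts per voxel (healthy vs ischaemic) instead of being fixed
a priori; and an edge-preserving Laplace (L1) Markov-random-field penalty
with rate 5 on weighted parameter differences between 4-neighbour voxels
(missing neighbours at the mask border are replaced by in-mask diagonal
voxels, then by the nearest in-mask voxel). The MRF weight of parameter k
is the inverse of the voxel's previous sample of that parameter, floored
at 0.001, so all four parameters contribute on comparable scales. `F_b`
and `PS` are additionally constrained positive (the kinetics require it
and the weights presuppose it). The non-hierarchical comparator freezes
`F_b ~ N(X, 0.2)` (X = 3.5 or 1.0) and `PS ~ N(1, 0.2)` with no
hyperprior step. A `spatial_norm` exponent p ∈ [1, 2] switches the MRF
penalty between Laplace (p=1, default) and Gaussian (p=2) for
edge-preservation comparisons.

### Sampler

Raster sweep over voxels; per voxel the kinetic block
`(F_b, v_p, v_e, PS)` is proposed jointly by a Gaussian random walk and
accepted as one block; `sigma_i^2` is drawn exactly from its conjugate
Inverse-Gamma conditional `IG(c + N/2, d + SSR/2)`; the voxel's
`(alpha_b, alpha_PS)` get their own random-walk block. Neighbour values
in the MRF term are the neighbours' most recent samples
(Gibbs-within-MH). Default chains: 4000 steps, burn-in 1000 (desk-scale
studies here use 2000/1000); posterior maps report the median, the
coefficient of variation (sd/mean), and the Gelman–Rubin R statistic
across independently seeded chains.

Three burn-in-only devices make the random walk sample this posterior;
all are frozen (or expired) before the retained samples begin, so the
post-burn-in kernel is the plain MH/Gibbs scheme:

1. **Curvature-preconditioned proposals.** The likelihood confines the
   kinetic block to a curved ridge (flow trades against the volume
   fractions) with cross-section aspect ratios of order 10^3; isotropic
   proposals freeze on it. The proposal covariance is
   `(2.38^2/4) (J'J/sigma^2 + prior precision)^-1` from the model
   Jacobian at the current state, recomputed every 100 burn-in sweeps.
2. **Scale tuning.** Per-voxel step-size factors are scaled ×1.1 / ÷1.1
   every 50 burn-in sweeps to steer block acceptance into [0.2, 0.3],
   bracketing the 0.234 random-walk optimum; the achieved post-burn-in
   block acceptance is recorded and is 0.23–0.26 in the phantom studies.
3. **Variance tempering.** During the first 60% of burn-in, `sigma^2` is
   floored at a geometrically decaying fraction of the initial misfit,
   so the conjugate draws cannot collapse the likelihood onto the ridge
   before the chain has traversed it (on noise-free data `sigma^2`
   otherwise anneals to ~1e-5 within tens of sweeps and the chain stops
   moving).

**Initialisation.** Chains start at low flow
`(F_b, v_p, v_e, PS) = (0.5, 0.05, 0.1, 0.5)`, `sigma^2` at the
pre-contrast baseline variance, hyperparameters at their support
midpoints. The flow ridge is one-sided — steep below the true flow, flat
above it — so approaching from below anchors burn-in at the identifiable
ridge entry; from a mid-range start a 2000-step chain is still descending
the flat ridge when sampling begins (a 10000-step chain converges to the
same posterior either way; the long-run marginal concentrates near the
truth through the ridge-volume effect).

## Evaluation

Per realisation and parameter,
`NMSE_k = mean_voxels((est_k - true_k)^2) / mean_voxels(true_k^2)`
(scale-invariant, so the four parameters are comparable); "all" is the
mean of the four per-parameter NMSEs. Methods are compared with the
two-sided Mann–Whitney U test on per-realisation NMSE values (exact null
for n+m ≤ 20 without ties, normal approximation with tie correction
otherwise). Flagged (failed) least-squares fits enter the NMSE with
their best-attempt values — dropping them would flatter the baseline.
Outlier accounting uses the `F_b > 5` mL/min/mL rule. The Monte-Carlo
study fixes one noisy realisation per (condition, realisation) pair and
feeds the identical data to every method; all randomness descends from a
single master seed, and reports carry per-condition results alongside
the pooled ones.

**Study sizes.** The bundled desk-scale study uses n = 5 realisations
per condition and 2000-step chains (burn-in 1000); the full-scale
configuration (n = 20, 4000 steps) is a parameter change in
`monte_carlo_study` or the CLI.

## Known limitations

- At SNR 15 the upper flow ridge is genuinely flat: voxel-wise
  least squares occasionally escapes to `F_b` 3–6 with tiny `v_p`
  (the outlier/failed-fit pathology this package exists to quantify);
  only the Bayesian posterior's volume effect and priors suppress it.
- The MRF treatment is pseudo-likelihood (each voxel conditions on its
  neighbours' latest samples), not a joint MRF acceptance.
- `tau0` is not sampled or fitted; it must be supplied.
- R-hat uses the classic between/within form without rank
  normalisation; with a single chain it is not reported.
- 2-D (in-slice) neighbourhoods only.
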
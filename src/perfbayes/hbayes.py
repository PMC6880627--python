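"""Hierarchical Bayesian 2CXM inference by Metropolis–Hastings sampling.

Each voxel i carries kinetic parameters Theta_i = (F_b, v_p, v_e, PS), a
noise variance sigma_i^2 and hyperparameters alpha_i = (alpha_b, alpha_PS).
The posterior factorises as likelihood x prior x hyperprior:

  * likelihood: i.i.d. Gaussian residuals, y_i(t_j) ~ N(C_Theta_i(t_j), sigma_i^2);
  * F_b | alpha_b ~ N(alpha_b, 0.1) and PS | alpha_PS ~ N(alpha_PS, 0.1),
    with flat hyperpriors alpha_b on [0.001, 7] and alpha_PS on [0.001, 5]
    so the prior mean adapts per voxel (healthy vs ischaemic) instead of
    being fixed a priori;
  * v_p uniform on (0, 0.3], v_e uniform on (0, 0.4];
  * sigma^2 ~ Inverse-Gamma(c=0.001, d=0.001) (flat, conjugate);
  * an edge-preserving Markov-random-field prior: Laplace (L1) penalty with
    rate 5 on weighted differences between 4-neighbour voxels, the weight
    of parameter k being the inverse of the voxel's previous sample of that
    parameter (so all four parameters contribute on comparable scales).

Sampling scheme: raster sweep over voxels; per voxel the four kinetic
parameters are proposed jointly by a Gaussian random walk and accepted as
one block; sigma^2 is drawn exactly from its conjugate Inverse-Gamma
conditional; the hyperparameters get their own random-walk block.  During
burn-in, per-voxel proposal scales are rescaled by x1.1 / /1.1 every 50
sweeps to steer block acceptance into [0.2, 0.3] (around the 0.234
random-walk optimum), then frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .kinetics import DEFAULT_HCT, ForwardOperator, KineticParams, SampledCurve

__all__ = [
    "PriorSpec",
    "NeighbourGraph",
    "ChainState",
    "PosteriorSummary",
    "log_likelihood",
    "log_prior",
    "log_hyperprior",
    "build_neighbour_graph",
    "run_mcmc",
    "summarize",
    "gelman_rubin",
]

PARAM_NAMES = ("fb", "vp", "ve", "ps")


@dataclass(frozen=True)
class PriorSpec:
    """Constants of the prior, hyperprior and spatial model.

    With ``hierarchical=False`` the hyperparameters are frozen at
    ``(fb_mean, ps_mean)`` and no hyperprior step is run (the fixed-prior
    comparator, F_b ~ N(X, 0.2), PS ~ N(1.0, 0.2)).
    """

    hierarchical: bool = True
    fb_var: float = 0.1
    ps_var: float = 0.1
    fb_mean: float = 3.5  # used only when hierarchical=False
    ps_mean: float = 1.0  # used only when hierarchical=False
    vp_support: tuple[float, float] = (0.0, 0.3)
    ve_support: tuple[float, float] = (0.0, 0.4)
    sigma2_shape: float = 0.001  # c
    sigma2_scale: float = 0.001  # d
    spatial_rate: float = 5.0  # 1/0.2; 0 disables the spatial prior
    spatial_norm: float = 1.0  # p of the GGMRF penalty: 1 Laplace, 2 Gaussian
    alpha_b_support: tuple[float, float] = (0.001, 7.0)
    alpha_ps_support: tuple[float, float] = (0.001, 5.0)
    weight_floor: float = 0.001
    likelihood_on: bool = True  # test hook: False samples the prior alone

    def __post_init__(self) -> None:
        if self.fb_var <= 0 or self.ps_var <= 0:
            raise ValueError("prior variances must be positive")
        if self.sigma2_shape <= 0 or self.sigma2_scale <= 0:
            raise ValueError("Inverse-Gamma parameters must be positive")
        if self.spatial_rate < 0:
            raise ValueError("spatial_rate must be non-negative")
        if not 1.0 <= self.spatial_norm <= 2.0:
            raise ValueError("spatial_norm must lie in [1, 2]")

    def nonhierarchical(self, fb_mean: float = 3.5) -> "PriorSpec":
        """Fixed-prior comparator with F_b ~ N(fb_mean, 0.2), PS ~ N(1, 0.2)."""
        return replace(
            self,
            hierarchical=False,
            fb_mean=fb_mean,
            ps_mean=1.0,
            fb_var=0.2,
            ps_var=0.2,
        )


@dataclass(frozen=True)
class NeighbourGraph:
    """Per-voxel neighbour lists over a 2-D myocardial mask."""

    voxels: tuple  # masked voxel coordinates in raster order
    neighbours: dict  # voxel -> tuple of neighbour voxels

    def index_lists(self) -> list[np.ndarray]:
        """Neighbour indices into the raster-ordered voxel list."""
        pos = {v: i for i, v in enumerate(self.voxels)}
        return [
            np.array([pos[n] for n in self.neighbours[v]], dtype=int)
            for v in self.voxels
        ]


def build_neighbour_graph(mask: np.ndarray) -> NeighbourGraph:
    """4-neighbourhood graph with fallbacks for voxels at the mask border.

    Every masked voxel gets (up to) four neighbours: its in-mask
    4-neighbours first; an out-of-mask 4-neighbour is replaced by an
    in-mask diagonal voxel, or failing that by the closest in-mask voxel.
    """
    mask = np.asarray(mask, dtype=bool)
    voxels = [tuple(v) for v in np.argwhere(mask)]
    if len(voxels) < 2:
        raise ValueError("mask must contain at least 2 voxels to define neighbours")
    in_mask = set(voxels)
    rows, cols = mask.shape
    all_xy = np.argwhere(mask)
    neighbours: dict[tuple, tuple] = {}
    for i, j in voxels:
        four = [(i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)]
        nb = [v for v in four if v in in_mask]
        n_missing = 4 - len(nb)
        if n_missing:
            diagonals = [(i - 1, j - 1), (i - 1, j + 1), (i + 1, j - 1), (i + 1, j + 1)]
            for d in diagonals:
                if n_missing == 0:
                    break
                if d in in_mask and d not in nb:
                    nb.append(d)
                    n_missing -= 1
            if n_missing:
                # closest remaining in-mask voxels, raster tie-break
                d2 = (all_xy[:, 0] - i) ** 2 + (all_xy[:, 1] - j) ** 2
                for idx in np.argsort(d2, kind="stable"):
                    if n_missing == 0:
                        break
                    cand = tuple(all_xy[idx])
                    if cand != (i, j) and cand not in nb:
                        nb.append(cand)
                        n_missing -= 1
        neighbours[(i, j)] = tuple(nb)
    return NeighbourGraph(voxels=tuple(voxels), neighbours=neighbours)


def log_likelihood(
    params: KineticParams, sigma2: float, curve: SampledCurve, aif: SampledCurve
) -> float:
    """Gaussian i.i.d. log-likelihood of a voxel curve under the 2CXM."""
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be positive, got {sigma2}")
    op = ForwardOperator(curve.times, aif.values, tau0=params.tau0, hct=params.hct)
    resid = op(params.fb, params.vp, params.ve, params.ps) - curve.values
    n = curve.values.size
    ssr = float(resid @ resid)
    return -0.5 * n * np.log(2.0 * np.pi * sigma2) - 0.5 * ssr / sigma2


def _theta_in_support(theta: np.ndarray, spec: PriorSpec) -> bool:
    fb, vp, ve, ps = theta
    return (
        fb > 0
        and ps > 0
        and spec.vp_support[0] < vp <= spec.vp_support[1]
        and spec.ve_support[0] < ve <= spec.ve_support[1]
    )


def _log_prior_theta(
    theta: np.ndarray,
    alpha: np.ndarray,
    neighbour_thetas: np.ndarray | None,
    weights: np.ndarray | None,
    spec: PriorSpec,
) -> float:
    """Prior terms that depend on the kinetic block (unnormalised)."""
    if not _theta_in_support(theta, spec):
        return -np.inf
    fb, _, _, ps = theta
    lp = -0.5 * (fb - alpha[0]) ** 2 / spec.fb_var
    lp += -0.5 * (ps - alpha[1]) ** 2 / spec.ps_var
    if spec.spatial_rate > 0 and neighbour_thetas is not None and len(neighbour_thetas):
        diffs = weights * np.abs(theta - neighbour_thetas)
        if spec.spatial_norm != 1.0:
            diffs = diffs**spec.spatial_norm
        lp -= spec.spatial_rate * float(np.sum(diffs))
    return lp


def log_prior(
    params: KineticParams,
    sigma2: float,
    hyper: tuple[float, float],
    neighbour_params: list | None = None,
    spec: PriorSpec = PriorSpec(),
    weights: np.ndarray | None = None,
) -> float:
    """Unnormalised log of the conditional prior of one voxel.

    ``neighbour_params`` is a list of neighbouring voxels' (fb, vp, ve, ps)
    vectors (or :class:`KineticParams`).  ``weights`` are the per-parameter
    MRF weights; by default the inverse of the voxel's own parameter values
    floored at ``spec.weight_floor``.
    """
    theta = np.array([params.fb, params.vp, params.ve, params.ps])
    if sigma2 <= 0:
        return -np.inf
    nb = None
    if neighbour_params:
        nb = np.array(
            [
                [p.fb, p.vp, p.ve, p.ps] if isinstance(p, KineticParams) else np.asarray(p)
                for p in neighbour_params
            ],
            dtype=float,
        )
    if weights is None:
        weights = 1.0 / np.maximum(theta, spec.weight_floor)
    lp = _log_prior_theta(theta, np.asarray(hyper, dtype=float), nb, weights, spec)
    if not np.isfinite(lp):
        return -np.inf
    # conventional Inverse-Gamma(c, d) kernel on sigma^2
    c, d = spec.sigma2_shape, spec.sigma2_scale
    lp += -(c + 1.0) * np.log(sigma2) - d / sigma2
    return float(lp)


def log_hyperprior(
    alpha_b: float, alpha_ps: float, spec: PriorSpec = PriorSpec()
) -> float:
    """Flat hyperprior: 0 inside both (closed) supports, -inf outside."""
    lo_b, hi_b = spec.alpha_b_support
    lo_s, hi_s = spec.alpha_ps_support
    if lo_b <= alpha_b <= hi_b and lo_s <= alpha_ps <= hi_s:
        return 0.0
    return -np.inf


@dataclass
class ChainState:
    """Stored MCMC samples and diagnostics for one slice."""

    voxels: tuple
    mask_shape: tuple[int, int]
    samples: np.ndarray  # (n_steps, n_vox, 4) kinetic parameters
    sigma2: np.ndarray  # (n_steps, n_vox)
    alpha: np.ndarray  # (n_steps, n_vox, 2)
    block_accept_post: float  # post-burn-in kinetic-block acceptance fraction
    alpha_accept_post: float
    proposal_scales: np.ndarray  # final per-voxel scale factors
    burn_in: int
    seed: int

    @property
    def n_steps(self) -> int:
        return self.samples.shape[0]


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior median / coefficient-of-variation maps per parameter."""

    median: dict  # param -> 2-D map
    cov: dict  # param -> 2-D map (posterior sd / posterior mean)
    burn_in: int
    rhat: dict | None = None  # param -> 2-D map, set when >= 2 chains given


# relative proposal step sizes per kinetic parameter, scaled per voxel
_REL_STEP = np.array([0.15, 0.01, 0.02, 0.10])
_ALPHA_STEP = np.array([0.3, 0.3])
_TUNE_WINDOW = 50
_TUNE_BAND = (0.2, 0.3)
_TUNE_FACTOR = 1.1
# Proposal preconditioning: the likelihood confines the four kinetic
# parameters to a narrow curved ridge (flow trades off against the volume
# fractions), which isotropic proposals cannot follow once sigma^2
# tightens.  The proposal covariance is therefore shaped by the local
# Gauss-Newton curvature J'J/sigma^2 plus the prior precision, recomputed
# every _PRECOND_EVERY sweeps during burn-in and frozen afterwards.
_PRECOND_EVERY = 100
# weak curvature assigned to the uniform-prior parameters (half support)^-2
_PRIOR_PREC_VP = 1.0 / 0.15**2
_PRIOR_PREC_VE = 1.0 / 0.2**2
_GN_SCALE = 2.38**2 / 4.0  # optimal random-walk scaling in 4 dimensions


def run_mcmc(
    series: np.ndarray,
    mask: np.ndarray,
    aif: SampledCurve,
    graph: NeighbourGraph | None,
    spec: PriorSpec = PriorSpec(),
    n_steps: int = 4000,
    burn_in: int = 1000,
    seed: int = 0,
    tau0: float = 0.0,
    hct: float = DEFAULT_HCT,
    theta_init: np.ndarray | None = None,
    fix_kinetics: bool = False,
) -> ChainState:
    """Sample the per-voxel posterior over a masked (t, y, x) series.

    ``theta_init`` optionally overrides the default chain start
    (F_b=3, v_p=0.1, v_e=0.2, PS=1); ``fix_kinetics`` freezes the kinetic
    block at its initial value (test hook for the conjugate sigma^2
    conditional).
    """
    mask = np.asarray(mask, dtype=bool)
    if n_steps <= burn_in:
        raise ValueError("n_steps must exceed burn_in")
    if graph is None:
        if spec.spatial_rate > 0:
            raise ValueError("a neighbour graph is required when the spatial prior is on")
        voxels = tuple(tuple(v) for v in np.argwhere(mask))
        nb_idx: list[np.ndarray] = [np.empty(0, dtype=int) for _ in voxels]
    else:
        voxels = graph.voxels
        nb_idx = graph.index_lists()
    n_vox = len(voxels)
    if n_vox == 0:
        raise ValueError("mask is empty")
    times = aif.times
    n_t = times.size
    if series.shape[0] != n_t:
        raise ValueError("series time axis does not match the AIF grid")
    y = np.stack([series[:, i, j] for (i, j) in voxels], axis=1)  # (n_t, n_vox)

    op = ForwardOperator(times, aif.values, tau0=tau0, hct=hct)
    rng = np.random.default_rng(seed)

    # --- state initialisation -------------------------------------------
    # Chains start at low flow: the flow likelihood ridge is one-sided
    # (steep below the truth, nearly flat above), so approaching from
    # below anchors burn-in at the identifiable ridge entry instead of
    # requiring a long traverse of the flat upper ridge.
    if theta_init is None:
        theta = np.tile([0.5, 0.05, 0.1, 0.5], (n_vox, 1))
    else:
        theta = np.array(theta_init, dtype=float)
        if theta.shape == (4,):
            theta = np.tile(theta, (n_vox, 1))
    # noise variance started at the pre-contrast baseline sample variance
    sigma2 = np.maximum(np.var(y[:5], axis=0, ddof=1), 1e-8)
    if spec.hierarchical:
        alpha = np.tile(
            [np.mean(spec.alpha_b_support), np.mean(spec.alpha_ps_support)], (n_vox, 1)
        )
    else:
        alpha = np.tile([spec.fb_mean, spec.ps_mean], (n_vox, 1))

    curves = np.stack([op.eval(*theta[v]) for v in range(n_vox)], axis=1)
    ssr = np.sum((curves - y) ** 2, axis=0)

    scales = np.ones(n_vox)
    ascales = np.ones(n_vox)
    # per-voxel proposal shape: Cholesky factors, preconditioned in burn-in
    chol = np.tile(np.diag(_REL_STEP), (n_vox, 1, 1))
    prior_prec = np.diag(
        [1.0 / spec.fb_var, _PRIOR_PREC_VP, _PRIOR_PREC_VE, 1.0 / spec.ps_var]
    )

    def _precondition() -> None:
        """Shape each voxel's proposal from the local model curvature."""
        for v in range(n_vox):
            jac = np.empty((n_t, 4))
            base = curves[:, v]
            for k in range(4):
                h = 1e-5 * max(abs(theta[v, k]), 1e-3)
                pert = theta[v].copy()
                pert[k] += h
                jac[:, k] = (op.eval(*pert) - base) / h
            fisher = prior_prec.copy()
            if lik_on:
                fisher = fisher + (jac.T @ jac) / sigma2[v]
            try:
                chol[v] = np.linalg.cholesky(_GN_SCALE * np.linalg.inv(fisher))
            except np.linalg.LinAlgError:  # pragma: no cover - keep last shape
                pass
    samples = np.empty((n_steps, n_vox, 4))
    sigma2_s = np.empty((n_steps, n_vox))
    alpha_s = np.empty((n_steps, n_vox, 2))

    win_prop = np.zeros(n_vox, dtype=int)
    win_acc = np.zeros(n_vox, dtype=int)
    awin_prop = np.zeros(n_vox, dtype=int)
    awin_acc = np.zeros(n_vox, dtype=int)
    post_prop = post_acc = apost_prop = apost_acc = 0

    lik_on = spec.likelihood_on
    c_shape, d_scale = spec.sigma2_shape, spec.sigma2_scale
    gibbs_shape = c_shape + (0.5 * n_t if lik_on else 0.0)

    # Tempering: during early burn-in sigma^2 is floored at a decaying
    # fraction of the initial misfit, keeping the likelihood ridge wide
    # enough for the chain to traverse it before the conjugate draws
    # tighten; the floor is fully released at 60% of burn-in, so the
    # post-burn-in chain targets the exact posterior.
    anneal = lik_on and not fix_kinetics and burn_in > 0
    if anneal:
        floor0 = ssr / n_t
        anneal_len = max(int(0.6 * burn_in), 1)
        anneal_decay = 1e-4 ** (1.0 / anneal_len)

    for step in range(n_steps):
        post = step >= burn_in
        if not fix_kinetics:
            for v in range(n_vox):
                cur = theta[v]
                # MRF weights: inverse of this voxel's previous accepted sample
                w = 1.0 / np.maximum(cur, spec.weight_floor)
                prop = cur + scales[v] * (chol[v] @ rng.standard_normal(4))
                win_prop[v] += 1
                if post:
                    post_prop += 1
                nb = theta[nb_idx[v]] if nb_idx[v].size else None
                lp_prop = _log_prior_theta(prop, alpha[v], nb, w, spec)
                if np.isfinite(lp_prop):
                    lp_cur = _log_prior_theta(cur, alpha[v], nb, w, spec)
                    delta = lp_prop - lp_cur
                    if lik_on:
                        curve_p = op.eval(*prop)
                        ssr_p = float(np.sum((curve_p - y[:, v]) ** 2))
                        delta += -0.5 * (ssr_p - ssr[v]) / sigma2[v]
                    if not np.isfinite(delta):
                        raise RuntimeError(
                            f"non-finite posterior at voxel {voxels[v]}, step {step}"
                        )
                    if np.log(rng.random()) < delta:
                        theta[v] = prop
                        if lik_on:
                            curves[:, v] = curve_p
                            ssr[v] = ssr_p
                        win_acc[v] += 1
                        if post:
                            post_acc += 1
        elif post:
            post_prop += 1  # degenerate accounting when the block is frozen

        # exact conjugate draw for sigma^2 (gamma draws can underflow to 0
        # when the shape is the tiny prior value c, i.e. likelihood off)
        gibbs_scale = d_scale + (0.5 * ssr if lik_on else 0.0)
        gamma_draw = np.maximum(rng.gamma(gibbs_shape, 1.0, size=n_vox), 1e-290)
        sigma2 = gibbs_scale / gamma_draw
        if anneal and step < anneal_len:
            sigma2 = np.maximum(sigma2, floor0 * anneal_decay**step)

        if spec.hierarchical:
            aprop = alpha + ascales[:, None] * _ALPHA_STEP * rng.standard_normal(
                (n_vox, 2)
            )
            in_sup = (
                (aprop[:, 0] >= spec.alpha_b_support[0])
                & (aprop[:, 0] <= spec.alpha_b_support[1])
                & (aprop[:, 1] >= spec.alpha_ps_support[0])
                & (aprop[:, 1] <= spec.alpha_ps_support[1])
            )
            d_b = (theta[:, 0] - aprop[:, 0]) ** 2 - (theta[:, 0] - alpha[:, 0]) ** 2
            d_s = (theta[:, 3] - aprop[:, 1]) ** 2 - (theta[:, 3] - alpha[:, 1]) ** 2
            adelta = -0.5 * d_b / spec.fb_var - 0.5 * d_s / spec.ps_var
            accept = in_sup & (np.log(rng.random(n_vox)) < adelta)
            alpha[accept] = aprop[accept]
            awin_prop += 1
            awin_acc += accept
            if post:
                apost_prop += n_vox
                apost_acc += int(accept.sum())

        samples[step] = theta
        sigma2_s[step] = sigma2
        alpha_s[step] = alpha

        # reshape proposals from the local curvature (burn-in only)
        if not post and not fix_kinetics and step % _PRECOND_EVERY == 0:
            _precondition()

        # proposal-scale tuning: burn-in only, every _TUNE_WINDOW sweeps
        if not post and (step + 1) % _TUNE_WINDOW == 0:
            rate = win_acc / np.maximum(win_prop, 1)
            scales[rate > _TUNE_BAND[1]] *= _TUNE_FACTOR
            scales[rate < _TUNE_BAND[0]] /= _TUNE_FACTOR
            win_prop[:] = 0
            win_acc[:] = 0
            arate = awin_acc / np.maximum(awin_prop, 1)
            ascales[arate > _TUNE_BAND[1]] *= _TUNE_FACTOR
            ascales[arate < _TUNE_BAND[0]] /= _TUNE_FACTOR
            awin_prop[:] = 0
            awin_acc[:] = 0

    return ChainState(
        voxels=voxels,
        mask_shape=mask.shape,
        samples=samples,
        sigma2=sigma2_s,
        alpha=alpha_s,
        block_accept_post=post_acc / max(post_prop, 1),
        alpha_accept_post=apost_acc / max(apost_prop, 1),
        proposal_scales=scales,
        burn_in=burn_in,
        seed=int(seed),
    )


def gelman_rubin(chains: np.ndarray) -> float:
    """Classic Gelman–Rubin R statistic for m chains of one scalar quantity.

    ``chains`` has shape (m, n).  R = sqrt(((n-1)/n W + B/n) / W) with W
    the mean within-chain variance and B the between-chain variance of the
    chain means (times n).  Identical chains give B = 0 and R ~ 1.
    """
    chains = np.asarray(chains, dtype=float)
    m, n = chains.shape
    if m < 2 or n < 2:
        raise ValueError("need >= 2 chains of length >= 2")
    means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0:
        return 1.0
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


def summarize(
    chain: ChainState,
    burn_in: int | None = None,
    extra_chains: list[ChainState] | None = None,
) -> PosteriorSummary:
    """Median / CoV maps from post-burn-in samples (R-hat with >=2 chains)."""
    if burn_in is None:
        burn_in = chain.burn_in
    if burn_in >= chain.n_steps:
        raise ValueError("burn_in must be smaller than the chain length")
    post = chain.samples[burn_in:]
    median = {}
    cov = {}
    for k, name in enumerate(PARAM_NAMES):
        med_map = np.full(chain.mask_shape, np.nan)
        cov_map = np.full(chain.mask_shape, np.nan)
        med = np.median(post[:, :, k], axis=0)
        mean = post[:, :, k].mean(axis=0)
        sd = post[:, :, k].std(axis=0, ddof=1)
        for v, (i, j) in enumerate(chain.voxels):
            med_map[i, j] = med[v]
            cov_map[i, j] = sd[v] / mean[v] if mean[v] != 0 else np.nan
        median[name] = med_map
        cov[name] = cov_map
    rhat = None
    if extra_chains:
        rhat = {}
        all_chains = [chain] + list(extra_chains)
        for k, name in enumerate(PARAM_NAMES):
            rmap = np.full(chain.mask_shape, np.nan)
            for v, (i, j) in enumerate(chain.voxels):
                stacked = np.stack([c.samples[burn_in:, v, k] for c in all_chains])
                rmap[i, j] = gelman_rubin(stacked)
            rhat[name] = rmap
    return PosteriorSummary(median=median, cov=cov, burn_in=burn_in, rhat=rhat)
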
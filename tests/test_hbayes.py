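"""Hierarchical Bayesian sampler: densities, graph, MCMC correctness."""

import numpy as np
import pytest
from scipy import stats

from perfbayes.hbayes import (
    PriorSpec,
    build_neighbour_graph,
    gelman_rubin,
    log_hyperprior,
    log_likelihood,
    log_prior,
    run_mcmc,
    summarize,
)
from perfbayes.kinetics import ForwardOperator, KineticParams, SampledCurve
from perfbayes.phantom import build_phantom, simulate_series


@pytest.fixture(scope="module")
def small_sim():
    """One noisy stress realisation on a 3x3 grid (fast sampler target)."""
    ph = build_phantom("stress", shape=(3, 3))
    return ph, simulate_series(ph, seed=21)


class TestLogLikelihood:
    def test_zero_residuals_value(self, times, aif, stress_params):
        op = ForwardOperator(times, aif.values)
        curve = SampledCurve(times, op(3.5, 0.08, 0.16, 1.0))
        sigma2 = 0.01
        n = len(times)
        expected = -0.5 * n * np.log(2 * np.pi * sigma2)
        assert log_likelihood(stress_params, sigma2, curve, aif) == pytest.approx(expected)

    def test_variance_doubling_identity(self, times, aif, stress_params):
        rng = np.random.default_rng(3)
        op = ForwardOperator(times, aif.values)
        y = op(3.5, 0.08, 0.16, 1.0) + rng.normal(0, 0.05, times.size)
        curve = SampledCurve(times, y)
        ssr = np.sum((op(3.5, 0.08, 0.16, 1.0) - y) ** 2)
        n = times.size
        s2 = 0.02
        l1 = log_likelihood(stress_params, s2, curve, aif)
        l2 = log_likelihood(stress_params, 2 * s2, curve, aif)
        expected_delta = -0.5 * n * np.log(2.0) + 0.5 * ssr * (1 / s2 - 1 / (2 * s2))
        assert l2 - l1 == pytest.approx(expected_delta)

    def test_sigma2_argmax_is_mean_squared_residual(self, times, aif, stress_params):
        rng = np.random.default_rng(4)
        op = ForwardOperator(times, aif.values)
        y = op(3.5, 0.08, 0.16, 1.0) + rng.normal(0, 0.05, times.size)
        curve = SampledCurve(times, y)
        ssr = float(np.sum((op(3.5, 0.08, 0.16, 1.0) - y) ** 2))
        grid = np.linspace(0.5, 2.0, 81) * ssr / times.size
        vals = [log_likelihood(stress_params, s2, curve, aif) for s2 in grid]
        assert grid[int(np.argmax(vals))] == pytest.approx(ssr / times.size, rel=0.03)

    def test_nonpositive_variance_rejected(self, times, aif, stress_params):
        curve = SampledCurve(times, np.zeros_like(times))
        with pytest.raises(ValueError):
            log_likelihood(stress_params, 0.0, curve, aif)


class TestLogPrior:
    def test_vp_outside_support_is_minus_inf(self):
        p = KineticParams(fb=3.0, vp=0.35, ve=0.2, ps=1.0)  # vp > 0.3
        assert log_prior(p, 0.01, (3.5, 1.0)) == -np.inf

    def test_identical_neighbours_add_nothing_spatial(self):
        p = KineticParams(fb=3.0, vp=0.1, ve=0.2, ps=1.0)
        with_nb = log_prior(p, 0.01, (3.5, 1.0), neighbour_params=[p, p])
        without = log_prior(p, 0.01, (3.5, 1.0), neighbour_params=None)
        assert with_nb == pytest.approx(without)

    def test_spatial_term_single_difference(self):
        """One neighbour, one differing parameter: rate * W * |delta|."""
        spec = PriorSpec()
        p = KineticParams(fb=3.0, vp=0.1, ve=0.2, ps=1.0)
        q = KineticParams(fb=3.1, vp=0.1, ve=0.2, ps=1.0)  # |delta fb| = 0.1
        w = np.ones(4)
        base = log_prior(p, 0.01, (3.5, 1.0), [p], spec, weights=w)
        offset = log_prior(p, 0.01, (3.5, 1.0), [q], spec, weights=w)
        assert base - offset == pytest.approx(5.0 * 1.0 * 0.1)

    def test_finite_inside_supports(self):
        p = KineticParams(fb=3.0, vp=0.1, ve=0.2, ps=1.0)
        assert np.isfinite(log_prior(p, 0.01, (3.5, 1.0)))


class TestLogHyperprior:
    @pytest.mark.parametrize(
        "ab,aps,expected",
        [
            (3.5, 1.0, 0.0),
            (7.5, 1.0, -np.inf),
            (3.5, 5.5, -np.inf),
            (0.001, 5.0, 0.0),  # boundary inclusive
            (7.0, 0.001, 0.0),
        ],
    )
    def test_indicator_values(self, ab, aps, expected):
        assert log_hyperprior(ab, aps) == expected


class TestNeighbourGraph:
    def test_interior_voxel_has_four_neighbours(self):
        g = build_neighbour_graph(np.ones((6, 6), bool))
        assert sorted(g.neighbours[(3, 3)]) == [(2, 3), (3, 2), (3, 4), (4, 3)]

    def test_corner_filled_with_diagonal_fallback(self):
        g = build_neighbour_graph(np.ones((6, 6), bool))
        nb = g.neighbours[(0, 0)]
        assert len(nb) == 4
        assert (0, 1) in nb and (1, 0) in nb
        assert (1, 1) in nb  # diagonal substitute for the missing sides

    def test_c_shaped_mask_uses_diagonal_substitute(self):
        mask = np.array(
            [
                [1, 1, 1, 1],
                [1, 0, 0, 0],
                [1, 1, 1, 1],
                [0, 0, 0, 0],
            ],
            dtype=bool,
        )
        g = build_neighbour_graph(mask)
        nb = g.neighbours[(0, 3)]
        # right and below are out of mask; the diagonal (1,2)... is off-mask
        # too, so the closest in-mask voxels are used; never itself
        assert (0, 3) not in nb
        assert (0, 2) in nb
        assert all(mask[v] for v in nb)

    def test_four_neighbour_part_symmetric(self):
        rng = np.random.default_rng(0)
        mask = rng.random((5, 5)) > 0.3
        mask[2, 2] = True
        if mask.sum() < 2:
            mask[0, 0] = True
        g = build_neighbour_graph(mask)
        for v, nbs in g.neighbours.items():
            for n in nbs:
                di, dj = abs(v[0] - n[0]), abs(v[1] - n[1])
                if di + dj == 1:  # 4-neighbour edges must be mutual
                    assert v in g.neighbours[n]

    def test_single_voxel_mask_rejected(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        with pytest.raises(ValueError):
            build_neighbour_graph(mask)


class TestSampler:
    def test_prior_recovery_with_likelihood_off(self):
        """With the likelihood disabled, v_p samples follow Uniform(0, 0.3]."""
        ph = build_phantom("stress", shape=(2, 2))
        sim = simulate_series(ph, seed=1)
        spec = PriorSpec(likelihood_on=False, spatial_rate=0.0)
        chain = run_mcmc(
            sim.noisy, ph.mask, sim.aif, None, spec,
            n_steps=61_000, burn_in=1000, seed=3,
        )
        vp = chain.samples[1000::20, 0, 1][:3000]
        stat, p = stats.kstest(vp, "uniform", args=(0.0, 0.3))
        assert p > 0.01

    def test_sigma2_conjugate_posterior_moments(self, times, aif):
        """Kinetics frozen at truth: sigma^2 is exactly InvGamma(c+N/2, d+SSR/2)."""
        ph = build_phantom("stress", shape=(1, 1))
        sim = simulate_series(ph, seed=2)
        spec = PriorSpec(spatial_rate=0.0)
        truth = np.array([3.5, 0.08, 0.16, 1.0])
        chain = run_mcmc(
            sim.noisy, ph.mask, sim.aif, None, spec,
            n_steps=4000, burn_in=1000, seed=6,
            theta_init=truth, fix_kinetics=True,
        )
        n = sim.noisy.shape[0]
        op = ForwardOperator(sim.times, sim.aif.values)
        ssr = float(np.sum((op(*truth) - sim.noisy[:, 0, 0]) ** 2))
        a = spec.sigma2_shape + n / 2
        b = spec.sigma2_scale + ssr / 2
        exact_mean = b / (a - 1)
        exact_sd = exact_mean / np.sqrt(a - 2)
        draws = chain.sigma2[1000:, 0]
        mc_se = exact_sd / np.sqrt(draws.size)  # draws are i.i.d. (exact Gibbs)
        assert abs(draws.mean() - exact_mean) < 3 * mc_se

    def test_block_acceptance_inside_tuning_band(self, small_sim):
        """Burn-in tuning steers block acceptance towards the [0.2, 0.3]
        band around the 0.234 random-walk optimum; short chains can sit
        anywhere inside the band (the full-length phantom study checks
        the tighter 0.234 +/- 0.05 figure)."""
        ph, sim = small_sim
        graph = build_neighbour_graph(ph.mask)
        chain = run_mcmc(
            sim.noisy, ph.mask, sim.aif, graph, PriorSpec(),
            n_steps=1500, burn_in=750, seed=4,
        )
        assert 0.15 < chain.block_accept_post < 0.35

    def test_all_samples_inside_supports(self, small_sim):
        ph, sim = small_sim
        graph = build_neighbour_graph(ph.mask)
        spec = PriorSpec()
        chain = run_mcmc(
            sim.noisy, ph.mask, sim.aif, graph, spec,
            n_steps=800, burn_in=400, seed=8,
        )
        s = chain.samples
        assert np.all(s[:, :, 0] > 0)  # F_b
        assert np.all((s[:, :, 1] > 0) & (s[:, :, 1] <= spec.vp_support[1]))
        assert np.all((s[:, :, 2] > 0) & (s[:, :, 2] <= spec.ve_support[1]))
        assert np.all(s[:, :, 3] > 0)  # PS
        assert np.all(chain.sigma2 > 0)
        assert np.all(
            (chain.alpha[:, :, 0] >= spec.alpha_b_support[0])
            & (chain.alpha[:, :, 0] <= spec.alpha_b_support[1])
        )
        assert np.all(
            (chain.alpha[:, :, 1] >= spec.alpha_ps_support[0])
            & (chain.alpha[:, :, 1] <= spec.alpha_ps_support[1])
        )

    def test_seeded_chains_bit_identical(self, small_sim):
        ph, sim = small_sim
        graph = build_neighbour_graph(ph.mask)
        kwargs = dict(n_steps=400, burn_in=200, seed=9)
        c1 = run_mcmc(sim.noisy, ph.mask, sim.aif, graph, PriorSpec(), **kwargs)
        c2 = run_mcmc(sim.noisy, ph.mask, sim.aif, graph, PriorSpec(), **kwargs)
        np.testing.assert_array_equal(c1.samples, c2.samples)
        np.testing.assert_array_equal(c1.sigma2, c2.sigma2)

    def test_noise_free_posterior_recovers_flow_everywhere(self):
        """On the noise-free stress phantom every voxel's F_b median is
        within 5% of the true 3.5 mL/min/mL."""
        ph = build_phantom("stress")
        sim = simulate_series(ph, snr=np.inf, seed=0)
        graph = build_neighbour_graph(ph.mask)
        chain = run_mcmc(
            sim.clean, ph.mask, sim.aif, graph, PriorSpec(),
            n_steps=2000, burn_in=1000, seed=5,
        )
        fb = summarize(chain).median["fb"]
        assert np.all(np.abs(fb - 3.5) / 3.5 < 0.05)

    def test_missing_graph_with_spatial_prior_rejected(self, small_sim):
        ph, sim = small_sim
        with pytest.raises(ValueError):
            run_mcmc(sim.noisy, ph.mask, sim.aif, None, PriorSpec(), n_steps=10, burn_in=5)

    def test_burn_in_must_be_shorter_than_chain(self, small_sim):
        ph, sim = small_sim
        graph = build_neighbour_graph(ph.mask)
        with pytest.raises(ValueError):
            run_mcmc(sim.noisy, ph.mask, sim.aif, graph, PriorSpec(), n_steps=100, burn_in=100)


@pytest.fixture(scope="module")
def defect_fits():
    ph = build_phantom("stress_defect")
    sim = simulate_series(ph, seed=11)
    graph = build_neighbour_graph(ph.mask)
    fits = {}
    for name, spec in (
        ("hier", PriorSpec()),
        ("fixed", PriorSpec().nonhierarchical(fb_mean=3.5)),
        ("l2", PriorSpec(spatial_norm=2.0)),
    ):
        chain = run_mcmc(
            sim.noisy, ph.mask, sim.aif, graph, spec,
            n_steps=2000, burn_in=1000, seed=5,
        )
        fits[name] = summarize(chain).median["fb"]
    return ph, fits


class TestHierarchy:
    def test_hierarchical_model_lowers_defect_flow(self, defect_fits):
        ph, fits = defect_fits
        defect = ph.maps["fb"] == 1.0
        fb = fits["hier"]
        assert fb[defect].mean() < fb[~defect].mean()

    def test_fixed_prior_overestimates_defect_flow(self, defect_fits):
        """Freezing the F_b prior mean at the stress value drags defect
        voxels towards it; the adaptive hyperprior must do better."""
        ph, fits = defect_fits
        defect = ph.maps["fb"] == 1.0
        err_hier = np.abs(fits["hier"][defect] - 1.0).mean()
        err_fixed = np.abs(fits["fixed"][defect] - 1.0).mean()
        assert err_hier < err_fixed

    def test_laplace_prior_preserves_edges_better_than_gaussian(self, defect_fits):
        """Mean absolute F_b step across the defect boundary is larger under
        the L1 (Laplace) spatial prior than under the L2 (Gaussian) one."""
        ph, fits = defect_fits
        defect = ph.maps["fb"] == 1.0

        def boundary_step(fb):
            steps = []
            rows, cols = defect.shape
            for i in range(rows):
                for j in range(cols):
                    for di, dj in ((0, 1), (1, 0)):
                        ii, jj = i + di, j + dj
                        if ii < rows and jj < cols and defect[i, j] != defect[ii, jj]:
                            steps.append(abs(fb[i, j] - fb[ii, jj]))
            return float(np.mean(steps))

        assert boundary_step(fits["hier"]) > boundary_step(fits["l2"])


class TestSummaries:
    def _chain_of(self, samples):
        from perfbayes.hbayes import ChainState

        n = samples.shape[0]
        return ChainState(
            voxels=((0, 0),),
            mask_shape=(1, 1),
            samples=samples.reshape(n, 1, 1).repeat(4, axis=2),
            sigma2=np.ones((n, 1)),
            alpha=np.ones((n, 1, 2)),
            block_accept_post=0.25,
            alpha_accept_post=0.25,
            proposal_scales=np.ones(1),
            burn_in=0,
            seed=0,
        )

    def test_constant_chain_median_and_cov(self):
        chain = self._chain_of(np.full(100, 2.5))
        s = summarize(chain, burn_in=10)
        assert s.median["fb"][0, 0] == 2.5
        assert s.cov["fb"][0, 0] == 0.0

    def test_gaussian_chain_cov(self):
        rng = np.random.default_rng(12)
        chain = self._chain_of(rng.normal(2.0, 0.2, 20_000))
        s = summarize(chain, burn_in=0)
        assert s.cov["fb"][0, 0] == pytest.approx(0.1, rel=0.05)

    def test_burn_in_longer_than_chain_rejected(self):
        chain = self._chain_of(np.ones(50))
        with pytest.raises(ValueError):
            summarize(chain, burn_in=50)

    def test_identical_chains_rhat_near_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=500)
        r = gelman_rubin(np.stack([x, x]))
        assert r == pytest.approx(1.0, abs=2e-3)

    def test_diverged_chains_rhat_large(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 500)
        b = rng.normal(5, 1, 500)
        assert gelman_rubin(np.stack([a, b])) > 1.5
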
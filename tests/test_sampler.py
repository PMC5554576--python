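"""Gibbs sampler correctness: oracles, determinism, bookkeeping."""

import itertools

import numpy as np
import pytest
from scipy.stats import norm

import bayescox as bc
from bayescox import _kernel
from bayescox.sampler import ChainConfig, GibbsSampler, combine_chains, prepare, run_chain


def _make_sampler(times, status, X, pi, spike=None, seed=0, cfg=None):
    data, baseline = prepare(times, status, X)
    prior = bc.SelectionPrior(pi=np.asarray(pi, float),
                              k=float(np.sum(pi)))
    cfg = cfg or ChainConfig(n_iter=1000, burn_in=200, seed=seed)
    rng = np.random.default_rng(seed)
    return GibbsSampler(data, prior, spike or bc.SpikeSlabPrior(),
                        baseline, cfg, rng), data, baseline


class TestBetaSweep:
    def test_acceptance_decisions_match_full_recomputation(self, tiny_survival):
        """Each sequential accept/reject equals the direct-oracle decision."""
        times, status, X = tiny_survival
        s, data, baseline = _make_sampler(times, status, X, [0.5, 0.5], seed=3)
        part = data.partition
        rng = np.random.default_rng(42)
        for sweep in range(50):
            z = rng.standard_normal(2)
            u = rng.random(2)
            beta_ref = s.beta.copy()
            # oracle: sequential decisions via full likelihood recomputation
            for i in range(2):
                prop = beta_ref.copy()
                prop[i] = beta_ref[i] + z[i] * s.scales[i]
                sd = s.spike_slab.slab_sd if s.gamma[i] else s.spike_slab.tau
                dlog = (bc.grouped_log_likelihood(prop, s.h, part, X)
                        - bc.grouped_log_likelihood(beta_ref, s.h, part, X)
                        + (beta_ref[i] ** 2 - prop[i] ** 2) / (2 * sd * sd))
                if np.log(u[i]) < dlog:
                    beta_ref = prop
            s.update_beta(z=z, u=u)
            np.testing.assert_allclose(s.beta, beta_ref, atol=1e-12)
            s.update_gamma()
            s.update_h()

    def test_incremental_bookkeeping_exact_after_1000_sweeps(self, tiny_survival):
        times, status, X = tiny_survival
        s, data, _ = _make_sampler(times, status, X, [0.3, 0.3], seed=1)
        for _ in range(1000):
            s.step()
        t1, t2 = _kernel.loglik_terms(s.eta, s.W, s.h_event, data.is_event)
        assert abs(t1 - s._t1) < 1e-10 and abs(t2 - s._t2) < 1e-10
        np.testing.assert_allclose(s.eta, data.X @ s.beta, atol=1e-10)

    def test_tiny_proposal_scale_freezes_chain(self, tiny_survival):
        """As the proposal scale vanishes, acceptance -> 1 and beta barely moves."""
        times, status, X = tiny_survival
        cfg = ChainConfig(n_iter=200, burn_in=199, seed=0, init_scale=1e-8,
                          scale_bounds=(1e-9, 1e-8))
        s, _, _ = _make_sampler(times, status, X, [0.5, 0.5], cfg=cfg)
        acc = np.mean([s.update_beta().mean() for _ in range(100)])
        assert acc > 0.99
        assert np.abs(s.beta).max() < 1e-5

    def test_posterior_mean_matches_grid_quadrature(self):
        """p=1 conditional posterior (h, gamma fixed): MCMC mean vs quadrature."""
        rng = np.random.default_rng(8)
        n = 200
        X = rng.standard_normal((n, 1))
        T = (-np.log(rng.uniform(size=n)) / (0.05 * np.exp(X[:, 0] * 0.8)))
        status = np.ones(n, dtype=int)
        s, data, _ = _make_sampler(T, status, X, [1.0], seed=2)
        s.gamma[:] = 1
        h = s.h.copy()           # freeze the hazard at its initial value
        samples = []
        for it in range(20_000):
            s.update_beta()
            if it >= 2000:
                samples.append(s.beta[0])
        samples = np.asarray(samples)

        grid = np.linspace(-0.5, 2.0, 2001)
        part = data.partition
        logpost = np.array([
            bc.grouped_log_likelihood([b], h, part, X)
            + norm.logpdf(b, scale=s.spike_slab.slab_sd) for b in grid])
        w = np.exp(logpost - logpost.max())
        w /= w.sum()
        want = float(np.dot(w, grid))

        # Monte-Carlo SE via batch means on the autocorrelated chain
        batches = samples[: len(samples) // 30 * 30].reshape(30, -1).mean(axis=1)
        se = batches.std(ddof=1) / np.sqrt(len(batches))
        assert abs(samples.mean() - want) < 3 * se + 1e-4


class TestGammaUpdate:
    def test_all_included_when_pi_one(self, tiny_survival):
        times, status, X = tiny_survival
        s, _, _ = _make_sampler(times, status, X, [1.0, 1.0])
        s.update_gamma()
        assert np.all(s.gamma == 1)

    def test_long_run_fraction_at_beta_zero(self, tiny_survival):
        """beta=0, pi=0.5, cb=20: P(gamma=1) = 1/21 per coordinate."""
        times, status, X = tiny_survival
        s, _, _ = _make_sampler(times, status, X, [0.5, 0.5], seed=4)
        s.beta[:] = 0.0
        draws = np.array([(s.update_gamma(), s.gamma.copy())[1]
                          for _ in range(20_000)])
        assert draws.mean() == pytest.approx(1 / 21, abs=0.005)


class TestHUpdate:
    def test_gamma_full_conditional_moments(self):
        """d=1 event, 3 survivors at beta=0, c0=2, alpha-inc 0.5: mean 1.5/5."""
        times = np.array([1.0, 2.0, 2.0, 2.0, 2.0])
        status = np.array([1, 0, 0, 0, 1])
        X = np.zeros((5, 1))
        data, baseline = prepare(times, status, X)
        # interval 1 = (0, 1]: event subject 0; survivors 1-4 pass through
        prior = bc.SelectionPrior(pi=np.array([0.0]), k=0.0)
        base = bc.BaselineHazardPrior(c0=2.0, eta0=baseline.eta0,
                                      kappa0=baseline.kappa0,
                                      alpha_increments=np.full(data.J, 0.5))
        cfg = ChainConfig(n_iter=10, burn_in=1, seed=0, init_scale=1e-9,
                          scale_bounds=(1e-10, 1e-9))
        s = GibbsSampler(data, prior, bc.SpikeSlabPrior(), base, cfg,
                         np.random.default_rng(0))
        hs = []
        for _ in range(30_000):
            s.update_h()
            hs.append(s.h[0])
        # rate = c0 + 4 survivors at exp(0) = 6 ... interval 1 has subjects
        # 1..4 at risk beyond it, so rate = 2 + 4 = 6, shape = 0.5 + 1
        assert np.mean(hs) == pytest.approx(1.5 / 6.0, rel=0.03)

    def test_posterior_mean_decreases_with_risk_set(self):
        rng = np.random.default_rng(0)
        means = []
        for extra in (0, 10, 40):
            n = 2 + extra
            times = np.concatenate([[1.0, 5.0], np.full(extra, 5.0)])
            status = np.concatenate([[1, 1], np.zeros(extra, int)])
            data, baseline = prepare(times, status, np.zeros((n, 1)))
            rate = baseline.c0 + data.exposure_sums(np.zeros(n))
            shape = baseline.alpha_increments + data.d
            means.append((shape / rate)[0])
        assert means[0] > means[1] > means[2]


class TestRunChain:
    def test_seed_determinism(self, tiny_survival):
        times, status, X = tiny_survival
        prior = bc.uniform_selection_prior(2, 1)
        cfg = ChainConfig(n_iter=500, burn_in=100, seed=9)
        a = run_chain(times, status, X, prior, config=cfg)
        b = run_chain(times, status, X, prior, config=cfg)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.gamma, b.gamma)
        np.testing.assert_array_equal(a.h, b.h)

    def test_pure_noise_model_size_tracks_prior(self):
        """With no true effects and weak data the mean model size ~ sum(pi)."""
        rng = np.random.default_rng(3)
        n, p = 12, 50
        X = rng.standard_normal((n, p))
        T = rng.exponential(10.0, n)
        status = (rng.random(n) < 0.5).astype(int)
        status[0] = 1
        prior = bc.uniform_selection_prior(p, 5.0)   # sum(pi) = 5
        cfg = ChainConfig(n_iter=6000, burn_in=1000, seed=0)
        res = run_chain(T, status, X, prior, config=cfg)
        size = res.gamma.sum(axis=1).mean()
        assert 2.5 < size < 7.5

    def test_marginal_inclusion_matches_enumeration_quadrature(self):
        """p=2 joint posterior: sampler P(gamma_i=1) vs exact enumeration.

        The interval hazards are integrated out analytically (the gamma prior
        against the grouped likelihood gives a finite alternating sum), and
        beta is integrated on a fine 2-D grid for each of the four gamma
        configurations.
        """
        rng = np.random.default_rng(6)
        times = np.array([1, 1, 2, 2, 3, 3, 4, 4, 5, 5], dtype=float)
        status = np.array([1, 0, 1, 1, 0, 1, 0, 1, 1, 0])
        X = rng.standard_normal((10, 2))
        pi = np.array([0.5, 0.5])
        spike = bc.SpikeSlabPrior(tau=0.1, cb=5.0)

        data, baseline = prepare(times, status, X)
        part = data.partition
        c0, alpha = baseline.c0, baseline.alpha_increments

        def marginal_loglik(beta):
            e = np.exp(X @ beta)
            total = 0.0
            for j in range(part.n_intervals):
                rj, dj = part.risk_sets[j], part.event_sets[j]
                surv = [i for i in rj if i not in dj]
                A = e[surv].sum()
                m = 0.0
                for r in range(len(dj) + 1):
                    for sub in itertools.combinations(dj, r):
                        S = A + e[list(sub)].sum()
                        m += (-1) ** r * (c0 / (c0 + S)) ** alpha[j]
                total += np.log(m)
            return total

        grid = np.linspace(-1.8, 1.8, 81)
        L = np.array([[marginal_loglik(np.array([b1, b2])) for b2 in grid]
                      for b1 in grid])
        post = np.zeros((2, 2))
        for g1 in (0, 1):
            for g2 in (0, 1):
                sd1 = spike.slab_sd if g1 else spike.tau
                sd2 = spike.slab_sd if g2 else spike.tau
                pr = (norm.logpdf(grid, scale=sd1)[:, None]
                      + norm.logpdf(grid, scale=sd2)[None, :])
                post[g1, g2] = (np.exp(L + pr - L.max()).sum()
                                * pi[0] ** g1 * (1 - pi[0]) ** (1 - g1)
                                * pi[1] ** g2 * (1 - pi[1]) ** (1 - g2))
        want1 = post[1].sum() / post.sum()
        want2 = post[:, 1].sum() / post.sum()

        cfg = ChainConfig(n_iter=40_000, burn_in=4_000, seed=1)
        res = run_chain(times, status, X, bc.SelectionPrior(pi=pi, k=1.0),
                        spike_slab=spike, config=cfg)
        got = res.gamma.mean(axis=0)
        for j, want_j in ((0, want1), (1, want2)):
            g = res.gamma[:, j].astype(float)
            batches = g[: len(g) // 30 * 30].reshape(30, -1).mean(axis=1)
            se = batches.std(ddof=1) / np.sqrt(30)
            assert abs(got[j] - want_j) < 3 * se + 0.01


class TestCombineChains:
    def test_self_combination_preserves_means(self, tiny_survival):
        times, status, X = tiny_survival
        prior = bc.uniform_selection_prior(2, 1)
        cfg = ChainConfig(n_iter=400, burn_in=100, seed=2)
        r = run_chain(times, status, X, prior, config=cfg)
        pooled = combine_chains([r, r])
        np.testing.assert_allclose(pooled.beta.mean(axis=0),
                                   r.beta.mean(axis=0))

    def test_pooled_inclusion_is_weighted_mean(self, tiny_survival):
        times, status, X = tiny_survival
        prior = bc.uniform_selection_prior(2, 1)
        a = run_chain(times, status, X, prior,
                      config=ChainConfig(n_iter=400, burn_in=100, seed=1))
        b = run_chain(times, status, X, prior,
                      config=ChainConfig(n_iter=400, burn_in=100, seed=2))
        pooled = combine_chains([a, b])
        want = (a.gamma.mean(axis=0) + b.gamma.mean(axis=0)) / 2
        np.testing.assert_allclose(pooled.gamma.mean(axis=0), want)

    def test_dimension_mismatch_rejected(self, tiny_survival):
        times, status, X = tiny_survival
        prior2 = bc.uniform_selection_prior(2, 1)
        r2 = run_chain(times, status, X, prior2,
                       config=ChainConfig(n_iter=300, burn_in=100, seed=0))
        prior1 = bc.uniform_selection_prior(1, 1)
        r1 = run_chain(times, status, X[:, :1], prior1,
                       config=ChainConfig(n_iter=300, burn_in=100, seed=0))
        with pytest.raises(ValueError):
            combine_chains([r2, r1])
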
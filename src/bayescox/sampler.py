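"""Gibbs sampler for the grouped Cox model with spike-and-slab selection.

One iteration sweeps three blocks of full conditionals:

1. each ``beta_i`` by adaptive random-walk Metropolis-Hastings (Gaussian
   proposal, per-coordinate scale tuned toward a target acceptance rate
   during burn-in only, then frozen);
2. each inclusion indicator ``gamma_i`` by an exact Bernoulli draw from its
   conditional ``P(gamma_i=1 | beta_i) = a/(a+b)``;
3. each interval hazard increment ``h_j`` from its (approximate) gamma full
   conditional ``Gamma(alpha_inc_j + d_j, rate = c0 + sum_{R_j \\ D_j} e^{x'beta})``.

Chains start from the empty model (beta = 0, gamma = 0) with ``h`` at its
prior mean.  All randomness flows from one ``numpy.random.Generator`` per
chain, so a seed fixes the run bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .grouped import (BaselineHazardPrior, TimePartition,
                      calibrate_baseline_prior, partition_time_axis)
from .priors import SelectionPrior, SpikeSlabPrior, gamma_conditional

_EXP_CAP = 700.0


@dataclass
class ChainConfig:
    """MCMC run settings."""

    n_iter: int = 20_000
    burn_in: int = 5_000
    thin: int = 1
    seed: int = 0
    init_scale: float = 0.05
    adapt_target: float = 0.35
    adapt_window: int = 100
    scale_bounds: tuple = (1e-3, 10.0)

    def __post_init__(self):
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.init_scale <= 0:
            raise ValueError("proposal scales must be positive")


@dataclass
class ChainResult:
    """Stored post-burn-in samples plus acceptance bookkeeping."""

    beta: np.ndarray            # (S, p)
    gamma: np.ndarray           # (S, p) uint8
    h: np.ndarray               # (S, J)
    loglik: np.ndarray          # (S,) log-likelihood at stored iterations
    loglik_trace: np.ndarray    # (n_iter,) full per-iteration trace
    accept_rate: np.ndarray     # (p,) post-burn-in beta acceptance rates
    config: ChainConfig
    partition: TimePartition = field(repr=False, default=None)

    @property
    def n_samples(self) -> int:
        return self.beta.shape[0]

    @property
    def inclusion_probs(self) -> np.ndarray:
        """Posterior inclusion probabilities: column means of gamma."""
        return self.gamma.mean(axis=0)


class _GroupedData:
    """Precomputed per-subject quantities for fast likelihood updates."""

    def __init__(self, times, status, X, partition: TimePartition):
        times = np.asarray(times, dtype=float)
        status = np.asarray(status, dtype=np.int64)
        self.X = np.asfortranarray(X, dtype=np.float64)
        self.n, self.p = self.X.shape
        self.partition = partition
        self.J = partition.n_intervals
        self.interval = partition.interval_of(times)   # j(l), 0-based
        self.is_event = (status == 1).astype(np.uint8)
        self.d = np.bincount(self.interval[self.is_event == 1],
                             minlength=self.J).astype(np.float64)

    def hazard_exposure(self, h):
        """W_l = hazard mass of intervals subject l fully survives; and
        h_event_l = increment of the event interval (0 for censored)."""
        cumh = np.cumsum(h)
        W = cumh[self.interval] - np.where(self.is_event == 1,
                                           h[self.interval], 0.0)
        h_event = np.where(self.is_event == 1, h[self.interval], 0.0)
        return W, h_event

    def exposure_sums(self, eta):
        """Per-interval sum of exp(x'beta) over R_j \\ D_j."""
        e = np.exp(np.clip(eta, -_EXP_CAP, _EXP_CAP))
        total = np.bincount(self.interval, weights=e, minlength=self.J)
        censored = np.bincount(self.interval[self.is_event == 0],
                               weights=e[self.is_event == 0], minlength=self.J)
        # subjects with j(l) > j are at risk through all of interval j
        beyond = np.concatenate([np.cumsum(total[::-1])[::-1][1:], [0.0]])
        return beyond + censored


class GibbsSampler:
    """Mutable sampler state for one (possibly tempered) chain."""

    def __init__(self, data: _GroupedData, selection: SelectionPrior,
                 spike_slab: SpikeSlabPrior, baseline: BaselineHazardPrior,
                 config: ChainConfig, rng: np.random.Generator):
        self.data = data
        self.selection = selection
        self.spike_slab = spike_slab
        self.baseline = baseline
        self.config = config
        self.rng = rng

        p, J = data.p, data.J
        self.beta = np.zeros(p)
        self.gamma = np.zeros(p, dtype=np.uint8)
        self.h = baseline.prior_mean_h.copy()
        self.eta = np.zeros(data.n)
        self.scales = np.full(p, config.init_scale)
        self.iteration = 0
        self._accept_win = np.zeros(p)
        self._accept_post = np.zeros(p)
        self._post_iters = 0
        self._refresh_likelihood()

    # -- likelihood bookkeeping ------------------------------------------
    def _refresh_likelihood(self):
        self.W, self.h_event = self.data.hazard_exposure(self.h)
        self._t1, self._t2 = _kernel.loglik_terms(
            self.eta, self.W, self.h_event, self.data.is_event)

    @property
    def loglik(self) -> float:
        return -self._t1 + self._t2

    # -- full-conditional updates ----------------------------------------
    def update_beta(self, z=None, u=None):
        """One RW-MH sweep over all coordinates; returns acceptance flags."""
        p = self.data.p
        if z is None:
            z = self.rng.standard_normal(p)
        if u is None:
            u = self.rng.random(p)
        accepted = np.zeros(p, dtype=np.uint8)
        self._t1, self._t2 = _kernel.beta_sweep(
            self.beta, self.gamma, self.eta, self.data.X, self.W,
            self.h_event, self.data.is_event, self.scales,
            self.spike_slab.tau, self.spike_slab.slab_sd,
            self._t1, self._t2, z, u, accepted)
        return accepted

    def update_gamma(self):
        """Exact Bernoulli draw of each gamma_i from its full conditional."""
        prob = gamma_conditional(self.beta, self.selection.pi, self.spike_slab)
        self.gamma = (self.rng.random(self.data.p) < prob).astype(np.uint8)

    def update_h(self):
        """Gamma full-conditional draw of every interval increment."""
        rate = self.baseline.c0 + self.data.exposure_sums(self.eta)
        shape = self.baseline.alpha_increments + self.data.d
        self.h = self.rng.gamma(shape, 1.0 / rate)
        self._refresh_likelihood()

    # -- adaptation -------------------------------------------------------
    def _adapt(self):
        cfg = self.config
        batch = self.iteration // cfg.adapt_window
        rate = self._accept_win / cfg.adapt_window
        step = 1.0 / np.sqrt(max(batch, 1))   # diminishing adaptation
        self.scales *= np.exp(step * (rate - cfg.adapt_target))
        np.clip(self.scales, *cfg.scale_bounds, out=self.scales)
        self._accept_win[:] = 0.0

    def step(self):
        """One full Gibbs iteration: beta sweep -> gamma -> h."""
        cfg = self.config
        acc = self.update_beta()
        self.update_gamma()
        self.update_h()
        self.iteration += 1
        if self.iteration <= cfg.burn_in:
            self._accept_win += acc
            if self.iteration % cfg.adapt_window == 0:
                self._adapt()
        else:
            self._accept_post += acc
            self._post_iters += 1
        return acc

    def state(self):
        """Snapshot of (beta, gamma, h) — the full parameter state."""
        return self.beta.copy(), self.gamma.copy(), self.h.copy()

    def set_state(self, beta, gamma, h):
        """Install a parameter state (used by tempering swaps)."""
        self.beta = np.array(beta, dtype=float)
        self.gamma = np.array(gamma, dtype=np.uint8)
        self.h = np.array(h, dtype=float)
        self.eta = self.data.X @ self.beta
        self._refresh_likelihood()


def prepare(times, status, X, partition=None, baseline=None, c0=2.0):
    """Build the precomputed data bundle and baseline prior."""
    if partition is None:
        partition = partition_time_axis(times, status)
    data = _GroupedData(times, status, X, partition)
    if baseline is None:
        baseline = calibrate_baseline_prior(times, status, partition, c0=c0)
    return data, baseline


def run_chain(times, status, X, selection: SelectionPrior,
              spike_slab: SpikeSlabPrior | None = None,
              config: ChainConfig | None = None,
              partition: TimePartition | None = None,
              baseline: BaselineHazardPrior | None = None,
              c0: float = 2.0) -> ChainResult:
    """Run one MCMC chain from the empty model and store post-burn-in samples."""
    spike_slab = spike_slab or SpikeSlabPrior()
    config = config or ChainConfig()
    data, baseline = prepare(times, status, X, partition, baseline, c0)
    rng = np.random.default_rng(config.seed)
    s = GibbsSampler(data, selection, spike_slab, baseline, config, rng)

    n_keep = (config.n_iter - config.burn_in) // config.thin
    beta_s = np.empty((n_keep, data.p))
    gamma_s = np.empty((n_keep, data.p), dtype=np.uint8)
    h_s = np.empty((n_keep, data.J))
    ll_s = np.empty(n_keep)
    trace = np.empty(config.n_iter)

    k = 0
    for it in range(config.n_iter):
        s.step()
        trace[it] = s.loglik
        post = it + 1 - config.burn_in
        if post > 0 and post % config.thin == 0 and k < n_keep:
            beta_s[k] = s.beta
            gamma_s[k] = s.gamma
            h_s[k] = s.h
            ll_s[k] = s.loglik
            k += 1

    acc = s._accept_post / max(s._post_iters, 1)
    return ChainResult(beta=beta_s[:k], gamma=gamma_s[:k], h=h_s[:k],
                       loglik=ll_s[:k], loglik_trace=trace, accept_rate=acc,
                       config=config, partition=s.data.partition)


def combine_chains(results) -> ChainResult:
    """Pool post-burn-in samples of several chains (sample-count weighted)."""
    results = list(results)
    if not results:
        raise ValueError("no chains to combine")
    p = results[0].beta.shape[1]
    J = results[0].h.shape[1]
    for r in results[1:]:
        if r.beta.shape[1] != p or r.h.shape[1] != J:
            raise ValueError("chain dimensions do not match")
    return ChainResult(
        beta=np.concatenate([r.beta for r in results]),
        gamma=np.concatenate([r.gamma for r in results]),
        h=np.concatenate([r.h for r in results]),
        loglik=np.concatenate([r.loglik for r in results]),
        loglik_trace=np.concatenate([r.loglik_trace for r in results]),
        accept_rate=np.mean([r.accept_rate for r in results], axis=0),
        config=results[0].config,
        partition=results[0].partition)
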
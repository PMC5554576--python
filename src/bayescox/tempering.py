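"""Parallel tempering over prior-broadened replica chains.

Replica ``ch`` (ch = 0..v) targets the posterior whose spike-and-slab prior
uses ``tau * T**ch`` on a log-linear temperature ladder ``T**ch``; the
likelihood, the Bernoulli selection prior and the gamma-process hazard prior
are shared by all replicas.  Every ``swap_interval`` iterations a uniformly
random adjacent pair is proposed for a full state exchange
(beta, gamma, h), accepted with the usual replica-exchange probability

    min{1, [f(theta_2) g(theta_1)] / [f(theta_1) g(theta_2)]}

where f, g are the two replicas' own un-normalized posteriors.  Because only
the coefficient prior differs between replicas, every shared factor cancels
and the acceptance ratio reduces to spike-and-slab prior log-densities.
Chain 0 is untempered: its samples are draws from the target posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .priors import SelectionPrior, SpikeSlabPrior, spike_slab_logpdf
from .sampler import ChainConfig, ChainResult, GibbsSampler, prepare


@dataclass
class TemperatureLadder:
    """Log-linear ladder T**ch for ch = 0..n_chains-1."""

    base: float = 1.5
    n_chains: int = 6
    swap_interval: int = 10
    attempted: int = field(default=0, compare=False)
    accepted: int = field(default=0, compare=False)

    def __post_init__(self):
        if self.base < 1:
            raise ValueError("temperature base must be >= 1")
        if self.n_chains < 2:
            raise ValueError("tempering needs at least 2 chains")

    @property
    def temperatures(self) -> np.ndarray:
        return self.base ** np.arange(self.n_chains)

    @property
    def swap_acceptance_rate(self) -> float:
        return self.accepted / self.attempted if self.attempted else np.nan


def build_ladder(base: float, n_chains: int = 6,
                 swap_interval: int = 10) -> TemperatureLadder:
    return TemperatureLadder(base=base, n_chains=n_chains,
                             swap_interval=swap_interval)


def swap_probability(logdens_f_at_1, logdens_f_at_2,
                     logdens_g_at_1, logdens_g_at_2) -> float:
    """Replica-exchange acceptance probability from four log densities."""
    log_alpha = (logdens_f_at_2 - logdens_f_at_1) + \
                (logdens_g_at_1 - logdens_g_at_2)
    return float(min(1.0, np.exp(min(log_alpha, 0.0))))


def _prior_logdens(sampler: GibbsSampler, beta, gamma) -> float:
    """Spike-and-slab prior log density of a state under a chain's own tau."""
    return float(spike_slab_logpdf(beta, gamma, sampler.spike_slab).sum())


def run_parallel_tempering(times, status, X, selection: SelectionPrior,
                           spike_slab: SpikeSlabPrior | None = None,
                           config: ChainConfig | None = None,
                           ladder: TemperatureLadder | None = None,
                           partition=None, baseline=None,
                           c0: float = 2.0,
                           tune_target: float | None = None) -> ChainResult:
    """Run all replicas in lockstep; return the untempered chain's samples.

    With ``tune_target`` set, the ladder base adapts by stochastic
    approximation after each burn-in swap attempt toward that acceptance
    rate and freezes when sampling starts (burn-in doubles as the pilot).
    The returned result's ``swap_acceptance_rate`` attribute (also on the
    ladder object) reports the post-burn-in accepted/attempted exchanges.
    """
    spike_slab = spike_slab or SpikeSlabPrior()
    config = config or ChainConfig()
    ladder = ladder or TemperatureLadder()
    data, baseline = prepare(times, status, X, partition, baseline, c0)

    master = np.random.default_rng(config.seed)
    chains = []
    for ch, T in enumerate(ladder.temperatures):
        rng = np.random.default_rng([config.seed, 101 + ch])
        chains.append(GibbsSampler(data, selection, spike_slab.tempered(T),
                                   baseline, config, rng))

    def _retemper():
        for ch, T in enumerate(ladder.temperatures):
            chains[ch].spike_slab = spike_slab.tempered(T)

    tune_trace: list = []

    cold = chains[0]
    n_keep = (config.n_iter - config.burn_in) // config.thin
    beta_s = np.empty((n_keep, data.p))
    gamma_s = np.empty((n_keep, data.p), dtype=np.uint8)
    h_s = np.empty((n_keep, data.J))
    ll_s = np.empty(n_keep)
    trace = np.empty(config.n_iter)

    k = 0
    for it in range(config.n_iter):
        for c in chains:
            c.step()
        if (it + 1) % ladder.swap_interval == 0:
            if tune_trace and it + 1 > config.burn_in:
                # freeze at the Polyak average of the tuning trajectory
                half = tune_trace[len(tune_trace) // 2:]
                ladder.base = float(np.exp(np.mean(half)))
                _retemper()
                tune_trace = []
            lo = master.integers(0, ladder.n_chains - 1)
            a, b = chains[lo], chains[lo + 1]
            sa, sb = a.state(), b.state()
            # shared likelihood/h-prior/Bernoulli factors cancel; only the
            # spike-and-slab prior distinguishes the replicas
            prob = swap_probability(
                _prior_logdens(a, sa[0], sa[1]),
                _prior_logdens(a, sb[0], sb[1]),
                _prior_logdens(b, sa[0], sa[1]),
                _prior_logdens(b, sb[0], sb[1]))
            accept = master.random() < prob
            if it + 1 > config.burn_in:
                # report the stationary rate: burn-in swaps are transient
                ladder.attempted += 1
                ladder.accepted += int(accept)
            elif tune_target is not None:
                # Robbins-Monro on log(base): acceptance falls as the
                # ladder spreads, so accept > target widens it
                n_tuned = len(tune_trace) + 1
                step = 0.4 / np.sqrt(max(1, n_tuned - 100))
                log_base = max(np.log(ladder.base)
                               + step * (prob - tune_target), 5e-4)
                ladder.base = float(np.exp(log_base))
                tune_trace.append(log_base)
                _retemper()
            if accept:
                a.set_state(*sb)
                b.set_state(*sa)
        trace[it] = cold.loglik
        post = it + 1 - config.burn_in
        if post > 0 and post % config.thin == 0 and k < n_keep:
            beta_s[k] = cold.beta
            gamma_s[k] = cold.gamma
            h_s[k] = cold.h
            ll_s[k] = cold.loglik
            k += 1

    acc = cold._accept_post / max(cold._post_iters, 1)
    result = ChainResult(beta=beta_s[:k], gamma=gamma_s[:k], h=h_s[:k],
                         loglik=ll_s[:k], loglik_trace=trace, accept_rate=acc,
                         config=config, partition=data.partition)
    result.swap_acceptance_rate = ladder.swap_acceptance_rate
    return result


def tune_ladder(times, status, X, selection: SelectionPrior,
                spike_slab: SpikeSlabPrior | None = None,
                n_chains: int = 6, swap_interval: int = 10,
                target: float = 0.5, pilot_iters: int = 4_000,
                seed: int = 0, start_base: float = 1.05) -> TemperatureLadder:
    """Choose the ladder base by a short pilot run.

    The pilot adapts log(base) by stochastic approximation after every
    swap attempt (swap acceptance decreases monotonically in the base) and
    returns a fresh frozen ladder with the tuned base.
    """
    cfg = ChainConfig(n_iter=pilot_iters, burn_in=pilot_iters - 1, seed=seed)
    ladder = build_ladder(start_base, n_chains, swap_interval)
    run_parallel_tempering(times, status, X, selection, spike_slab, cfg,
                           ladder, tune_target=target)
    return build_ladder(ladder.base, n_chains, swap_interval)
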
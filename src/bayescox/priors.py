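"""Spike-and-slab coefficient prior and variable-selection priors.

Each regression coefficient carries a two-component normal mixture indexed by
a binary inclusion indicator ``gamma_i``:

    beta_i | gamma_i ~ (1 - gamma_i) N(0, tau^2) + gamma_i N(0, (cb*tau)^2)

The narrow "spike" (sd ``tau``) absorbs excluded variables; the wide "slab"
(sd ``cb*tau``) accommodates genuine effects.  ``gamma_i`` are independent
Bernoulli(pi_i) a priori, and the selection prior ``pi`` is where secondary
information (e.g. per-gene copy-number variability) enters the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import norm

#: clipping bound keeping constructed inclusion probabilities away from {0, 1}
PI_EPS = 1e-6


@dataclass(frozen=True)
class SpikeSlabPrior:
    """Two-component normal mixture prior on a regression coefficient."""

    tau: float = 0.0375
    cb: float = 20.0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("spike standard deviation tau must be positive")
        if self.cb <= 1:
            raise ValueError("slab inflation cb must exceed 1")

    @property
    def slab_sd(self) -> float:
        return self.cb * self.tau

    def tempered(self, temperature: float) -> "SpikeSlabPrior":
        """Broadened prior for a heated chain: tau -> tau * temperature."""
        return SpikeSlabPrior(tau=self.tau * temperature, cb=self.cb)


@dataclass(frozen=True)
class SelectionPrior:
    """Per-feature prior inclusion probabilities pi with expected model size k."""

    pi: np.ndarray
    k: float

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        if np.any(pi < 0) or np.any(pi > 1):
            raise ValueError("inclusion probabilities must lie in [0, 1]")
        object.__setattr__(self, "pi", pi)


def spike_slab_logpdf(beta_i, gamma_i, prior: SpikeSlabPrior):
    """Log density of beta_i under its mixture component (vectorized)."""
    sd = np.where(np.asarray(gamma_i) == 1, prior.slab_sd, prior.tau)
    return norm.logpdf(np.asarray(beta_i, dtype=float), scale=sd)


def gamma_conditional(beta_i, pi_i, prior: SpikeSlabPrior):
    """P(gamma_i = 1 | beta_i) = a / (a + b) with
    a = N(beta_i; 0, (cb*tau)^2) * pi_i and b = N(beta_i; 0, tau^2) * (1 - pi_i).

    Computed through the log-odds so the spike density underflowing for large
    |beta| yields exactly 1 instead of NaN; degenerate pi in {0, 1} short-circuit.
    """
    beta_i = np.asarray(beta_i, dtype=float)
    pi_i = np.asarray(pi_i, dtype=float)
    with np.errstate(divide="ignore"):
        log_odds_prior = np.log(pi_i) - np.log1p(-pi_i)
    dlog = (norm.logpdf(beta_i, scale=prior.slab_sd)
            - norm.logpdf(beta_i, scale=prior.tau))
    logit = log_odds_prior + dlog
    out = expit(logit)
    out = np.where(pi_i == 0.0, 0.0, out)
    out = np.where(pi_i == 1.0, 1.0, out)
    if out.ndim == 0:
        return float(out)
    return out


def uniform_selection_prior(p: int, k: float) -> SelectionPrior:
    """Uninformative prior: pi_i = k/p for every feature."""
    if not 0 < k <= p:
        raise ValueError("expected model size k must satisfy 0 < k <= p")
    return SelectionPrior(pi=np.full(p, k / p), k=float(k))


def cnv_informed_prior(sigma, k: float, eps: float = PI_EPS) -> SelectionPrior:
    """Selection prior proportional to per-feature secondary-data dispersion.

    ``pi_i = k * sigma_i / sum_j sigma_j`` — features whose copy-number (or
    other secondary) signal varies more across samples get proportionally
    higher prior inclusion probability, preserving ``sum(pi) = k`` before
    clipping into ``[eps, 1 - eps]``.
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("dispersion values must be nonnegative")
    total = sigma.sum()
    if total <= 0:
        raise ValueError("all-zero dispersion vector cannot inform a prior")
    pi = np.clip(k * sigma / total, eps, 1.0 - eps)
    return SelectionPrior(pi=pi, k=float(k))


def scenario_prior(kind: str, truth_indices, p: int,
                   rng: np.random.Generator | None = None,
                   high: float = 0.8, low: float = 0.1) -> SelectionPrior:
    """Simulation-study informative priors.

    ``correct``   — pi = ``high`` on the true predictors, ``low`` elsewhere.
    ``incorrect`` — pi = ``high`` on ``len(truth)`` non-predictors sampled
    without replacement (seeded via ``rng``), ``low`` everywhere else
    including the true predictors.
    """
    truth = np.asarray(sorted(truth_indices), dtype=int)
    pi = np.full(p, low)
    if kind == "correct":
        pi[truth] = high
    elif kind == "incorrect":
        non_pred = np.setdiff1d(np.arange(p), truth)
        if truth.size > non_pred.size:
            raise ValueError("not enough non-predictors to misinform the prior")
        if rng is None:
            rng = np.random.default_rng()
        decoys = rng.choice(non_pred, size=truth.size, replace=False)
        pi[decoys] = high
    else:
        raise ValueError(f"unknown scenario prior kind: {kind!r}")
    return SelectionPrior(pi=pi, k=float(pi.sum()))
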
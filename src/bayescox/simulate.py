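"""Synthetic survival data: block-correlated covariates, Cox-Weibull times.

The generator reproduces a standard high-dimensional survival simulation:
Gaussian covariates with autoregressive correlation ``rho^|i-j|`` inside
blocks of size ``m`` (independent across blocks), event times drawn by
inverting the Weibull-baseline proportional-hazards survival function,

    T* = [ -log U / (eta * exp(x'beta)) ]^(1/kappa),   U ~ Uniform(0, 1),

and uninformative censoring as the minimum of a uniform administrative
window and an exponential loss to follow-up.

Two effect scenarios are provided: a *sparse* one with six true predictors
beta = (0.75, -0.75, 0.5, -0.5, 0.25, -0.25, 0, ...), and a *nonsparse* one
with 122 true predictors drawn uniformly from (-0.8, -0.2) U (0.2, 0.8),
61 of each sign.  Both use n = 200 subjects and p = 500 features, with the
Weibull baseline solved from the survival constraints S(12) = 0.9 and
S(36) = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: administrative censoring window upper bound (time units)
DEFAULT_ADMIN_MAX = 180.0
#: exponential loss-to-follow-up rate (1 / time units)
DEFAULT_DROPOUT_RATE = 0.0018


@dataclass(frozen=True)
class SimulationScenario:
    """Complete description of one simulated study arm."""

    n: int
    p: int
    beta_true: np.ndarray
    k_true: int
    rho: float = 0.5
    block_size: int = 100
    eta: float = 0.0
    kappa: float = 0.0
    admin_max: float = DEFAULT_ADMIN_MAX
    dropout_rate: float = DEFAULT_DROPOUT_RATE
    seed: int = 0
    name: str = field(default="custom")

    @property
    def truth_indices(self) -> np.ndarray:
        return np.nonzero(self.beta_true != 0.0)[0]


def weibull_from_quantiles(t1, s1, t2, s2) -> tuple[float, float]:
    """Solve ``exp(-eta * t**kappa) = s`` at two (time, survival) points.

    kappa = log(log s1 / log s2) / log(t1 / t2); eta by back-substitution.

    Raises
    ------
    ValueError
        If the implied shape is not positive (survival must decrease in time).
    """
    if not (0 < s1 < 1 and 0 < s2 < 1):
        raise ValueError("survival probabilities must lie strictly in (0, 1)")
    if t1 == t2:
        raise ValueError("quantile times must be distinct")
    if s1 == s2:
        raise ValueError("survival constraints not monotone")
    kappa = np.log(np.log(s1) / np.log(s2)) / np.log(t1 / t2)
    if kappa <= 0:
        raise ValueError("survival constraints not monotone")
    eta = -np.log(s1) / t1 ** kappa
    return float(eta), float(kappa)


def simulate_block_covariates(n, p, rho, m, rng: np.random.Generator) -> np.ndarray:
    """n x p Gaussian matrix, correlation rho^|i-j| within blocks of size m."""
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    X = np.empty((n, p))
    for start in range(0, p, m):
        width = min(m, p - start)
        # AR(1) innovation form: x_1 = z_1, x_j = rho x_{j-1} + sqrt(1-rho^2) z_j
        Z = rng.standard_normal((n, width))
        B = np.empty_like(Z)
        B[:, 0] = Z[:, 0]
        scale = np.sqrt(1.0 - rho * rho)
        for j in range(1, width):
            B[:, j] = rho * B[:, j - 1] + scale * Z[:, j]
        X[:, start:start + width] = B
    return X


def simulate_event_times(X, beta, eta, kappa, rng: np.random.Generator) -> np.ndarray:
    """Latent (uncensored) event times by inverse-probability transform."""
    if eta <= 0 or kappa <= 0:
        raise ValueError("eta and kappa must be positive")
    lp = np.asarray(X) @ np.asarray(beta)
    U = rng.uniform(size=lp.shape[0])
    return (-np.log(U) / (eta * np.exp(lp))) ** (1.0 / kappa)


def apply_censoring(t_star, rng: np.random.Generator,
                    admin_max: float = DEFAULT_ADMIN_MAX,
                    dropout_rate: float = DEFAULT_DROPOUT_RATE):
    """Censor latent times by min(Uniform(0, admin_max), Exp(dropout_rate)).

    Returns ``(t, delta)`` with ``t = min(T*, C*)`` and ``delta = 1`` iff
    ``T* <= C*`` (ties count as events).  ``admin_max=None`` or
    ``dropout_rate=0`` disable the respective component; with both disabled
    every subject is an event.
    """
    t_star = np.asarray(t_star, dtype=float)
    n = t_star.shape[0]
    c = np.full(n, np.inf)
    if admin_max is not None and np.isfinite(admin_max):
        c = np.minimum(c, rng.uniform(0.0, admin_max, size=n))
    if dropout_rate and dropout_rate > 0:
        c = np.minimum(c, rng.exponential(1.0 / dropout_rate, size=n))
    delta = (t_star <= c).astype(int)
    t = np.minimum(t_star, c)
    return t, delta


def make_scenario(kind: str, seed: int = 0, n: int = 200, p: int = 500,
                  rho: float = 0.5, block_size: int = 100) -> SimulationScenario:
    """Build the sparse or nonsparse effect scenario."""
    eta, kappa = weibull_from_quantiles(12.0, 0.9, 36.0, 0.5)
    beta = np.zeros(p)
    if kind == "sparse":
        coef = np.array([0.75, -0.75, 0.5, -0.5, 0.25, -0.25])
        beta[:6] = coef
        k_true = 6
    elif kind == "nonsparse":
        k_true = 122
        # stream distinct from the dataset draws under the same seed
        rng = np.random.default_rng([seed, 7])
        half = k_true // 2
        mags = rng.uniform(0.2, 0.8, size=k_true)
        signs = np.concatenate([np.ones(k_true - half), -np.ones(half)])
        rng.shuffle(signs)
        beta[:k_true] = signs * mags
    else:
        raise ValueError(f"unknown scenario kind: {kind!r}")
    return SimulationScenario(n=n, p=p, beta_true=beta, k_true=k_true, rho=rho,
                              block_size=block_size, eta=eta, kappa=kappa,
                              seed=seed, name=kind)


def simulate_dataset(scenario: SimulationScenario, seed: int | None = None):
    """Draw one full dataset (X, t, delta) for a scenario.

    A distinct ``seed`` generates an independent replicate (e.g. a test set)
    under the same scenario.
    """
    rng = np.random.default_rng([scenario.seed if seed is None else seed, 11])
    X = simulate_block_covariates(scenario.n, scenario.p, scenario.rho,
                                  scenario.block_size, rng)
    t_star = simulate_event_times(X, scenario.beta_true, scenario.eta,
                                  scenario.kappa, rng)
    t, delta = apply_censoring(t_star, rng, scenario.admin_max,
                               scenario.dropout_rate)
    return X, t, delta
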
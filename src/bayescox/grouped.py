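"""Grouped-data survival likelihood on a finite partition of the time axis.

The semiparametric proportional-hazards model is discretized on a partition
``0 = s_0 < s_1 < ... < s_J`` of the time axis.  Within interval
``I_j = (s_{j-1}, s_j]`` the cumulative baseline hazard increases by an
increment ``h_j > 0``, and a subject with linear predictor ``x'beta`` survives
the interval with probability ``exp(-h_j * exp(x'beta))``.  The increments
carry independent gamma-process priors centred on an initial Weibull guess
``H*(t) = eta0 * t**kappa0`` with confidence weight ``c0``:

    h_j ~ Gamma(shape = c0*(H*(s_j) - H*(s_{j-1})) + d_j-free prior form)

The functions here build the partition, evaluate the grouped log-likelihood,
and calibrate ``(eta0, kappa0)`` to the Nelson-Aalen estimate of the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lifelines import NelsonAalenFitter


@dataclass(frozen=True)
class TimePartition:
    """Partition of the time axis with per-interval risk and event sets.

    Attributes
    ----------
    breaks : ndarray, shape (J+1,)
        ``s_0 = 0 < s_1 < ... < s_J`` with ``s_J`` strictly beyond the
        largest observed time.  Intervals are half-open: ``I_j = (s_{j-1}, s_j]``.
    risk_sets : list of ndarray
        ``R_j`` — 0-based subject indices at risk entering interval j
        (``t > s_{j-1}``).
    event_sets : list of ndarray
        ``D_j`` — subjects with an event in interval j.
    """

    breaks: np.ndarray
    risk_sets: list = field(repr=False, default_factory=list)
    event_sets: list = field(repr=False, default_factory=list)

    @property
    def n_intervals(self) -> int:
        return len(self.breaks) - 1

    @property
    def event_counts(self) -> np.ndarray:
        """Number of events d_j per interval."""
        return np.array([len(d) for d in self.event_sets])

    def interval_of(self, times: np.ndarray) -> np.ndarray:
        """0-based interval index j such that s_{j-1} < t <= s_j."""
        t = np.asarray(times, dtype=float)
        idx = np.searchsorted(self.breaks, t, side="left") - 1
        return np.clip(idx, 0, self.n_intervals - 1)


@dataclass(frozen=True)
class BaselineHazardPrior:
    """Gamma-process prior on the cumulative-hazard increments.

    ``alpha_0j = c0 * H*(s_j)`` with ``H*(t) = eta0 * t**kappa0``; the prior on
    ``h_j`` is ``Gamma(alpha_0j - alpha_0,j-1, rate=c0)`` so that
    ``E[h_j] = H*(s_j) - H*(s_{j-1})``.
    """

    c0: float
    eta0: float
    kappa0: float
    alpha_increments: np.ndarray

    def __post_init__(self):
        if self.c0 <= 0 or self.eta0 <= 0 or self.kappa0 <= 0:
            raise ValueError("c0, eta0 and kappa0 must all be positive")
        if np.any(self.alpha_increments <= 0):
            raise ValueError("alpha increments must be strictly positive")

    @property
    def prior_mean_h(self) -> np.ndarray:
        return self.alpha_increments / self.c0


def partition_time_axis(times, status) -> TimePartition:
    """Build the event-time partition of the time axis.

    Breaks are placed at the distinct event times, except that the largest
    event time ``t_max`` is replaced by ``s_J = s_{J-1} + 2*(t_max - s_{J-1})``
    so the last event sits in the middle of the final interval.

    Raises
    ------
    ValueError
        If no subject experienced an event.
    """
    times = np.asarray(times, dtype=float)
    status = np.asarray(status)
    event_times = np.unique(times[status == 1])
    if event_times.size == 0:
        raise ValueError("cannot partition without events")
    t_max = event_times[-1]
    inner = event_times[:-1]
    s_prev = inner[-1] if inner.size else 0.0
    s_last = s_prev + 2.0 * (t_max - s_prev)
    breaks = np.concatenate(([0.0], inner, [s_last]))
    # tolerate censoring times beyond the last break (events define it)
    if times.max() > s_last:
        breaks[-1] = np.nextafter(times.max(), np.inf)

    n_int = len(breaks) - 1
    risk_sets, event_sets = [], []
    for j in range(n_int):
        lo, hi = breaks[j], breaks[j + 1]
        at_risk = np.nonzero(times > lo)[0]
        events = np.nonzero((status == 1) & (times > lo) & (times <= hi))[0]
        risk_sets.append(at_risk)
        event_sets.append(events)
    return TimePartition(breaks=breaks, risk_sets=risk_sets, event_sets=event_sets)


def grouped_log_likelihood(beta, h, partition: TimePartition, X, times=None,
                           status=None) -> float:
    """Log of the grouped-data likelihood.

    log L = sum_j [ -h_j * sum_{i in R_j \\ D_j} exp(x_i'beta)
                    + sum_{i in D_j} log(1 - exp(-h_j exp(x_i'beta))) ]

    All arithmetic is done in log space via ``log1p``/``expm1`` so small
    ``h_j`` do not underflow.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h <= 0):
        raise ValueError("all interval hazard increments h_j must be positive")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    beta = np.asarray(beta, dtype=float)
    eta = X @ beta
    # clip only to avoid inf*0; exp(700) is already beyond any plausible risk
    e = np.exp(np.clip(eta, -700.0, 700.0))
    total = 0.0
    for j in range(partition.n_intervals):
        rj = partition.risk_sets[j]
        dj = partition.event_sets[j]
        surv = np.setdiff1d(rj, dj, assume_unique=True)
        total -= h[j] * e[surv].sum()
        if dj.size:
            total += np.log(-np.expm1(-h[j] * e[dj])).sum()
    return float(total)


def nelson_aalen(times, status):
    """Nelson-Aalen estimate of the cumulative hazard.

    Returns ``(t, H)`` arrays: the ordered distinct event times and the value
    of ``H_hat = sum d_i/n_i`` at each.  With no events both arrays are empty
    (the estimate is identically zero).
    """
    times = np.asarray(times, dtype=float)
    status = np.asarray(status)
    if not np.any(status == 1):
        return np.array([]), np.array([])
    naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
    naf.fit(times, event_observed=status)
    ch = naf.cumulative_hazard_.iloc[:, 0]
    jump = ch.diff().fillna(ch.iloc[0]) > 0
    t = ch.index.values[jump.values]
    H = ch.values[jump.values]
    return np.asarray(t, dtype=float), np.asarray(H, dtype=float)


def fit_weibull_initial(times, status) -> tuple[float, float]:
    """Calibrate the Weibull initial guess ``H*(t) = eta0 * t**kappa0``.

    Ordinary least squares of ``log H_hat(t)`` on ``log t`` over the
    Nelson-Aalen jump points: the slope is ``kappa0`` and the intercept
    ``log eta0``.

    Raises
    ------
    ValueError
        With fewer than two distinct event times.
    """
    t, H = nelson_aalen(times, status)
    if t.size < 2:
        raise ValueError("need at least two distinct event times to calibrate H*")
    slope, intercept = np.polyfit(np.log(t), np.log(H), 1)
    return float(np.exp(intercept)), float(slope)


def alpha_increments(partition: TimePartition, eta0: float, kappa0: float,
                     c0: float) -> np.ndarray:
    """Per-interval increments ``alpha_0j - alpha_0,j-1 = c0*eta0*(s_j^k - s_{j-1}^k)``."""
    if c0 <= 0 or eta0 <= 0 or kappa0 <= 0:
        raise ValueError("c0, eta0, kappa0 must be positive")
    Hstar = c0 * eta0 * partition.breaks ** kappa0
    return np.diff(Hstar)


def calibrate_baseline_prior(times, status, partition: TimePartition,
                             c0: float = 2.0) -> BaselineHazardPrior:
    """Fit the Weibull guess to the data and package the gamma-process prior."""
    eta0, kappa0 = fit_weibull_initial(times, status)
    inc = alpha_increments(partition, eta0, kappa0, c0)
    return BaselineHazardPrior(c0=c0, eta0=eta0, kappa0=kappa0, alpha_increments=inc)
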
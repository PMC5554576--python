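"""MCMC mixing diagnostics: running means, ESS, trace summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class TraceSummary:
    """Per-iteration summary traces of a stored chain."""

    loglik: np.ndarray
    model_size: np.ndarray
    beta_l2: np.ndarray


def running_means(samples) -> np.ndarray:
    """Cumulative means r_k = (1/k) sum_{j<=k} x_j along axis 0."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample array")
    k = np.arange(1, x.shape[0] + 1, dtype=float)
    if x.ndim == 1:
        return np.cumsum(x) / k
    return np.cumsum(x, axis=0) / k[:, None]


def effective_sample_size(series) -> float:
    """ESS = N / (1 + 2 * sum_k rho_k), initial-positive-sequence truncation.

    Autocorrelations are summed until the first nonpositive estimate.  A
    constant series has no information and returns 0 by convention.
    """
    x = np.asarray(series, dtype=float)
    n = x.shape[0]
    if n < 10:
        raise ValueError("series too short for an ESS estimate")
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var == 0:
        return 0.0
    # FFT autocovariance
    m = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real / n
    rho = acov / acov[0]
    s = 0.0
    for k in range(1, n):
        if rho[k] <= 0:
            break
        s += rho[k]
    return float(min(n, n / (1.0 + 2.0 * s)))


def trace_summaries(result) -> TraceSummary:
    """L2 norm of beta, model size and log likelihood per stored iteration."""
    beta = np.asarray(result.beta, dtype=float)
    gamma = np.asarray(result.gamma)
    if beta.size == 0:
        raise ValueError("no stored samples")
    return TraceSummary(loglik=np.asarray(result.loglik, dtype=float),
                        model_size=gamma.sum(axis=1).astype(float),
                        beta_l2=np.linalg.norm(beta, axis=1))


def ess_per_coordinate(beta_samples) -> np.ndarray:
    """Effective sample size of each coefficient's chain."""
    beta = np.asarray(beta_samples, dtype=float)
    return np.array([effective_sample_size(beta[:, i])
                     for i in range(beta.shape[1])])


def plot_diagnostics(result, path, coords=None):
    """Write running-mean and summary-trace plots to ``path`` (PNG).

    ``coords`` selects which coefficients' running means to draw (default:
    the 8 with the largest posterior mean magnitude).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    beta = np.asarray(result.beta, dtype=float)
    tr = trace_summaries(result)
    if coords is None:
        coords = np.argsort(-np.abs(beta.mean(axis=0)))[:8]

    fig, axes = plt.subplots(2, 2, figsize=(10, 7))
    rm = running_means(beta[:, coords])
    for k, c in enumerate(coords):
        axes[0, 0].plot(rm[:, k], lw=0.8, label=f"x{c + 1}")
    axes[0, 0].set_title("running means of beta")
    axes[0, 0].legend(fontsize=6, ncol=2)
    axes[0, 1].plot(tr.loglik, lw=0.5)
    axes[0, 1].set_title("log likelihood")
    axes[1, 0].plot(tr.model_size, lw=0.5)
    axes[1, 0].set_title("model size")
    axes[1, 1].plot(tr.beta_l2, lw=0.5)
    axes[1, 1].set_title("L2 norm of beta")
    for ax in axes.flat:
        ax.set_xlabel("stored iteration")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
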
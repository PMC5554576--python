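"""Posterior selection summaries and Brier-score prediction evaluation.

Variable selection follows the mean-model-size rule: the posterior mean
number of included variables per iteration, rounded, gives the cutoff count
``p_m``, and the ``p_m`` features with the highest posterior inclusion
probabilities form the top model.

Prediction error is measured by the censoring-weighted (IPCW) Brier score of
Graf et al.:

    BS(t) = 1/n * sum_l [ S_hat(t|x_l)^2 * 1{t_l <= t, event} / G(t_l-)
                          + (1 - S_hat(t|x_l))^2 * 1{t_l > t} / G(t) ]

with ``G`` the Kaplan-Meier estimate of the censoring distribution on the
evaluation set; terms whose weight denominator is zero are dropped.  The
integrated Brier score is the time average of BS over [0, t_max].  The
reference model is the covariate-free Kaplan-Meier curve of the training
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter

from .grouped import TimePartition


# ---------------------------------------------------------------------------
# selection summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionSummary:
    inclusion_probs: np.ndarray
    p_m: int
    selected: np.ndarray            # indices, size p_m
    beta_mean: np.ndarray
    beta_sd: np.ndarray


def summarize_selection(gamma_samples, beta_samples) -> SelectionSummary:
    """Posterior inclusion probabilities, mean model size and top model."""
    gamma_samples = np.asarray(gamma_samples)
    beta_samples = np.asarray(beta_samples)
    if gamma_samples.size == 0:
        raise ValueError("no posterior samples to summarize")
    probs = gamma_samples.mean(axis=0)
    mean_size = gamma_samples.sum(axis=1).mean()
    p_m = int(np.floor(mean_size + 0.5))        # round half up
    order = np.argsort(-probs, kind="stable")   # ties -> lower index first
    selected = np.sort(order[:p_m])
    return SelectionSummary(inclusion_probs=probs, p_m=p_m, selected=selected,
                            beta_mean=beta_samples.mean(axis=0),
                            beta_sd=beta_samples.std(axis=0, ddof=1))


def confusion_counts(selected, truth_indices, p: int):
    """(TP, FN, FP, TN) of a selected set against the simulation truth."""
    sel = set(np.asarray(selected, dtype=int).tolist())
    truth = set(np.asarray(truth_indices, dtype=int).tolist())
    tp = len(sel & truth)
    fn = len(truth - sel)
    fp = len(sel - truth)
    tn = p - tp - fn - fp
    return tp, fn, fp, tn


# ---------------------------------------------------------------------------
# survival prediction from the selected model
# ---------------------------------------------------------------------------

@dataclass
class PredictionResult:
    grid: np.ndarray
    surv: np.ndarray                  # (n_subjects, len(grid))
    bs: np.ndarray = None             # model Brier curve
    ibs: float = np.nan
    bs_reference: np.ndarray = None   # Kaplan-Meier reference curve
    ibs_reference: float = np.nan
    extrapolated: bool = field(default=False, repr=False)


def predict_survival(summary: SelectionSummary, h_samples,
                     partition: TimePartition, X_new, grid) -> PredictionResult:
    """Plug-in survival curves S(t|x) = exp(-H0(t) * exp(x'beta_sel)).

    ``H0`` is the step cumulative sum of the posterior-mean interval
    increments (jumps at the partition breaks); ``beta_sel`` keeps the
    posterior means of the selected variables and zeroes the rest.  Beyond
    the last break the curve is extrapolated flat.
    """
    grid = np.asarray(grid, dtype=float)
    h_bar = np.asarray(h_samples).mean(axis=0)
    breaks = partition.breaks
    H0 = np.concatenate([[0.0], np.cumsum(h_bar)])
    # step function: H0(t) = sum of increments of intervals ending at or before t
    H0_grid = H0[np.searchsorted(breaks, grid, side="right") - 1]
    beta_sel = np.zeros_like(summary.beta_mean)
    beta_sel[summary.selected] = summary.beta_mean[summary.selected]
    risk = np.exp(np.asarray(X_new) @ beta_sel)
    surv = np.exp(-np.outer(risk, H0_grid))
    return PredictionResult(grid=grid, surv=surv,
                            extrapolated=bool(grid.max() > breaks[-1]))


def km_curve(times, status, grid) -> np.ndarray:
    """Kaplan-Meier survival probabilities evaluated on a grid."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, float), event_observed=np.asarray(status))
    return kmf.survival_function_at_times(np.asarray(grid, float)).to_numpy()


def censoring_survival(times, status):
    """Step function of the censoring KM estimate G; returns (jump_times, G)."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, float),
            event_observed=1 - np.asarray(status))
    sf = kmf.survival_function_.iloc[:, 0]
    return sf.index.to_numpy(dtype=float), sf.to_numpy(dtype=float)


def _step_eval(jump_t, values, t, left=False):
    """Right-continuous step function evaluation (left limit if ``left``)."""
    side = "left" if left else "right"
    idx = np.searchsorted(jump_t, t, side=side) - 1
    out = np.ones_like(np.asarray(t, dtype=float))
    pos = idx >= 0
    out[pos] = values[np.clip(idx, 0, len(values) - 1)][pos]
    return out


def brier_curve(pred_surv, test_times, test_status, grid) -> np.ndarray:
    """Graf IPCW Brier score on a grid.

    ``pred_surv`` is an (n, len(grid)) matrix of predicted survival
    probabilities for the evaluation subjects; censoring weights come from
    the Kaplan-Meier estimate of the censoring distribution on the
    evaluation set itself.
    """
    t = np.asarray(test_times, dtype=float)
    d = np.asarray(test_status, dtype=int)
    grid = np.asarray(grid, dtype=float)
    S = np.atleast_2d(np.asarray(pred_surv, dtype=float))
    n = t.shape[0]
    if S.shape != (n, grid.shape[0]):
        raise ValueError("pred_surv must be (n_subjects, len(grid))")

    gt, gv = censoring_survival(t, d)
    G_at_grid = _step_eval(gt, gv, grid)            # G(t), right-continuous
    G_at_tminus = _step_eval(gt, gv, t, left=True)  # G(t_l-)

    bs = np.empty(grid.shape[0])
    for k, tk in enumerate(grid):
        died = (t <= tk) & (d == 1)
        alive = t > tk
        terms = np.zeros(n)
        w_died = np.where(G_at_tminus[died] > 0, 1.0 / G_at_tminus[died], 0.0)
        terms[died] = S[died, k] ** 2 * w_died
        if G_at_grid[k] > 0:
            terms[alive] = (1.0 - S[alive, k]) ** 2 / G_at_grid[k]
        bs[k] = terms.sum() / n
    return bs


def integrated_brier_score(grid, bs_curve) -> float:
    """Time-averaged Brier score: trapezoid integral over the grid span."""
    grid = np.asarray(grid, dtype=float)
    bs_curve = np.asarray(bs_curve, dtype=float)
    if grid.size < 2:
        raise ValueError("need at least two grid points to integrate")
    span = grid[-1] - grid[0]
    return float(np.trapezoid(bs_curve, grid) / span)


def evaluation_grid(test_times, test_status, t_max: float) -> np.ndarray:
    """All unique test event times up to t_max, plus the endpoints 0 and t_max."""
    t = np.asarray(test_times, dtype=float)
    d = np.asarray(test_status, dtype=int)
    ev = np.unique(t[(d == 1) & (t <= t_max)])
    return np.unique(np.concatenate([[0.0], ev, [t_max]]))


def evaluate_prediction(summary: SelectionSummary, h_samples,
                        partition: TimePartition, X_test, test_times,
                        test_status, train_times, train_status,
                        t_max: float = 80.0) -> PredictionResult:
    """Full evaluation: model and Kaplan-Meier-reference Brier curves + IBS."""
    grid = evaluation_grid(test_times, test_status, t_max)
    pred = predict_survival(summary, h_samples, partition, X_test, grid)
    pred.bs = brier_curve(pred.surv, test_times, test_status, grid)
    pred.ibs = integrated_brier_score(grid, pred.bs)
    km = km_curve(train_times, train_status, grid)
    ref = np.tile(km, (len(np.asarray(test_times)), 1))
    pred.bs_reference = brier_curve(ref, test_times, test_status, grid)
    pred.ibs_reference = integrated_brier_score(grid, pred.bs_reference)
    return pred
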
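"""Model/Results interface to the Bayesian Cox spike-and-slab sampler.

``BayesCoxSSVS`` is built from data (or a :class:`~bayescox.datasets.SurvivalDataset`),
holds the prior configuration, and its :meth:`fit` runs the Gibbs sampler
(optionally with parallel tempering or several pooled chains) and returns a
:class:`BayesCoxResults` carrying the posterior samples, selection summary,
diagnostics, prediction and a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datasets import SurvivalDataset
from .diagnostics import ess_per_coordinate, trace_summaries
from .evaluate import (PredictionResult, SelectionSummary, confusion_counts,
                       evaluate_prediction, predict_survival,
                       summarize_selection)
from .priors import SelectionPrior, SpikeSlabPrior, uniform_selection_prior
from .sampler import (ChainConfig, ChainResult, combine_chains, prepare,
                      run_chain)
from .tempering import TemperatureLadder, run_parallel_tempering


class BayesCoxSSVS:
    """Bayesian semiparametric Cox model with stochastic search selection.

    Parameters
    ----------
    times, status, X : array-like
        Right-censored survival data (status 1 = event) and an n x p
        covariate matrix.
    selection_prior : SelectionPrior or array-like, optional
        Per-feature prior inclusion probabilities; defaults to the
        uninformative prior pi = k/p.
    spike_slab : SpikeSlabPrior, optional
        Coefficient mixture prior (default tau = 0.0375, cb = 20, i.e.
        slab sd 0.75).
    c0 : float
        Confidence weight of the gamma-process baseline-hazard prior.
    k : float
        A-priori expected model size for the default uninformative prior.
    """

    def __init__(self, times, status, X, feature_names=None,
                 selection_prior=None, spike_slab: SpikeSlabPrior | None = None,
                 c0: float = 2.0, k: float = 20.0):
        self.times = np.asarray(times, dtype=float)
        self.status = np.asarray(status, dtype=int)
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        p = self.X.shape[1]
        self.feature_names = list(feature_names) if feature_names is not None \
            else [f"x{i + 1}" for i in range(p)]
        if selection_prior is None:
            selection_prior = uniform_selection_prior(p, min(k, p))
        elif not isinstance(selection_prior, SelectionPrior):
            pi = np.asarray(selection_prior, dtype=float)
            selection_prior = SelectionPrior(pi=pi, k=float(pi.sum()))
        self.selection_prior = selection_prior
        self.spike_slab = spike_slab or SpikeSlabPrior()
        self.c0 = c0
        self.data, self.baseline = prepare(self.times, self.status, self.X,
                                           c0=c0)
        self.partition = self.data.partition

    @classmethod
    def from_dataset(cls, ds: SurvivalDataset, **kwargs) -> "BayesCoxSSVS":
        return cls(ds.times, ds.status, ds.X,
                   feature_names=ds.feature_names, **kwargs)

    def fit(self, n_iter: int = 20_000, burn_in: int = 5_000, thin: int = 1,
            seed: int = 0, n_chains: int = 1,
            tempering: TemperatureLadder | bool = False,
            **config_kwargs) -> "BayesCoxResults":
        """Run the Gibbs sampler and return a results object.

        ``n_chains > 1`` runs independent chains with offset seeds and pools
        their post-burn-in samples.  ``tempering`` may be a
        :class:`TemperatureLadder` (or ``True`` for the default ladder); it
        returns the untempered chain.
        """
        def cfg(s):
            return ChainConfig(n_iter=n_iter, burn_in=burn_in, thin=thin,
                               seed=s, **config_kwargs)

        if tempering:
            ladder = tempering if isinstance(tempering, TemperatureLadder) \
                else TemperatureLadder()
            result = run_parallel_tempering(
                self.times, self.status, self.X, self.selection_prior,
                self.spike_slab, cfg(seed), ladder,
                partition=self.partition, baseline=self.baseline)
        elif n_chains == 1:
            result = run_chain(self.times, self.status, self.X,
                               self.selection_prior, self.spike_slab,
                               cfg(seed), partition=self.partition,
                               baseline=self.baseline)
        else:
            chains = [run_chain(self.times, self.status, self.X,
                                self.selection_prior, self.spike_slab,
                                cfg(seed + 1000 * c), partition=self.partition,
                                baseline=self.baseline)
                      for c in range(n_chains)]
            result = combine_chains(chains)
        return BayesCoxResults(self, result)


class BayesCoxResults:
    """Posterior samples with selection, prediction and diagnostics."""

    def __init__(self, model: BayesCoxSSVS, chain: ChainResult):
        self.model = model
        self.chain = chain
        self._selection: SelectionSummary | None = None

    # -- selection --------------------------------------------------------
    @property
    def selection(self) -> SelectionSummary:
        if self._selection is None:
            self._selection = summarize_selection(self.chain.gamma,
                                                  self.chain.beta)
        return self._selection

    @property
    def inclusion_probs(self) -> np.ndarray:
        return self.selection.inclusion_probs

    @property
    def mean_model_size(self) -> int:
        return self.selection.p_m

    @property
    def selected(self) -> np.ndarray:
        return self.selection.selected

    @property
    def params(self) -> np.ndarray:
        """Posterior mean of beta."""
        return self.selection.beta_mean

    def confusion(self, truth_indices):
        return confusion_counts(self.selected, truth_indices, self.model.X.shape[1])

    def summary(self) -> pd.DataFrame:
        """Per-feature posterior summary, ordered by inclusion probability."""
        s = self.selection
        df = pd.DataFrame({
            "feature": self.model.feature_names,
            "beta_mean": s.beta_mean,
            "beta_sd": s.beta_sd,
            "inclusion_prob": s.inclusion_probs,
        })
        df["selected"] = df.index.isin(s.selected)
        return df.sort_values("inclusion_prob", ascending=False,
                              kind="stable").reset_index(drop=True)

    # -- prediction -------------------------------------------------------
    def predict_survival(self, X_new, times) -> PredictionResult:
        return predict_survival(self.selection, self.chain.h,
                                self.model.partition, X_new, times)

    def evaluate(self, X_test, test_times, test_status, t_max: float = 80.0,
                 mode: str = "plugin", refit_iters: int = 4_000,
                 refit_burn_in: int = 1_000) -> PredictionResult:
        """Brier curve and IBS on a test set, vs the Kaplan-Meier reference.

        ``mode="plugin"`` predicts from the posterior means of this run
        restricted to the selected variables; ``mode="refit"`` reruns the
        sampler on the selected variables only (all included a priori) and
        predicts from that fit's posterior means.
        """
        if mode == "plugin":
            summary, h, partition = self.selection, self.chain.h, \
                self.model.partition
            X_eval = X_test
        elif mode == "refit":
            sel = self.selected
            if sel.size == 0:
                summary, h = self.selection, self.chain.h
                partition, X_eval = self.model.partition, X_test
            else:
                sub = BayesCoxSSVS(self.model.times, self.model.status,
                                   self.model.X[:, sel],
                                   selection_prior=np.ones(sel.size),
                                   spike_slab=self.model.spike_slab,
                                   c0=self.model.c0)
                res = sub.fit(n_iter=refit_iters, burn_in=refit_burn_in,
                              seed=self.chain.config.seed)
                summary, h = res.selection, res.chain.h
                partition = sub.partition
                X_eval = np.asarray(X_test)[:, sel]
        else:
            raise ValueError(f"unknown prediction mode {mode!r}")
        return evaluate_prediction(summary, h, partition, X_eval,
                                   test_times, test_status,
                                   self.model.times, self.model.status,
                                   t_max=t_max)

    # -- diagnostics ------------------------------------------------------
    def trace_summaries(self):
        return trace_summaries(self.chain)

    def effective_sample_sizes(self) -> np.ndarray:
        return ess_per_coordinate(self.chain.beta)

    @property
    def swap_acceptance_rate(self) -> float:
        return getattr(self.chain, "swap_acceptance_rate", np.nan)
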
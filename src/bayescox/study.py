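"""Simulation-study pipelines: one call per study arm.

Each arm generates an independent training and test dataset for a scenario,
fits the model under one of the three selection priors (uninformative,
correct informative, incorrect informative), and evaluates selection against
the simulation truth and prediction by the integrated Brier score against
the Kaplan-Meier reference.  These are the entry points used by the
acceptance script and the heavier end-to-end tests.
"""

from __future__ import annotations

import numpy as np

from .model import BayesCoxSSVS
from .priors import scenario_prior, uniform_selection_prior
from .simulate import make_scenario, simulate_dataset
from .tempering import run_parallel_tempering, tune_ladder
from .sampler import ChainConfig

#: offset separating the test-set stream from the training stream
TEST_SEED_OFFSET = 5_000


def _build_prior(kind: str, scenario, seed: int):
    if kind == "uninformative":
        return uniform_selection_prior(scenario.p, 20.0)
    return scenario_prior(kind, scenario.truth_indices, scenario.p,
                          rng=np.random.default_rng([seed, 23]))


def run_arm(scenario_kind: str, prior_kind: str, seed: int,
            n_iter: int = 20_000, burn_in: int = 5_000,
            t_max: float = 80.0) -> dict:
    """Fit one scenario/prior arm and evaluate selection and prediction.

    Returns a dict with posterior inclusion probabilities, the mean model
    size ``p_m``, the confusion counts of the selected model against the
    simulation truth, the recovery percentage ``100 * TP / k_true``, and the
    test-set integrated Brier scores of the model and the Kaplan-Meier
    reference.
    """
    sc = make_scenario(scenario_kind, seed=seed)
    X, t, d = simulate_dataset(sc)
    X_te, t_te, d_te = simulate_dataset(sc, seed=seed + TEST_SEED_OFFSET)

    prior = _build_prior(prior_kind, sc, seed)
    model = BayesCoxSSVS(t, d, X, selection_prior=prior)
    res = model.fit(n_iter=n_iter, burn_in=burn_in, seed=seed)
    pred = res.evaluate(X_te, t_te, d_te, t_max=t_max)
    tp, fn, fp, tn = res.confusion(sc.truth_indices)
    return {
        "scenario": scenario_kind,
        "prior": prior_kind,
        "seed": seed,
        "inclusion_probs": res.inclusion_probs,
        "p_m": res.mean_model_size,
        "selected": res.selected,
        "tp": tp, "fn": fn, "fp": fp, "tn": tn,
        "recovery_pct": 100.0 * tp / sc.k_true,
        "ibs": pred.ibs,
        "ibs_reference": pred.ibs_reference,
        "accept_rate": res.chain.accept_rate,
        "results": res,
    }


def run_tempering_arm(seed: int, scenario_kind: str = "sparse",
                      prior_kind: str = "uninformative",
                      n_iter: int = 10_000, burn_in: int = 5_000,
                      n_chains: int = 6) -> dict:
    """Parallel tempering with the ladder base tuned during burn-in.

    The burn-in doubles as the tuning pilot (stochastic approximation on
    the log base toward ~50% swap acceptance, frozen at sampling start).
    Returns the tuned base, the stationary swap acceptance rate (as a
    percentage) and the cold chain's posterior inclusion probabilities.
    """
    sc = make_scenario(scenario_kind, seed=seed)
    X, t, d = simulate_dataset(sc)
    prior = _build_prior(prior_kind, sc, seed)

    from .tempering import TemperatureLadder
    ladder = TemperatureLadder(base=1.05, n_chains=n_chains)
    cfg = ChainConfig(n_iter=n_iter, burn_in=burn_in, seed=seed)
    res = run_parallel_tempering(t, d, X, prior, config=cfg, ladder=ladder,
                                 tune_target=0.48)
    return {
        "base": ladder.base,
        "swap_acceptance_pct": 100.0 * res.swap_acceptance_rate,
        "inclusion_probs": res.gamma.mean(axis=0),
        "results": res,
    }
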
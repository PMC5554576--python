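"""Numba inner loops for the coordinate-wise random-walk Metropolis sweep.

The kernels are pure functions: all randomness (proposal noise ``z`` and
acceptance uniforms ``u``) is drawn beforehand from a single numpy Generator,
so chains are reproducible bit-for-bit and the kernels can be checked against
a plain-Python oracle.

The grouped log-likelihood is maintained through two running terms,

    t1 = sum_l W_l * exp(eta_l)              (interval-exposure term)
    t2 = sum_{events l} log(1 - exp(-h_{j(l)} * exp(eta_l)))

where ``W_l`` is the total hazard mass of the intervals subject ``l`` fully
survives and ``h_{j(l)}`` the increment of the interval containing an event.
``logL = -t1 + t2``.  A single-coordinate move changes every ``eta_l`` by
``X[l, i] * delta``, so both terms are recomputed in O(n) per proposal.
"""

import numpy as np
from numba import njit

_EXP_CAP = 700.0


@njit(cache=True, fastmath=True)
def loglik_terms(eta, W, h_event, is_event):
    """Return (t1, t2) for the current linear predictor."""
    n = eta.shape[0]
    t1 = 0.0
    t2 = 0.0
    for l in range(n):
        x = eta[l]
        if x > _EXP_CAP:
            x = _EXP_CAP
        e = np.exp(x)
        t1 += W[l] * e
        if is_event[l]:
            t2 += np.log(-np.expm1(-h_event[l] * e))
    return t1, t2


@njit(cache=True, fastmath=True)
def beta_sweep(beta, gamma, eta, Xc, W, h_event, is_event,
               scales, tau, slab_sd, t1, t2, z, u, accepted):
    """One full sweep of per-coordinate RW-MH updates on beta (in place).

    Parameters are the current state (``beta``, ``gamma``, ``eta``), the
    column-major covariate matrix ``Xc``, likelihood bookkeeping
    (``W``, ``h_event``, ``is_event``, running terms ``t1``/``t2``),
    per-coordinate proposal ``scales``, the spike/slab standard deviations,
    pre-drawn standard normals ``z`` and uniforms ``u``, and an output
    ``accepted`` flag array.  Returns the updated ``(t1, t2)``.
    """
    n, p = Xc.shape
    for i in range(p):
        sd = slab_sd if gamma[i] == 1 else tau
        delta = z[i] * scales[i]
        b_old = beta[i]
        b_new = b_old + delta
        d_prior = (b_old * b_old - b_new * b_new) / (2.0 * sd * sd)

        t1_new = 0.0
        t2_new = 0.0
        ok = True
        for l in range(n):
            x = eta[l] + Xc[l, i] * delta
            if x > _EXP_CAP:
                x = _EXP_CAP
            e = np.exp(x)
            t1_new += W[l] * e
            if is_event[l]:
                arg = -np.expm1(-h_event[l] * e)
                if arg <= 0.0:
                    ok = False
                    break
                t2_new += np.log(arg)
        if not ok or not np.isfinite(t1_new) or not np.isfinite(t2_new):
            accepted[i] = 0
            continue

        d_log = -(t1_new - t1) + (t2_new - t2) + d_prior
        if np.log(u[i]) < d_log:
            beta[i] = b_new
            for l in range(n):
                eta[l] += Xc[l, i] * delta
            t1 = t1_new
            t2 = t2_new
            accepted[i] = 1
        else:
            accepted[i] = 0
    return t1, t2
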
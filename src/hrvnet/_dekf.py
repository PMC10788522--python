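"""Dual-extended-Kalman-filter inner loop for time-varying MVAR estimation.

Two coupled Kalman recursions run over the sample axis:

* the *state* filter tracks the stacked last ``p`` channel vectors with
  the companion-form transition built from the current coefficient
  estimates, and
* the *parameter* filter treats the MVAR coefficients as a random-walk
  state observed through the (linear, given the lagged state) regression
  onto the next sample.

Because the observation is linear in the coefficients once the lagged
state is fixed, the parameter filter decouples exactly into one scalar
-observation Kalman filter per target channel, which keeps the
per-sample cost at O(c * (p*c)^2).

The loop is compiled with numba when available; a pure-NumPy fallback
with identical semantics is used otherwise.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco


@njit(cache=True)
def dekf_loop(y, p, q_param, q_state, r_obs, rhat0, adapt, init_param_var):
    """Run the dual filter over ``y`` (channels x samples).

    Returns ``(coeff_traj, rhat, param_cov, state_cov, fail_at)`` where
    ``coeff_traj`` has shape ``(n - p, c, p*c)`` (row i holds target
    channel i's stacked lag-1..p coefficient rows at that sample),
    ``rhat`` is the adapted innovation variance per channel and
    ``fail_at`` is -1 on success or the sample index where the state
    became non-finite.
    """
    c, n = y.shape
    d = p * c

    theta = np.zeros((c, d))
    Ppar = np.zeros((c, d, d))
    for i in range(c):
        for a in range(d):
            Ppar[i, a, a] = init_param_var

    # state x_t = [y_t; y_{t-1}; ...; y_{t-p+1}], initialised from data
    x = np.zeros(d)
    for r in range(p):
        for i in range(c):
            x[r * c + i] = y[i, p - 1 - r]
    Px = np.eye(d) * 1e-2

    F = np.zeros((d, d))
    for a in range(d - c):
        F[c + a, a] = 1.0

    rhat = rhat0.copy()
    out = np.zeros((n - p, c, d))
    fail_at = -1

    for t in range(p, n):
        phi = x.copy()  # estimated [y_{t-1}; ...; y_{t-p}]

        # --- parameter filter, one scalar-observation KF per channel ---
        for i in range(c):
            P = Ppar[i].copy()
            for a in range(d):
                P[a, a] += q_param
            Pphi = P @ phi
            s = phi @ Pphi + rhat[i]
            e = y[i, t] - theta[i] @ phi
            K = Pphi / s
            theta[i] = theta[i] + K * e
            P = P - np.outer(K, Pphi)
            Ppar[i] = 0.5 * (P + P.T)
            if adapt > 0.0:
                r_new = (1.0 - adapt) * rhat[i] + adapt * e * e
                if r_new > 1e-12:
                    rhat[i] = r_new
        out[t - p] = theta

        # --- state filter with companion transition from fresh theta ---
        F[:c, :] = theta
        xp = F @ x
        Pxp = F @ Px @ F.T
        for a in range(d):
            Pxp[a, a] += q_state
        for i in range(c):
            Pxp[i, i] += rhat[i]
        S = Pxp[:c, :c].copy()
        for i in range(c):
            S[i, i] += r_obs[i]
        Sinv = np.linalg.inv(S)
        Kx = np.ascontiguousarray(Pxp[:, :c]) @ Sinv
        nu = np.ascontiguousarray(y[:, t]) - xp[:c]
        x = xp + Kx @ nu
        Px = Pxp - Kx @ np.ascontiguousarray(Pxp[:c, :])
        Px = 0.5 * (Px + Px.T)

        ok = True
        for a in range(d):
            if not np.isfinite(x[a]):
                ok = False
        if not ok:
            fail_at = t
            break

    return out, rhat, Ppar, Px, fail_at
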
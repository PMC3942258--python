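"""Numba-compiled numerical kernels.

Hot paths only: the right-hand sides on flattened arrays and the embedded
Dormand-Prince 4(5) driver with the negativity-clamping step hook and the
windowed convergence rule.  Everything here works on contiguous float64
vectors; shape handling and validation live in the public modules.
"""

import numpy as np
from numba import njit

# Dormand-Prince tableau
_A21 = 1.0 / 5.0
_A31, _A32 = 3.0 / 40.0, 9.0 / 40.0
_A41, _A42, _A43 = 44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0
_A51, _A52, _A53, _A54 = (
    19372.0 / 6561.0,
    -25360.0 / 2187.0,
    64448.0 / 6561.0,
    -212.0 / 729.0,
)
_A61, _A62, _A63, _A64, _A65 = (
    9017.0 / 3168.0,
    -355.0 / 33.0,
    46732.0 / 5247.0,
    49.0 / 176.0,
    -5103.0 / 18656.0,
)
_B1, _B3, _B4, _B5, _B6 = (
    35.0 / 384.0,
    500.0 / 1113.0,
    125.0 / 192.0,
    -2187.0 / 6784.0,
    11.0 / 84.0,
)
# 5th-minus-4th-order weights (error estimator)
_E1, _E3, _E4, _E5, _E6, _E7 = (
    71.0 / 57600.0,
    -71.0 / 16695.0,
    71.0 / 1920.0,
    -17253.0 / 339200.0,
    22.0 / 525.0,
    -1.0 / 40.0,
)

# driver exit codes
CONVERGED = 0
TIME_LIMIT = 1
STEP_UNDERFLOW = 2
NONFINITE = 3

_MIN_STEP = 1e-13


@njit(cache=True)
def rhs(mode, n_side, u, v, du, dv, alpha, beta, cloc, dd2, onsite):
    """du/dt, dv/dt into preallocated du, dv.

    mode 0: well-mixed (cloc = c); mode 1: 1D periodic chain (cloc = c1);
    mode 2: periodic n_side x n_side grid, row-major (cloc = c2).
    onsite != 0 collapses the contact kernel onto the focal site with the
    same total strength.
    """
    n = u.shape[0]
    if mode == 0:
        for i in range(n):
            du[i] = u[i] * (alpha - u[i] - v[i] * (1.0 + cloc))
            dv[i] = v[i] * (beta - u[i] - v[i])
    elif mode == 1:
        for i in range(n):
            ip = i + 1 if i + 1 < n else 0
            im = i - 1 if i >= 1 else n - 1
            if onsite:
                inhib = 3.0 * cloc * v[i]
            else:
                inhib = cloc * (v[ip] + v[i] + v[im])
            du[i] = u[i] * (alpha - u[i] - v[i] - inhib) + dd2 * (
                u[ip] - 2.0 * u[i] + u[im]
            )
            dv[i] = v[i] * (beta - u[i] - v[i]) + dd2 * (v[ip] - 2.0 * v[i] + v[im])
    else:
        m = n_side
        for r in range(m):
            rp = r + 1 if r + 1 < m else 0
            rm = r - 1 if r >= 1 else m - 1
            for q in range(m):
                qp = q + 1 if q + 1 < m else 0
                qm = q - 1 if q >= 1 else m - 1
                i = r * m + q
                iN = rm * m + q
                iS = rp * m + q
                iW = r * m + qm
                iE = r * m + qp
                if onsite:
                    inhib = 5.0 * cloc * v[i]
                else:
                    inhib = cloc * (v[i] + v[iN] + v[iS] + v[iW] + v[iE])
                lap_u = u[iN] + u[iS] + u[iW] + u[iE] - 4.0 * u[i]
                lap_v = v[iN] + v[iS] + v[iW] + v[iE] - 4.0 * v[i]
                du[i] = u[i] * (alpha - u[i] - v[i] - inhib) + dd2 * lap_u
                dv[i] = v[i] * (beta - u[i] - v[i]) + dd2 * lap_v


@njit(cache=True)
def integrate(
    u,
    v,
    mode,
    n_side,
    alpha,
    beta,
    cloc,
    dd2,
    onsite,
    atol,
    max_step,
    conv_tol,
    window,
    t0,
    t_stop,
    check_conv,
):
    """Adaptive RK45 drive of (u, v) in place.

    Per-step absolute error (max-norm over all components) is kept below
    `atol`; steps are capped at `max_step`.  A proposed step with any
    concentration below -atol is rejected and retried smaller; residual
    negatives within atol of zero are snapped to zero on acceptance.  If
    `check_conv`, the run stops once the mean over the last `window`
    accepted steps of the per-step maximal state change drops below
    `conv_tol`.

    Returns (t, n_accepted_steps, status).
    """
    n = u.shape[0]
    k1u = np.empty(n)
    k1v = np.empty(n)
    k2u = np.empty(n)
    k2v = np.empty(n)
    k3u = np.empty(n)
    k3v = np.empty(n)
    k4u = np.empty(n)
    k4v = np.empty(n)
    k5u = np.empty(n)
    k5v = np.empty(n)
    k6u = np.empty(n)
    k6v = np.empty(n)
    k7u = np.empty(n)
    k7v = np.empty(n)
    ytu = np.empty(n)
    ytv = np.empty(n)
    unew = np.empty(n)
    vnew = np.empty(n)

    buf = np.zeros(window)
    buf_sum = 0.0
    buf_idx = 0
    buf_count = 0

    t = t0
    h = min(max_step, 1e-3)
    if h > t_stop - t:
        h = t_stop - t
    nsteps = 0
    last_nonfinite = False

    while t < t_stop:
        # stage 1
        rhs(mode, n_side, u, v, k1u, k1v, alpha, beta, cloc, dd2, onsite)
        # stage 2
        for i in range(n):
            ytu[i] = u[i] + h * _A21 * k1u[i]
            ytv[i] = v[i] + h * _A21 * k1v[i]
        rhs(mode, n_side, ytu, ytv, k2u, k2v, alpha, beta, cloc, dd2, onsite)
        # stage 3
        for i in range(n):
            ytu[i] = u[i] + h * (_A31 * k1u[i] + _A32 * k2u[i])
            ytv[i] = v[i] + h * (_A31 * k1v[i] + _A32 * k2v[i])
        rhs(mode, n_side, ytu, ytv, k3u, k3v, alpha, beta, cloc, dd2, onsite)
        # stage 4
        for i in range(n):
            ytu[i] = u[i] + h * (_A41 * k1u[i] + _A42 * k2u[i] + _A43 * k3u[i])
            ytv[i] = v[i] + h * (_A41 * k1v[i] + _A42 * k2v[i] + _A43 * k3v[i])
        rhs(mode, n_side, ytu, ytv, k4u, k4v, alpha, beta, cloc, dd2, onsite)
        # stage 5
        for i in range(n):
            ytu[i] = u[i] + h * (
                _A51 * k1u[i] + _A52 * k2u[i] + _A53 * k3u[i] + _A54 * k4u[i]
            )
            ytv[i] = v[i] + h * (
                _A51 * k1v[i] + _A52 * k2v[i] + _A53 * k3v[i] + _A54 * k4v[i]
            )
        rhs(mode, n_side, ytu, ytv, k5u, k5v, alpha, beta, cloc, dd2, onsite)
        # stage 6
        for i in range(n):
            ytu[i] = u[i] + h * (
                _A61 * k1u[i]
                + _A62 * k2u[i]
                + _A63 * k3u[i]
                + _A64 * k4u[i]
                + _A65 * k5u[i]
            )
            ytv[i] = v[i] + h * (
                _A61 * k1v[i]
                + _A62 * k2v[i]
                + _A63 * k3v[i]
                + _A64 * k4v[i]
                + _A65 * k5v[i]
            )
        rhs(mode, n_side, ytu, ytv, k6u, k6v, alpha, beta, cloc, dd2, onsite)
        # 5th-order solution (also stage 7 location)
        for i in range(n):
            unew[i] = u[i] + h * (
                _B1 * k1u[i]
                + _B3 * k3u[i]
                + _B4 * k4u[i]
                + _B5 * k5u[i]
                + _B6 * k6u[i]
            )
            vnew[i] = v[i] + h * (
                _B1 * k1v[i]
                + _B3 * k3v[i]
                + _B4 * k4v[i]
                + _B5 * k5v[i]
                + _B6 * k6v[i]
            )
        rhs(mode, n_side, unew, vnew, k7u, k7v, alpha, beta, cloc, dd2, onsite)

        err = 0.0
        for i in range(n):
            eu = h * (
                _E1 * k1u[i]
                + _E3 * k3u[i]
                + _E4 * k4u[i]
                + _E5 * k5u[i]
                + _E6 * k6u[i]
                + _E7 * k7u[i]
            )
            ev = h * (
                _E1 * k1v[i]
                + _E3 * k3v[i]
                + _E4 * k4v[i]
                + _E5 * k5v[i]
                + _E6 * k6v[i]
                + _E7 * k7v[i]
            )
            if abs(eu) > err:
                err = abs(eu)
            if abs(ev) > err:
                err = abs(ev)

        if not np.isfinite(err):
            last_nonfinite = True
            h *= 0.1
            if h < _MIN_STEP:
                return t, nsteps, NONFINITE
            continue
        last_nonfinite = False

        ymin = unew[0]
        for i in range(n):
            if unew[i] < ymin:
                ymin = unew[i]
            if vnew[i] < ymin:
                ymin = vnew[i]

        if err > atol or ymin < -atol:
            # reject; shrink by the error-controller factor, at least halve
            # when the rejection came from negativity alone
            if err > atol:
                fac = 0.9 * (atol / err) ** 0.2
                if fac < 0.1:
                    fac = 0.1
            else:
                fac = 0.5
            h *= fac
            if h < _MIN_STEP:
                return t, nsteps, STEP_UNDERFLOW
            continue

        # accept: snap residual negatives (within atol of zero) to exactly 0,
        # then record the per-step maximal change for the convergence window
        delta = 0.0
        for i in range(n):
            if unew[i] < 0.0:
                unew[i] = 0.0
            if vnew[i] < 0.0:
                vnew[i] = 0.0
            cu = abs(unew[i] - u[i])
            cv = abs(vnew[i] - v[i])
            if cu > delta:
                delta = cu
            if cv > delta:
                delta = cv
            u[i] = unew[i]
            v[i] = vnew[i]
        t += h
        nsteps += 1

        if check_conv:
            buf_sum += delta - buf[buf_idx]
            buf[buf_idx] = delta
            buf_idx += 1
            if buf_idx == window:
                buf_idx = 0
            if buf_count < window:
                buf_count += 1
            elif buf_sum / window < conv_tol:
                return t, nsteps, CONVERGED

        if err > 0.0:
            fac = 0.9 * (atol / err) ** 0.2
            if fac > 5.0:
                fac = 5.0
        else:
            fac = 5.0
        h *= fac
        if h > max_step:
            h = max_step
        if h > t_stop - t:
            h = t_stop - t

    return t, nsteps, TIME_LIMIT
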
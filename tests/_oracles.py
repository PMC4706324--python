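"""Independent brute-force oracles used to validate the fast implementations."""

import numpy as np
from scipy.optimize import minimize_scalar


def tv1d_exact(y, lam):
    """Exact 1D total-variation denoising (Condat's direct non-iterative
    algorithm): argmin_x 1/2||x-y||^2 + lam * sum|x_{i+1}-x_i|.

    Independent of the dual (Chambolle-type) iteration used by the package.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    x = np.empty(n)
    k = k0 = km = kp = 0
    vmin = y[0] - lam
    vmax = y[0] + lam
    umin = lam
    umax = -lam
    while True:
        if k == n - 1:
            if umin < 0:
                while k0 <= km:
                    x[k0] = vmin
                    k0 += 1
                k = km = k0
                vmin = y[k]
                umin = lam
                umax = vmin + umin - vmax
            elif umax > 0:
                while k0 <= kp:
                    x[k0] = vmax
                    k0 += 1
                k = kp = k0
                vmax = y[k]
                umax = -lam
                umin = vmax + umax - vmin
            else:
                vmin += umin / (k - k0 + 1)
                while k0 <= k:
                    x[k0] = vmin
                    k0 += 1
                return x
        if umin + y[k + 1] - vmin < -lam:
            while k0 <= km:
                x[k0] = vmin
                k0 += 1
            k = k0 = km = kp = km + 1
            vmin = y[k]
            vmax = y[k] + 2 * lam
            umin = lam
            umax = -lam
        elif umax + y[k + 1] - vmax > lam:
            while k0 <= kp:
                x[k0] = vmax
                k0 += 1
            k = k0 = km = kp = kp + 1
            vmin = y[k] - 2 * lam
            vmax = y[k]
            umin = lam
            umax = -lam
        else:
            k += 1
            umin += y[k] - vmin
            umax += y[k] - vmax
            if umin >= lam:
                vmin += (umin - lam) / (k - k0 + 1)
                umin = lam
                km = k
            if umax <= -lam:
                vmax += (umax + lam) / (k - k0 + 1)
                umax = -lam
                kp = k
    raise AssertionError("unreachable")


def soft_threshold_oracle(z, t):
    """Per-element numeric minimization of 1/2(u-z)^2 + t|u|."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    for idx, zi in np.ndenumerate(z):
        res = minimize_scalar(
            lambda u: 0.5 * (u - zi) ** 2 + t * abs(u),
            bounds=(-abs(zi) - 1.0, abs(zi) + 1.0),
            method="bounded",
            options={"xatol": 1e-12},
        )
        out[idx] = res.x
    return out


def ssim_loop(x, y, window=8, c1=1e-4, c2=9e-4):
    """Naive per-window SSIM loop (population statistics, valid windows)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = x.shape
    vals = []
    for i in range(m - window + 1):
        for j in range(n - window + 1):
            wx = x[i : i + window, j : j + window]
            wy = y[i : i + window, j : j + window]
            mux, muy = wx.mean(), wy.mean()
            sxx = wx.var()
            syy = wy.var()
            sxy = ((wx - mux) * (wy - muy)).mean()
            vals.append(
                (2 * mux * muy + c1) * (2 * sxy + c2)
                / ((mux**2 + muy**2 + c1) * (sxx + syy + c2))
            )
    return float(np.mean(vals))


def spearman_formula(a, b):
    """Spearman rho via the classic rank-difference formula (distinct values)."""
    a = np.asarray(a)
    b = np.asarray(b)
    ra = np.argsort(np.argsort(a))
    rb = np.argsort(np.argsort(b))
    d = ra - rb
    n = len(a)
    return 1.0 - 6.0 * float(np.sum(d**2)) / (n * (n**2 - 1))
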
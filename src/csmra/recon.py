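"""FCSA compressed-sensing reconstruction.

Solves

    min_x  1/2 ||y - A x||_2^2 + alpha ||Psi x||_1 + beta TV(x)

where A = (sampling mask) o (centered unitary 3D FFT) o (coil multiply),
Psi is an orthonormal wavelet decomposition and TV is isotropic total
variation with forward differences and Neumann boundaries.  The composite
problem is split each iteration into a wavelet soft-threshold subproblem and
a TV-denoising subproblem; their solutions are averaged and a FISTA momentum
step is applied.  Under the unitary scaling ||A|| <= 1, so the fixed step
size 1 is valid and no line search is performed.  The solver runs a fixed
number of outer iterations (default 15) with no early stopping.

Images are complex throughout the solver; magnitude is taken only at the
metrics boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import logging

import numba
import numpy as np
import pywt

from .errors import InvalidArgumentError, NumericError
from .phantom import CoilSet, KSpace, Volume, fftc, ifftc
from .sampling import SamplingMask

log = logging.getLogger(__name__)


@dataclass
class ReconParams:
    """Solver settings; ``alpha`` weights the wavelet-L1 term, ``beta`` the TV term."""

    alpha: float
    beta: float
    n_iter: int = 15
    wavelet_name: str = "db4"
    wavelet_levels: int = 3
    tv_inner_iters: int = 10
    step_size: float = 1.0

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise InvalidArgumentError("alpha and beta must be >= 0")
        if self.n_iter < 1:
            raise InvalidArgumentError("n_iter must be >= 1")


@dataclass
class ReconProblem:
    """Masked data y, its sampling mask, coil maps (None = unit coil), and params."""

    y: KSpace
    mask: SamplingMask
    coils: CoilSet | None
    params: ReconParams


@dataclass
class ReconResult:
    image: Volume  # complex
    objective_trace: list = field(default_factory=list)
    params: ReconParams | None = None


# ---------------------------------------------------------------------------
# forward / adjoint encoding operators
# ---------------------------------------------------------------------------


def _sens(prob: ReconProblem) -> np.ndarray | None:
    if prob.coils is None:
        return None
    return prob.coils.sensitivities


def forward_op(x: np.ndarray, sens: np.ndarray | None, mask2d: np.ndarray) -> np.ndarray:
    """A x: coil-multiply, centered unitary FFT, undersample."""
    if sens is None:
        k = fftc(x)[None]
    else:
        k = fftc(sens * x[None])
    return k * mask2d[None, None, :, :]


def adjoint_op(k: np.ndarray, sens: np.ndarray | None, mask2d: np.ndarray) -> np.ndarray:
    """A* k: undersample, inverse FFT, conjugate-coil combine."""
    imgs = ifftc(k * mask2d[None, None, :, :])
    if sens is None:
        return imgs[0]
    return np.sum(np.conj(sens) * imgs, axis=0)


# ---------------------------------------------------------------------------
# regularizer building blocks
# ---------------------------------------------------------------------------


def soft_threshold(z: np.ndarray, t: float) -> np.ndarray:
    """Elementwise soft threshold; for complex input the phase is preserved.

    This is the proximal operator of t*||.||_1.
    """
    if t < 0:
        raise InvalidArgumentError("threshold must be >= 0")
    z = np.asarray(z)
    mag = np.abs(z)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(mag > 0, np.maximum(mag - t, 0.0) / np.where(mag > 0, mag, 1.0), 0.0)
    return z * scale


def _wavedec(z, name, levels):
    import warnings

    try:
        with warnings.catch_warnings():
            # periodization stays a perfect-reconstruction orthonormal
            # transform even when pywt flags boundary effects at this depth
            warnings.simplefilter("ignore", UserWarning)
            coeffs = pywt.wavedecn(z, name, mode="periodization", level=levels)
    except ValueError as exc:
        raise InvalidArgumentError(str(exc)) from exc
    return coeffs


def wavelet_l1(z: np.ndarray, name: str = "db4", levels: int = 3) -> float:
    """||Psi z||_1 for the orthonormal wavelet decomposition."""
    coeffs = _wavedec(z, name, levels)
    arr, _ = pywt.coeffs_to_array(coeffs)
    return float(np.sum(np.abs(arr)))


def wavelet_prox(z: np.ndarray, weight: float, step: float = 1.0,
                 name: str = "db4", levels: int = 3) -> np.ndarray:
    """Exact prox of weight*step*||Psi .||_1 for orthonormal Psi.

    Decompose, soft-threshold every coefficient (approximation band
    included, since the objective penalizes all of ||Psi x||_1), reconstruct.
    """
    if weight < 0:
        raise InvalidArgumentError("weight must be >= 0")
    if weight * step == 0:
        return _waverec_like(_wavedec(z, name, levels), name, z)
    coeffs = _wavedec(z, name, levels)
    arr, slices = pywt.coeffs_to_array(coeffs)
    arr = soft_threshold(arr, weight * step)
    coeffs = pywt.array_to_coeffs(arr, slices, output_format="wavedecn")
    return _waverec_like(coeffs, name, z)


def _waverec_like(coeffs, name, z):
    out = pywt.waverecn(coeffs, name, mode="periodization")
    # periodization keeps shapes exact for even sizes; guard odd-size padding
    sl = tuple(slice(0, n) for n in z.shape)
    return np.asarray(out)[sl]


def _grad(u):
    """Forward differences along each axis, Neumann boundary (last diff 0)."""
    g = np.zeros((u.ndim,) + u.shape, dtype=u.dtype)
    for a in range(u.ndim):
        sl_lo = [slice(None)] * u.ndim
        sl_hi = [slice(None)] * u.ndim
        sl_lo[a] = slice(0, -1)
        sl_hi[a] = slice(1, None)
        g[a][tuple(sl_lo)] = u[tuple(sl_hi)] - u[tuple(sl_lo)]
    return g


def _div(p):
    """Discrete divergence, the negative adjoint of :func:`_grad`:
    <grad u, p> = -<u, div p>.  The dual component on the last slice of each
    axis is ignored, matching the Neumann boundary of the gradient."""
    ndim = p.shape[0]
    out = np.zeros(p.shape[1:], dtype=p.dtype)
    for a in range(ndim):
        sl_last = [slice(None)] * ndim
        sl_last[a] = slice(-1, None)
        pa = p[a].copy()
        pa[tuple(sl_last)] = 0
        sl_lo = [slice(None)] * ndim
        sl_hi = [slice(None)] * ndim
        sl_lo[a] = slice(0, -1)
        sl_hi[a] = slice(1, None)
        d = np.zeros_like(pa)
        d[tuple(sl_hi)] = pa[tuple(sl_lo)]
        out += pa - d
    return out


def total_variation(u: np.ndarray) -> float:
    """Isotropic TV: sum over voxels of the Euclidean norm of the forward gradient."""
    g = _grad(np.asarray(u))
    return float(np.sum(np.sqrt(np.sum(np.abs(g) ** 2, axis=0))))


@numba.njit(cache=True)
def _tv_inner_3d(z, p0, p1, p2, w, tw, iters):  # pragma: no cover - jitted
    n0, n1, n2 = z.shape
    for _ in range(iters):
        u = np.empty_like(z)
        for i in range(n0):
            for j in range(n1):
                for k in range(n2):
                    d = p0[i, j, k] + p1[i, j, k] + p2[i, j, k]
                    if i > 0:
                        d -= p0[i - 1, j, k]
                    if j > 0:
                        d -= p1[i, j - 1, k]
                    if k > 0:
                        d -= p2[i, j, k - 1]
                    u[i, j, k] = z[i, j, k] + w * d
        for i in range(n0):
            for j in range(n1):
                for k in range(n2):
                    g0 = u[i + 1, j, k] - u[i, j, k] if i < n0 - 1 else 0.0 * u[i, j, k]
                    g1 = u[i, j + 1, k] - u[i, j, k] if j < n1 - 1 else 0.0 * u[i, j, k]
                    g2 = u[i, j, k + 1] - u[i, j, k] if k < n2 - 1 else 0.0 * u[i, j, k]
                    q0 = p0[i, j, k] + tw * g0
                    q1 = p1[i, j, k] + tw * g1
                    q2 = p2[i, j, k] + tw * g2
                    nq = np.sqrt(
                        q0.real * q0.real + q0.imag * q0.imag
                        + q1.real * q1.real + q1.imag * q1.imag
                        + q2.real * q2.real + q2.imag * q2.imag
                    )
                    if nq > 1.0:
                        inv = 1.0 / nq
                        q0 *= inv
                        q1 *= inv
                        q2 *= inv
                    p0[i, j, k] = q0
                    p1[i, j, k] = q1
                    p2[i, j, k] = q2
    out = np.empty_like(z)
    for i in range(n0):
        for j in range(n1):
            for k in range(n2):
                d = p0[i, j, k] + p1[i, j, k] + p2[i, j, k]
                if i > 0:
                    d -= p0[i - 1, j, k]
                if j > 0:
                    d -= p1[i, j - 1, k]
                if k > 0:
                    d -= p2[i, j, k - 1]
                out[i, j, k] = z[i, j, k] + w * d
    return out


def tv_prox(z: np.ndarray, weight: float, step: float = 1.0, inner_iters: int = 10) -> np.ndarray:
    """Approximate prox of weight*step*TV via projected gradient on the dual.

    Solves argmin_u 1/2||u - z||^2 + w TV(u) with w = weight*step using the
    Chambolle-type dual iteration: u = z + w div(p) is recovered from the
    dual field p, which is updated by a gradient step of fixed size
    1/(4*ndim*w) followed by pointwise projection onto the isotropic unit
    ball.  Deterministic; runs exactly ``inner_iters`` iterations.
    """
    if weight < 0:
        raise InvalidArgumentError("weight must be >= 0")
    if inner_iters < 1:
        raise InvalidArgumentError("inner_iters must be >= 1")
    z = np.asarray(z)
    w = weight * step
    if w == 0:
        return z.copy()
    nd = z.ndim
    dtype = z.dtype if z.dtype.kind in "cf" else np.float64
    if nd == 3:
        zc = np.ascontiguousarray(z, dtype=dtype)
        p0 = np.zeros_like(zc)
        p1 = np.zeros_like(zc)
        p2 = np.zeros_like(zc)
        return _tv_inner_3d(zc, p0, p1, p2, dtype.type(w), 1.0 / 12.0, inner_iters)
    p = np.zeros((nd,) + z.shape, dtype=dtype)
    g = np.empty_like(p)
    # dual gradient step tau = 1/(4*nd*w); the update uses tau*w = 1/(4*nd)
    tw = 1.0 / (4.0 * nd)
    slices = []
    for a in range(nd):
        lo = [slice(None)] * nd
        hi = [slice(None)] * nd
        lo[a] = slice(0, -1)
        hi[a] = slice(1, None)
        slices.append((tuple(lo), tuple(hi)))
    for _ in range(inner_iters):
        u = z + w * _div(p)
        # q = p + (1/(4 nd)) * grad(u), built in place in g
        g.fill(0)
        for a, (lo, hi) in enumerate(slices):
            np.subtract(u[hi], u[lo], out=g[a][lo])
        g *= tw
        g += p
        if np.iscomplexobj(g):
            nq = np.sqrt(np.sum(g.real**2 + g.imag**2, axis=0))
        else:
            nq = np.sqrt(np.sum(g**2, axis=0))
        np.maximum(nq, 1.0, out=nq)
        np.divide(g, nq[None], out=g)
        p, g = g, p
    return z + w * _div(p)


# ---------------------------------------------------------------------------
# objective and solver
# ---------------------------------------------------------------------------


def objective(x: np.ndarray | Volume, prob: ReconProblem) -> float:
    """Value of 1/2||y - Ax||^2 + alpha ||Psi x||_1 + beta TV(x)."""
    x = x.data if isinstance(x, Volume) else np.asarray(x)
    pr = prob.params
    sens = _sens(prob)
    r = prob.y.data - forward_op(x, sens, prob.mask.mask)
    val = 0.5 * float(np.vdot(r, r).real)
    if pr.alpha > 0:
        val += pr.alpha * wavelet_l1(x, pr.wavelet_name, pr.wavelet_levels)
    if pr.beta > 0:
        val += pr.beta * total_variation(x)
    return val


def fcsa_reconstruct(prob: ReconProblem) -> ReconResult:
    """FISTA-accelerated composite splitting reconstruction.

    From the zero-filled adjoint x0 = A* y, each outer iteration takes a
    gradient step on the data term at the momentum point, solves the TV and
    wavelet subproblems on the result, averages the two solutions and
    applies the FISTA momentum update.  The objective is recorded at x0 and
    after every outer iteration.
    """
    pr = prob.params
    sens = _sens(prob)
    mask2d = prob.mask.mask
    y = prob.y.data
    step = pr.step_size

    x = adjoint_op(y, sens, mask2d)
    trace = [objective(x, prob)]
    xm = x
    t = 1.0
    for it in range(1, pr.n_iter + 1):
        g = xm - step * adjoint_op(forward_op(xm, sens, mask2d) - y, sens, mask2d)
        x1 = tv_prox(g, pr.beta, step, pr.tv_inner_iters)
        x2 = wavelet_prox(g, pr.alpha, step, pr.wavelet_name, pr.wavelet_levels)
        x_new = 0.5 * (x1 + x2)
        if not np.all(np.isfinite(x_new)):
            raise NumericError(f"non-finite image at outer iteration {it}")
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        xm = x_new + ((t - 1.0) / t_new) * (x_new - x)
        x, t = x_new, t_new
        trace.append(objective(x, prob))
    return ReconResult(image=Volume(x), objective_trace=trace, params=pr)


def reconstruct_per_coil(y: KSpace, mask: SamplingMask, params: ReconParams) -> ReconResult:
    """Alternate path when sensitivities are unknown: reconstruct each coil
    image independently (unit coil) and combine by sum of squares.

    The objective trace is the sum over coils.
    """
    traces = []
    imgs = []
    for c in range(y.n_coils):
        sub = ReconProblem(KSpace(y.data[c : c + 1]), mask, None, params)
        res = fcsa_reconstruct(sub)
        imgs.append(res.image.data)
        traces.append(res.objective_trace)
    combined = np.sqrt(np.sum(np.abs(np.stack(imgs)) ** 2, axis=0))
    trace = [float(s) for s in np.sum(traces, axis=0)]
    return ReconResult(image=Volume(combined), objective_trace=trace, params=params)


def coil_compress(kspace: KSpace, n_virtual: int) -> KSpace:
    """SVD coil compression: keep the top n_virtual virtual coils.

    The (coil x sample) data matrix is factored; the left singular vectors
    define virtual coils ordered by energy.  The preserved energy fraction
    is logged.
    """
    n_coils = kspace.n_coils
    if not (1 <= n_virtual <= n_coils):
        raise InvalidArgumentError(
            f"n_virtual must be in [1, {n_coils}], got {n_virtual}"
        )
    mat = kspace.data.reshape(n_coils, -1)
    u, s, _ = np.linalg.svd(mat, full_matrices=False)
    energy = float(np.sum(s[:n_virtual] ** 2) / np.sum(s**2))
    log.info("coil compression %d -> %d keeps %.6f of energy", n_coils, n_virtual, energy)
    virt = (u[:, :n_virtual].conj().T @ mat).reshape((n_virtual,) + kspace.volume_shape)
    return KSpace(virt)


def with_params(prob: ReconProblem, **kwargs) -> ReconProblem:
    """Copy of the problem with updated solver parameters."""
    return ReconProblem(prob.y, prob.mask, prob.coils, replace(prob.params, **kwargs))
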
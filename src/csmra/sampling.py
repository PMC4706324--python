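"""Variable-density Poisson-disk undersampling of the phase-encode plane.

The k-space mask lives on the two phase-encode dimensions and is broadcast
along the (fully sampled, continuous) readout direction.  Sampling is by dart
throwing with a location-dependent exclusion radius

    r(d) = r0 * (1 + s * d**p)

where d is the distance from the k-space center normalized to [0, 1].  The
default profile (p = 2, s = 3) makes the exclusion radius at the k-space edge
4x the center radius, i.e. dense sampling of low frequencies and sparse,
incoherent sampling of high frequencies.  A candidate point is rejected if it
lies closer to an already-accepted point than the exclusion radius evaluated
at the midpoint of the pair.  The global scale r0 is calibrated by bisection
until the achieved sampling fraction is within 0.005 of the target.  The DC
point is always sampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationError, InvalidArgumentError
from .phantom import KSpace

#: absolute tolerance on the achieved sampling fraction after calibration
RATE_TOL = 0.005
#: maximum bisection iterations on the radius scale
MAX_BISECT = 40

DEFAULT_PROFILE = {"power": 2.0, "edge_factor": 4.0}


@dataclass
class SamplingMask:
    """A binary phase-encode sampling pattern plus its generation record."""

    mask: np.ndarray  # bool, (n_phase1, n_phase2)
    target_rate: float
    achieved_rate: float
    density_profile: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise InvalidArgumentError("sampling mask must be 2D")

    @property
    def shape(self):
        return self.mask.shape

    @property
    def acceleration(self) -> float:
        return 1.0 / self.achieved_rate


def _grid_geometry(shape):
    n1, n2 = shape
    ci, cj = n1 // 2, n2 // 2  # DC location under the centered-FFT convention
    ii = np.arange(n1)[:, None] - ci
    jj = np.arange(n2)[None, :] - cj
    dmax = np.sqrt(max(ci, n1 - 1 - ci) ** 2 + max(cj, n2 - 1 - cj) ** 2)
    dist = np.hypot(ii, jj) / dmax
    return (ci, cj), dmax, dist


def _throw_darts(shape, r0, s, p, seed, calib_radius):
    """One deterministic dart-throwing pass at radius scale r0."""
    n1, n2 = shape
    (ci, cj), dmax, dist = _grid_geometry(shape)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n1 * n2)
    accepted = np.zeros((n1, n2), dtype=bool)
    accepted[ci, cj] = True  # DC always sampled
    if calib_radius > 0:
        accepted |= (dist * dmax) <= calib_radius
    rmax = r0 * (1.0 + s)
    w = int(np.ceil(rmax))
    inv_dmax = 1.0 / dmax
    for idx in order:
        i, j = divmod(int(idx), n2)
        if accepted[i, j]:
            continue
        i0, i1 = max(0, i - w), min(n1, i + w + 1)
        j0, j1 = max(0, j - w), min(n2, j + w + 1)
        sub = accepted[i0:i1, j0:j1]
        if sub.any():
            qi, qj = np.nonzero(sub)
            qi = qi + i0
            qj = qj + j0
            dd = np.hypot(qi - i, qj - j)
            dmid = np.hypot((qi + i) * 0.5 - ci, (qj + j) * 0.5 - cj) * inv_dmax
            rmid = r0 * (1.0 + s * dmid**p)
            if np.any(dd < rmid):
                continue
        accepted[i, j] = True
    return accepted


def poisson_disk_mask(
    shape,
    target_rate: float,
    profile=None,
    calib_center: bool = False,
    seed: int = 0,
) -> SamplingMask:
    """Build a variable-density Poisson-disk mask calibrated to a sampling rate.

    Parameters
    ----------
    shape
        (n_phase1, n_phase2) grid size.
    target_rate
        Desired fraction of sampled points, in (0, 1].
    profile
        Density profile parameters: ``power`` (exponent p) and
        ``edge_factor`` (exclusion radius at the edge relative to the
        center).  Defaults: p = 2, edge_factor = 4.
    calib_center
        If True, a small fully sampled disc (radius 5% of the grid
        diagonal) is placed at the k-space center.
    seed
        Seed for the candidate order; the same seed gives a bit-identical
        mask.

    Raises
    ------
    CalibrationError
        If bisection on the radius scale cannot reach the target rate
        within 0.005 in at most 40 iterations; the error reports the
        bracketing rates.
    """
    shape = tuple(int(n) for n in shape)
    if not (0.0 < target_rate <= 1.0):
        raise InvalidArgumentError(f"target_rate must be in (0, 1], got {target_rate}")
    prof = dict(DEFAULT_PROFILE)
    if profile:
        prof.update(profile)
    p = float(prof["power"])
    s = float(prof["edge_factor"]) - 1.0
    _, dmax, _ = _grid_geometry(shape)
    calib_radius = 0.05 * dmax if calib_center else 0.0

    if target_rate == 1.0:
        mask = np.ones(shape, dtype=bool)
        prof["r0"] = 0.0
        return SamplingMask(mask, 1.0, 1.0, density_profile=prof, seed=seed)

    def rate_at(r0):
        m = _throw_darts(shape, r0, s, p, seed, calib_radius)
        return m, m.mean()

    lo, hi = 0.25, float(max(shape))
    _, rate_lo = rate_at(lo)  # small radius -> high rate
    mask_hi, rate_hi = rate_at(hi)
    if not (rate_hi <= target_rate <= rate_lo):
        raise CalibrationError(
            f"target rate {target_rate} outside achievable range "
            f"[{rate_hi:.4f}, {rate_lo:.4f}]",
            rate_lo=rate_lo,
            rate_hi=rate_hi,
        )
    best = None
    for _ in range(MAX_BISECT):
        mid = 0.5 * (lo + hi)
        mask, rate = rate_at(mid)
        if abs(rate - target_rate) <= RATE_TOL:
            best = (mask, rate, mid)
            break
        if rate > target_rate:
            lo = mid
        else:
            hi = mid
    if best is None:
        raise CalibrationError(
            f"calibration did not reach rate {target_rate} +/- {RATE_TOL} in "
            f"{MAX_BISECT} iterations (bracket rates {rate_lo:.4f}, {rate_hi:.4f})",
            rate_lo=rate_lo,
            rate_hi=rate_hi,
        )
    mask, rate, r0 = best
    prof["r0"] = float(r0)
    if calib_center:
        prof["calib_radius"] = float(calib_radius)
    return SamplingMask(mask, float(target_rate), float(rate), density_profile=prof, seed=seed)


def min_distance_violations(smask: SamplingMask) -> int:
    """Exhaustive pair scan: count sampled pairs closer than the midpoint radius.

    A correct Poisson-disk mask has zero violations (pairs inside an optional
    fully sampled calibration disc are exempt by construction and excluded).
    """
    prof = smask.density_profile
    r0 = float(prof.get("r0", 0.0))
    if r0 == 0.0:
        return 0
    p = float(prof.get("power", 2.0))
    s = float(prof.get("edge_factor", 4.0)) - 1.0
    calib_radius = float(prof.get("calib_radius", 0.0))
    (ci, cj), dmax, _ = _grid_geometry(smask.shape)
    pi, pj = np.nonzero(smask.mask)
    pts = np.stack([pi, pj], axis=1).astype(float)
    in_calib = np.hypot(pi - ci, pj - cj) <= calib_radius
    n = len(pts)
    violations = 0
    chunk = 512
    for a in range(0, n, chunk):
        sl = slice(a, min(a + chunk, n))
        diff = pts[sl, None, :] - pts[None, :, :]
        dd = np.hypot(diff[..., 0], diff[..., 1])
        mid = 0.5 * (pts[sl, None, :] + pts[None, :, :])
        dmid = np.hypot(mid[..., 0] - ci, mid[..., 1] - cj) / dmax
        rmid = r0 * (1.0 + s * dmid**p)
        bad = dd < rmid
        # ignore self-pairs and pairs fully inside the calibration disc
        rows = np.arange(sl.start, sl.stop)
        bad[np.arange(sl.stop - sl.start), rows] = False
        if calib_radius > 0:
            bad &= ~(in_calib[sl, None] & in_calib[None, :])
        violations += int(bad.sum())
    return violations // 2  # each unordered pair counted twice


def apply_mask(kspace: KSpace, smask: SamplingMask) -> KSpace:
    """Zero out unsampled phase-encode locations (broadcast along readout)."""
    if smask.shape != kspace.data.shape[2:]:
        raise InvalidArgumentError(
            f"mask shape {smask.shape} does not match k-space phase-encode "
            f"dims {kspace.data.shape[2:]}"
        )
    return KSpace(kspace.data * smask.mask[None, None, :, :])
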
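"""SIFT keypoints and forced-location descriptors.

Standard Lowe pipeline: a Gaussian scale-space pyramid, difference-of-Gaussian
(DoG) extrema detection with contrast and edge-response rejection, dominant
gradient orientation per keypoint, and 4x4x8 = 128-bin gradient-histogram
descriptors.

The variant implemented here for image comparison does NOT match descriptors
by nearest-neighbor search.  Keypoints are detected on the *reference* image
only; descriptors are then computed on both the reference and the test image
at exactly the same (position, scale, orientation) tuples, and the mean
Euclidean distance over these forced pairs is the dissimilarity score
(smaller = more similar).  Because descriptors are built from gradients, the
score is exactly invariant to a constant intensity offset and exactly zero
for identical images.

Images are expected on a roughly [0, 1] intensity scale (the detection
thresholds assume it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import NoKeypointsError

# detection defaults (common published values)
N_SCALES = 3          # sampled scales per octave
SIGMA0 = 1.6          # base blur of the first pyramid level
ASSUMED_BLUR = 0.5    # blur assumed present in the input image
CONTRAST_THRESH = 0.03
EDGE_RATIO = 10.0
DESCRIPTOR_WIDTH = 4  # 4x4 spatial cells
DESCRIPTOR_BINS = 8   # orientation bins per cell
DESCRIPTOR_CLIP = 0.2


@dataclass
class KeypointSet:
    """Keypoint locations (x=col, y=row, scale sigma, orientation rad) + descriptors."""

    locations: list  # of (x, y, scale, orientation)
    descriptors: np.ndarray  # (n, 128)
    source: str = "reference"

    def __post_init__(self):
        self.descriptors = np.asarray(self.descriptors, dtype=float)
        if len(self.locations) != len(self.descriptors):
            raise ValueError("locations and descriptors must have equal length")

    def __len__(self):
        return len(self.locations)


@dataclass
class _Keypoint:
    octave: int
    level: int
    row: int  # coordinates within the octave
    col: int
    orientation: float = 0.0

    @property
    def sigma_octave(self) -> float:
        return SIGMA0 * 2.0 ** (self.level / N_SCALES)

    @property
    def sigma(self) -> float:
        return self.sigma_octave * 2.0**self.octave


def _n_octaves(shape) -> int:
    return max(1, int(np.floor(np.log2(min(shape)))) - 3)


def build_pyramid(img: np.ndarray, n_octaves: int | None = None):
    """Gaussian pyramid: per octave, N_SCALES + 3 images at blurs sigma0*2^(i/N)."""
    img = np.asarray(img, dtype=float)
    if n_octaves is None:
        n_octaves = _n_octaves(img.shape)
    k = 2.0 ** (1.0 / N_SCALES)
    base = gaussian_filter(img, np.sqrt(max(SIGMA0**2 - ASSUMED_BLUR**2, 0.01)))
    pyramid = []
    current = base
    for _ in range(n_octaves):
        octave = [current]
        sigma_prev = SIGMA0
        for _i in range(N_SCALES + 2):
            sigma_next = sigma_prev * k
            inc = np.sqrt(sigma_next**2 - sigma_prev**2)
            octave.append(gaussian_filter(octave[-1], inc))
            sigma_prev = sigma_next
        pyramid.append(octave)
        current = octave[N_SCALES][::2, ::2]
        if min(current.shape) < 16:
            break
    return pyramid


def _dog(octave):
    return [b - a for a, b in zip(octave[:-1], octave[1:])]


def _is_extremum(dogs, i, r, c, thresh):
    v = dogs[i][r, c]
    if abs(v) <= thresh:
        return False
    patch = np.stack([d[r - 1 : r + 2, c - 1 : c + 2] for d in dogs[i - 1 : i + 2]])
    if v > 0:
        return v >= patch.max() and np.sum(patch == v) == 1
    return v <= patch.min() and np.sum(patch == v) == 1


def _passes_edge_test(d, r, c):
    dxx = d[r, c + 1] + d[r, c - 1] - 2.0 * d[r, c]
    dyy = d[r + 1, c] + d[r - 1, c] - 2.0 * d[r, c]
    dxy = 0.25 * (d[r + 1, c + 1] - d[r + 1, c - 1] - d[r - 1, c + 1] + d[r - 1, c - 1])
    tr = dxx + dyy
    det = dxx * dyy - dxy * dxy
    if det <= 0:
        return False
    return tr * tr / det < (EDGE_RATIO + 1.0) ** 2 / EDGE_RATIO


def _gradients(img):
    gy = np.zeros_like(img)
    gx = np.zeros_like(img)
    gy[1:-1, :] = 0.5 * (img[2:, :] - img[:-2, :])
    gx[:, 1:-1] = 0.5 * (img[:, 2:] - img[:, :-2])
    mag = np.hypot(gx, gy)
    ang = np.arctan2(gy, gx)
    return mag, ang


def _dominant_orientation(gauss, r, c, sigma_oct):
    radius = int(round(3.0 * 1.5 * sigma_oct))
    n_bins = 36
    hist = np.zeros(n_bins)
    h, w = gauss.shape
    r0, r1 = max(1, r - radius), min(h - 1, r + radius + 1)
    c0, c1 = max(1, c - radius), min(w - 1, c + radius + 1)
    sub = gauss[r0 - 1 : r1 + 1, c0 - 1 : c1 + 1]
    mag, ang = _gradients(sub)
    mag = mag[1:-1, 1:-1]
    ang = ang[1:-1, 1:-1]
    rr = np.arange(r0, r1)[:, None] - r
    cc = np.arange(c0, c1)[None, :] - c
    weight = np.exp(-(rr**2 + cc**2) / (2.0 * (1.5 * sigma_oct) ** 2))
    bins = np.floor((ang + np.pi) / (2 * np.pi) * n_bins).astype(int) % n_bins
    np.add.at(hist, bins.ravel(), (weight * mag).ravel())
    # circular smoothing
    for _ in range(2):
        hist = (np.roll(hist, 1) + hist + np.roll(hist, -1)) / 3.0
    b = int(np.argmax(hist))
    # parabolic interpolation of the peak
    l, rgt = hist[(b - 1) % n_bins], hist[(b + 1) % n_bins]
    denom = l - 2.0 * hist[b] + rgt
    off = 0.0 if denom == 0 else 0.5 * (l - rgt) / denom
    return (b + 0.5 + off) / n_bins * 2 * np.pi - np.pi


def detect_keypoints(img: np.ndarray, contrast_thresh: float = CONTRAST_THRESH,
                     max_keypoints: int | None = 500):
    """DoG-extrema keypoints with dominant orientations (reference image only).

    Returns a list of internal keypoint records ordered by detection position,
    optionally truncated to the ``max_keypoints`` strongest DoG responses.
    """
    pyramid = build_pyramid(img)
    found = []
    for o, octave in enumerate(pyramid):
        dogs = _dog(octave)
        for i in range(1, len(dogs) - 1):
            d = dogs[i]
            h, w = d.shape
            strong = np.abs(d[1 : h - 1, 1 : w - 1]) > contrast_thresh
            for r, c in zip(*np.nonzero(strong)):
                r += 1
                c += 1
                if not _is_extremum(dogs, i, r, c, contrast_thresh):
                    continue
                if not _passes_edge_test(d, r, c):
                    continue
                kp = _Keypoint(octave=o, level=i, row=r, col=c)
                kp.orientation = _dominant_orientation(
                    octave[i], r, c, kp.sigma_octave
                )
                found.append((abs(d[r, c]), kp))
    found.sort(key=lambda t: (-t[0], t[1].octave, t[1].level, t[1].row, t[1].col))
    if max_keypoints is not None:
        found = found[:max_keypoints]
    return [kp for _, kp in found]


def _descriptor(gauss, kp: _Keypoint) -> np.ndarray:
    """128-d gradient-histogram descriptor at a fixed (pos, scale, orientation)."""
    d = DESCRIPTOR_WIDTH
    nb = DESCRIPTOR_BINS
    hist = np.zeros((d + 2, d + 2, nb))
    cos_t, sin_t = np.cos(kp.orientation), np.sin(kp.orientation)
    hist_width = 3.0 * kp.sigma_octave
    radius = int(round(hist_width * np.sqrt(2) * (d + 1) * 0.5))
    h, w = gauss.shape
    r0, r1 = max(1, kp.row - radius), min(h - 1, kp.row + radius + 1)
    c0, c1 = max(1, kp.col - radius), min(w - 1, kp.col + radius + 1)
    if r0 >= r1 or c0 >= c1:
        return np.zeros(d * d * nb)
    sub = gauss[r0 - 1 : r1 + 1, c0 - 1 : c1 + 1]
    mag, ang = _gradients(sub)
    mag = mag[1:-1, 1:-1]
    ang = ang[1:-1, 1:-1]
    rr = (np.arange(r0, r1)[:, None] - kp.row) * np.ones((1, c1 - c0))
    cc = np.ones((r1 - r0, 1)) * (np.arange(c0, c1)[None, :] - kp.col)
    # rotate into the keypoint frame
    rot_c = (cc * cos_t + rr * sin_t) / hist_width
    rot_r = (-cc * sin_t + rr * cos_t) / hist_width
    rbin = rot_r + d / 2.0 - 0.5
    cbin = rot_c + d / 2.0 - 0.5
    inside = (rbin > -1) & (rbin < d) & (cbin > -1) & (cbin < d)
    if not np.any(inside):
        return np.zeros(d * d * nb)
    rbin = rbin[inside]
    cbin = cbin[inside]
    m = mag[inside]
    theta = (ang[inside] - kp.orientation) % (2 * np.pi)
    obin = theta / (2 * np.pi) * nb
    weight = np.exp(-(rot_r[inside] ** 2 + rot_c[inside] ** 2) / (0.5 * d * d))
    m = m * weight
    # trilinear interpolation into (row, col, orientation) bins
    r_f = np.floor(rbin).astype(int)
    c_f = np.floor(cbin).astype(int)
    o_f = np.floor(obin).astype(int)
    dr = rbin - r_f
    dc = cbin - c_f
    do = obin - o_f
    for ir in (0, 1):
        wr = m * (dr if ir else 1 - dr)
        for ic in (0, 1):
            wc = wr * (dc if ic else 1 - dc)
            for io in (0, 1):
                wo = wc * (do if io else 1 - do)
                np.add.at(
                    hist,
                    (r_f + ir + 1, c_f + ic + 1, (o_f + io) % nb),
                    wo,
                )
    vec = hist[1 : d + 1, 1 : d + 1, :].ravel()
    norm = np.linalg.norm(vec)
    if norm > 0:
        vec = np.minimum(vec / norm, DESCRIPTOR_CLIP)
        norm = np.linalg.norm(vec)
        if norm > 0:
            vec = vec / norm
    return vec


def compute_descriptors(img: np.ndarray, keypoints) -> np.ndarray:
    """Descriptors for ``img`` at the given (forced) keypoints.

    The image's own Gaussian pyramid is built with the same structure as the
    detection pyramid, and each descriptor is evaluated at the keypoint's
    exact octave, level, position and orientation — no re-detection.
    """
    pyramid = build_pyramid(img)
    out = np.zeros((len(keypoints), DESCRIPTOR_WIDTH**2 * DESCRIPTOR_BINS))
    for n, kp in enumerate(keypoints):
        if kp.octave >= len(pyramid):
            continue
        out[n] = _descriptor(pyramid[kp.octave][kp.level], kp)
    return out


def keypoint_tuples(keypoints):
    """(x, y, scale, orientation) in full-image coordinates."""
    return [
        (kp.col * 2.0**kp.octave, kp.row * 2.0**kp.octave, kp.sigma, kp.orientation)
        for kp in keypoints
    ]


def sift_forced_distance(ref: np.ndarray, rec: np.ndarray):
    """Mean Euclidean distance between forced-correspondence descriptors.

    Keypoints are detected on ``ref`` only; descriptors are computed on both
    images at those identical locations/scales/orientations.  Smaller is
    more similar; identical images give exactly 0.

    Returns ``(distance, KeypointSet)`` where the keypoint set carries the
    reference descriptors.
    """
    ref = np.asarray(ref, dtype=float)
    rec = np.asarray(rec, dtype=float)
    if ref.shape != rec.shape:
        raise ValueError("images must have the same shape")
    kps = detect_keypoints(ref)
    if not kps:
        raise NoKeypointsError(
            "no DoG keypoints on the reference image; relax contrast_thresh"
        )
    d_ref = compute_descriptors(ref, kps)
    d_rec = compute_descriptors(rec, kps)
    dist = float(np.mean(np.linalg.norm(d_ref - d_rec, axis=1)))
    kpset = KeypointSet(keypoint_tuples(kps), d_ref, source="reference")
    return dist, kpset
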
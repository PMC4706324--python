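"""Synthetic TOF-MRA phantom: bright tubular arteries on dimmer parenchyma.

The phantom stands in for a volunteer time-of-flight angiography scan. It is a
magnitude volume containing an ellipsoidal "brain" envelope filled at the
parenchyma intensity, with a configurable number of smooth random-walk vessel
tubes painted at the (brighter) artery intensity. Ground-truth brain /
arterial / parenchymal masks are derived from the noiseless geometry, so every
downstream metric has an exact region definition. Acquisition noise is
complex Gaussian added before magnitude-taking, which gives the Rician
magnitude statistics of real MR magnitude images.

Axis convention: axis 0 is the readout (antero-posterior) direction; axes 1
and 2 are the two phase-encode directions (transverse, craniocaudal).
Undersampling masks live on axes 1-2 and are broadcast along axis 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft as spfft

from .errors import InvalidArgumentError

#: mapping from axis labels to array axes
AXIS_LABELS = {
    "readout": 0,
    "anteroposterior": 0,
    "phase1": 1,
    "transverse": 1,
    "phase2": 2,
    "craniocaudal": 2,
}

DEFAULT_INTENSITIES = {"artery": 1.0, "parenchyma": 0.3, "background": 0.0}


@dataclass
class Volume:
    """A 3D image volume.

    ``data`` is real (magnitude) or complex; magnitude volumes are
    elementwise non-negative.  ``voxel_size`` is metadata in mm.
    """

    data: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise InvalidArgumentError(f"Volume must be 3D, got {self.data.ndim}D")
        if min(self.data.shape) < 8:
            raise InvalidArgumentError(
                f"Volume shape components must be >= 8, got {self.data.shape}"
            )
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def shape(self):
        return self.data.shape

    def magnitude(self) -> np.ndarray:
        return np.abs(self.data)


@dataclass
class MaskSet:
    """Boolean brain / arterial / parenchymal volumes.

    Invariants: arterial is a subset of brain, and parenchymal is exactly
    brain AND NOT arterial.
    """

    brain: np.ndarray
    arterial: np.ndarray
    parenchymal: np.ndarray

    def __post_init__(self):
        self.brain = np.asarray(self.brain, dtype=bool)
        self.arterial = np.asarray(self.arterial, dtype=bool)
        self.parenchymal = np.asarray(self.parenchymal, dtype=bool)
        if not (self.brain.shape == self.arterial.shape == self.parenchymal.shape):
            raise InvalidArgumentError("mask shapes differ")
        if np.any(self.arterial & ~self.brain):
            raise InvalidArgumentError("arterial mask must be a subset of brain mask")
        if np.any(self.parenchymal != (self.brain & ~self.arterial)):
            raise InvalidArgumentError("parenchymal mask must equal brain AND NOT arterial")
        if not self.arterial.any() or not self.parenchymal.any():
            raise InvalidArgumentError("arterial and parenchymal masks must be non-empty")


@dataclass
class CoilSet:
    """Smooth complex receive-sensitivity maps, RSS-normalized to 1."""

    sensitivities: np.ndarray  # (n_coils, n0, n1, n2) complex
    n_coils: int = field(init=False)

    def __post_init__(self):
        self.sensitivities = np.asarray(self.sensitivities)
        if not np.iscomplexobj(self.sensitivities):
            self.sensitivities = self.sensitivities.astype(complex)
        if self.sensitivities.ndim != 4 or self.sensitivities.shape[0] < 1:
            raise InvalidArgumentError("sensitivities must be (n_coils >= 1, n0, n1, n2)")
        if not np.all(np.isfinite(self.sensitivities)):
            raise InvalidArgumentError("sensitivities must be finite")
        self.n_coils = self.sensitivities.shape[0]


@dataclass
class KSpace:
    """Multi-coil complex spectrum on the same grid as the Volume.

    The transform convention is the unitary centered FFT (DC at the grid
    center); index order is (coil, readout, phase1, phase2).
    """

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise InvalidArgumentError("k-space must be (n_coils, n0, n1, n2)")

    @property
    def n_coils(self):
        return self.data.shape[0]

    @property
    def volume_shape(self):
        return self.data.shape[1:]


# ---------------------------------------------------------------------------
# centered unitary FFTs
# ---------------------------------------------------------------------------

_AXES3 = (-3, -2, -1)


def fftc(x: np.ndarray, axes=_AXES3) -> np.ndarray:
    """Centered unitary FFT (DC at grid center)."""
    return spfft.fftshift(
        spfft.fftn(spfft.ifftshift(x, axes=axes), axes=axes, norm="ortho"), axes=axes
    )


def ifftc(k: np.ndarray, axes=_AXES3) -> np.ndarray:
    """Inverse of :func:`fftc`."""
    return spfft.fftshift(
        spfft.ifftn(spfft.ifftshift(k, axes=axes), axes=axes, norm="ortho"), axes=axes
    )


# ---------------------------------------------------------------------------
# phantom generation
# ---------------------------------------------------------------------------


def _brain_envelope(shape) -> np.ndarray:
    """Ellipsoidal brain mask occupying most of the field of view."""
    center = [(n - 1) / 2.0 for n in shape]
    semi = [0.42 * n for n in shape]
    gi, gj, gk = np.ogrid[: shape[0], : shape[1], : shape[2]]
    q = (
        ((gi - center[0]) / semi[0]) ** 2
        + ((gj - center[1]) / semi[1]) ** 2
        + ((gk - center[2]) / semi[2]) ** 2
    )
    return q <= 1.0


def _inside_envelope(p, shape, frac) -> bool:
    center = np.array([(n - 1) / 2.0 for n in shape])
    semi = np.array([0.42 * n for n in shape])
    return float(np.sum(((p - center) / (frac * semi)) ** 2)) <= 1.0


def _stamp_tube(mask, points, radii_vox):
    """Paint ellipsoidal balls of (possibly anisotropic) voxel radius along a path."""
    shape = mask.shape
    for p, rv in zip(points, radii_vox):
        lo = [max(0, int(np.floor(p[a] - rv[a]))) for a in range(3)]
        hi = [min(shape[a], int(np.ceil(p[a] + rv[a])) + 1) for a in range(3)]
        if any(l >= h for l, h in zip(lo, hi)):
            continue
        gi, gj, gk = np.ogrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        q = (
            ((gi - p[0]) / rv[0]) ** 2
            + ((gj - p[1]) / rv[1]) ** 2
            + ((gk - p[2]) / rv[2]) ** 2
        )
        mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] |= q <= 1.0


def _trace_vessel(rng, shape, r_start_mm, r_end_mm, voxel_size):
    """Smooth 3D random walk inside the brain envelope, radius tapering to the tip."""
    center = np.array([(n - 1) / 2.0 for n in shape])
    semi = np.array([0.42 * n for n in shape])
    # start well inside the envelope
    for _ in range(100):
        p = center + rng.uniform(-0.5, 0.5, size=3) * semi
        if _inside_envelope(p, shape, 0.7):
            break
    d = rng.standard_normal(3)
    d /= np.linalg.norm(d)
    step = 0.6  # voxels; dense enough for gap-free sphere stamping
    max_steps = int(4 * max(shape))
    pts = [p.copy()]
    for _ in range(max_steps):
        d = d + 0.3 * rng.standard_normal(3)
        d /= np.linalg.norm(d)
        p = p + step * d
        if not _inside_envelope(p, shape, 0.95):
            break
        pts.append(p.copy())
    pts = np.array(pts)
    radii_mm = np.linspace(r_start_mm, r_end_mm, len(pts))
    vs = np.asarray(voxel_size, dtype=float)
    radii_vox = radii_mm[:, None] / vs[None, :]
    return pts, radii_vox


def generate_phantom(
    shape=(96, 96, 48),
    n_vessels: int = 6,
    vessel_radius_range=(1.0, 3.0),
    intensity_levels=None,
    noise_sd: float = 0.02,
    voxel_size=(1.0, 1.0, 1.0),
    seed: int = 0,
):
    """Generate a TOF-MRA-like magnitude volume and its ground-truth masks.

    Parameters
    ----------
    shape
        Volume shape (readout, phase1, phase2); each component >= 16.
    n_vessels
        Number of vessel tubes (>= 1).
    vessel_radius_range
        (min, max) vessel radius in mm.  Each vessel tapers from a starting
        radius drawn near the maximum down toward the minimum at its tip,
        giving both large trunks and small peripheral branches.
    intensity_levels
        Dict with keys ``artery``, ``parenchyma``, ``background``; must
        satisfy artery > parenchyma > background >= 0.
    noise_sd
        SD of the complex Gaussian noise added in quadrature before the
        magnitude is taken (Rician magnitude noise).
    seed
        Seed for all randomness; equal seeds give bit-identical output.

    Returns
    -------
    (Volume, MaskSet)
        The noisy magnitude volume and masks derived from the noiseless
        geometry.
    """
    if intensity_levels is None:
        intensity_levels = dict(DEFAULT_INTENSITIES)
    art = float(intensity_levels["artery"])
    par = float(intensity_levels["parenchyma"])
    bg = float(intensity_levels["background"])
    if not (art > par > bg >= 0):
        raise InvalidArgumentError(
            f"intensity ordering artery > parenchyma > background >= 0 violated: "
            f"{art}, {par}, {bg}"
        )
    shape = tuple(int(n) for n in shape)
    if len(shape) != 3 or min(shape) < 16:
        raise InvalidArgumentError(f"shape must be 3 ints each >= 16, got {shape}")
    if n_vessels < 1:
        raise InvalidArgumentError("n_vessels must be >= 1")
    r_min, r_max = (float(r) for r in vessel_radius_range)
    if r_min > r_max:
        raise InvalidArgumentError("vessel_radius_range must be (min, max)")
    if r_min < max(voxel_size):
        raise InvalidArgumentError(
            f"minimum vessel radius {r_min} mm is below one voxel "
            f"({max(voxel_size)} mm) and cannot be resolved"
        )

    rng = np.random.default_rng(seed)
    brain = _brain_envelope(shape)
    arterial = np.zeros(shape, dtype=bool)
    for _ in range(n_vessels):
        r_start = rng.uniform(0.7 * r_max + 0.3 * r_min, r_max)
        pts, radii_vox = _trace_vessel(rng, shape, r_start, r_min, voxel_size)
        _stamp_tube(arterial, pts, radii_vox)
    arterial &= brain
    if not arterial.any():  # pragma: no cover - geometry makes this unreachable
        raise RuntimeError("vessel tracing produced an empty arterial mask")
    parenchymal = brain & ~arterial

    vol = np.full(shape, bg, dtype=float)
    vol[brain] = par
    vol[arterial] = art
    if noise_sd > 0:
        noise = noise_sd * (
            rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        )
        vol = np.abs(vol + noise)
    masks = MaskSet(brain=brain, arterial=arterial, parenchymal=parenchymal)
    return Volume(vol, voxel_size=voxel_size), masks


def simulate_coils(shape, n_coils: int = 4, seed: int = 0) -> CoilSet:
    """Smooth complex coil maps with root-sum-of-squares exactly 1 everywhere.

    Coil centers sit on an ellipse surrounding the volume in the phase-encode
    plane (like elements of a head coil array); magnitudes are broad Gaussian
    profiles and phases are gentle linear ramps.  Normalizing by the
    pointwise RSS makes the sum-of-squares combination of noiseless,
    fully sampled data reproduce the source volume exactly.
    """
    if n_coils < 1:
        raise InvalidArgumentError("n_coils must be >= 1")
    shape = tuple(int(n) for n in shape)
    rng = np.random.default_rng(seed)
    gi, gj, gk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    center = [(n - 1) / 2.0 for n in shape]
    width = 0.8 * max(shape)
    maps = np.empty((n_coils,) + shape, dtype=complex)
    for c in range(n_coils):
        theta = 2.0 * np.pi * c / n_coils + rng.uniform(-0.2, 0.2)
        cj = center[1] + 0.65 * shape[1] * np.cos(theta)
        ck = center[2] + 0.65 * shape[2] * np.sin(theta)
        ci = center[0] + rng.uniform(-0.2, 0.2) * shape[0]
        d2 = (gi - ci) ** 2 + (gj - cj) ** 2 + (gk - ck) ** 2
        mag = np.exp(-d2 / (2.0 * width**2))
        if c == 0:
            phase = np.zeros(shape)
        else:
            coeff = rng.uniform(-0.5, 0.5, size=3)
            phase = 2.0 * np.pi * (
                coeff[0] * gi / shape[0] + coeff[1] * gj / shape[1] + coeff[2] * gk / shape[2]
            )
        maps[c] = mag * np.exp(1j * phase)
    rss = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    maps /= rss[None]
    return CoilSet(sensitivities=maps)


def forward_kspace(vol: Volume, coils: CoilSet) -> KSpace:
    """Fully sampled multi-coil k-space: centered unitary FFT of coil-weighted images."""
    data = vol.data if isinstance(vol, Volume) else np.asarray(vol)
    if coils.sensitivities.shape[1:] != data.shape:
        raise InvalidArgumentError(
            f"coil maps {coils.sensitivities.shape[1:]} do not match volume {data.shape}"
        )
    return KSpace(fftc(coils.sensitivities * data[None]))


def sos_image(kspace: KSpace) -> Volume:
    """Sum-of-squares coil combination (the reference-standard image)."""
    imgs = ifftc(kspace.data)
    return Volume(np.sqrt(np.sum(np.abs(imgs) ** 2, axis=0)))
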
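"""Reading and writing volumes, masks, coil maps, k-space and sampling masks.

Volumes and mask sets go to NIfTI-1 (via nibabel; the affine encodes the
voxel size).  Complex arrays (k-space, coil sensitivities) use NumPy ``.npz``
containers with a documented index order of (coil, readout, phase1, phase2).
Sampling masks round-trip through ``.npz`` and can additionally be exported
as 0/255 PNG images.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image

from .phantom import CoilSet, KSpace, MaskSet, Volume
from .sampling import SamplingMask


def _affine(voxel_size):
    return np.diag(list(voxel_size) + [1.0])


def save_volume(vol: Volume, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), _affine(vol.voxel_size)), str(path))


def load_volume(path) -> Volume:
    img = nib.load(str(path))
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(np.asarray(img.get_fdata(), dtype=float), voxel_size=voxel_size)


def save_maskset(masks: MaskSet, path) -> None:
    """Masks stacked along a 4th axis in the order brain, arterial, parenchymal."""
    stack = np.stack([masks.brain, masks.arterial, masks.parenchymal], axis=-1)
    nib.save(nib.Nifti1Image(stack.astype(np.uint8), np.eye(4)), str(path))


def load_maskset(path) -> MaskSet:
    arr = np.asarray(nib.load(str(path)).dataobj).astype(bool)
    return MaskSet(brain=arr[..., 0], arterial=arr[..., 1], parenchymal=arr[..., 2])


def save_kspace(kspace: KSpace, path) -> None:
    np.savez_compressed(str(path), data=kspace.data, index_order="coil,readout,phase1,phase2")


def load_kspace(path) -> KSpace:
    with np.load(str(path)) as z:
        return KSpace(z["data"])


def save_coils(coils: CoilSet, path) -> None:
    np.savez_compressed(
        str(path), sensitivities=coils.sensitivities, index_order="coil,readout,phase1,phase2"
    )


def load_coils(path) -> CoilSet:
    with np.load(str(path)) as z:
        return CoilSet(z["sensitivities"])


def save_mask(smask: SamplingMask, path) -> None:
    prof = smask.density_profile
    np.savez_compressed(
        str(path),
        mask=smask.mask,
        target_rate=smask.target_rate,
        achieved_rate=smask.achieved_rate,
        seed=smask.seed,
        profile_keys=np.array(sorted(prof), dtype=object),
        profile_vals=np.array([prof[k] for k in sorted(prof)], dtype=float),
    )


def load_mask(path) -> SamplingMask:
    with np.load(str(path), allow_pickle=True) as z:
        prof = dict(zip([str(k) for k in z["profile_keys"]], [float(v) for v in z["profile_vals"]]))
        return SamplingMask(
            mask=z["mask"],
            target_rate=float(z["target_rate"]),
            achieved_rate=float(z["achieved_rate"]),
            density_profile=prof,
            seed=int(z["seed"]),
        )


def save_mask_png(smask: SamplingMask, path) -> None:
    Image.fromarray((smask.mask.astype(np.uint8)) * 255, mode="L").save(str(path))


def save_mip_png(img: np.ndarray, path) -> None:
    """16-bit grayscale PNG of a MIP, scaled to the full range."""
    data = np.asarray(img, dtype=float)
    top = data.max()
    scaled = np.zeros_like(data) if top == 0 else data / top
    Image.fromarray((scaled * 65535).astype(np.uint16)).save(str(path))


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
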
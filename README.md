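# csmra

Compressed-sensing reconstruction of time-of-flight MR angiography (TOF-MRA)
and selection of the regularization weights by statistical image metrics
restricted to clinically relevant regions.

## The problem

CS reconstruction of undersampled k-space solves

```
min_x  1/2 ||y - A x||_2^2 + alpha ||Psi(x)||_1 + beta ||TV(x)||_1
```

where `y` is the measured (undersampled) multi-coil k-space, `A` the
undersampled Fourier encoding operator (coil multiply, centered unitary FFT,
sampling mask), `Psi` an orthonormal wavelet transform and `TV` isotropic
total variation. Image quality depends strongly on the weights
`(alpha, beta)`, and common full-image error metrics (NMSE, PSNR) are
dominated by structures nobody cares about in an angiogram. This package
implements the alternative: score every `(alpha, beta)` cell of a weight
grid with *mask-restricted* metrics — SSIM and a forced-keypoint SIFT
distance on brain-masked maximum intensity projections (MIPs), and the
artery-to-parenchyma contrast-to-noise ratio

```
CNR = (S_artery - S_parenchyma) / SD_parenchyma
```

with the noise SD taken from the (reference − reconstruction) difference
over parenchyma — and rank the cells. A synthetic vascular phantom with
ground-truth brain/arterial/parenchymal masks replaces the volunteer scan,
so the whole pipeline runs from nothing but a seed.

The solver is FCSA: each FISTA-accelerated iteration takes a gradient step
on the data term, solves a wavelet soft-threshold subproblem and a TV
(Chambolle dual) subproblem on the result, and averages the two. The
forced-keypoint SIFT metric detects difference-of-Gaussian keypoints on the
*reference* MIP only and evaluates 128-bin descriptors on both images at
identical (position, scale, orientation) tuples; the mean Euclidean
distance over these forced pairs is the dissimilarity score.

## Worked example

```python
import numpy as np, csmra

# phantom + undersampled problem (96x96x48, 2 coils, 21% Poisson-disk mask)
prob, ref, masks = csmra.phantom_problem(seed=1)
from csmra.recon import with_params
res = csmra.fcsa_reconstruct(with_params(prob, alpha=3.2e-5, beta=3.2e-5))
print(csmra.evaluate_all(ref, np.abs(res.image.data), masks))
```

prints (seed 1):

```
{'nmse': 0.0149, 'psnr_db': 27.28, 'ssim': 0.8936,
 'nmse_masked': 0.0132, 'psnr_masked': 27.87, 'ssim_masked': 0.9312,
 'sift_dist_masked': 0.1143, 'cnr': 14.50, 'slice_nmse_mean': 0.1023}
```

i.e. at this mid-grid weight pair the reconstruction retains 93% masked
structural similarity to the fully sampled sum-of-squares reference and an
artery-to-parenchyma CNR of 14.5 at 4.7x acceleration.

The numbered drivers under `analysis/` run the full study at desk scale:

1. `01_build_phantom.py` — phantom, masks, coil maps, k-space, SoS reference
2. `02_sampling_mask.py` — 256x110 and 96x48 Poisson-disk masks calibrated
   to 21% (achieved 20.96% / 21.20%, zero exclusion-radius violations)
3. `03_single_reconstruction.py` — the reconstruction above, with its
   objective trace
4. `04_weight_sweep.py` — the 5x5 weight sweep with color maps and top-10
   tables; at seed 1 the masked-SSIM optimum (alpha=3.2e-5, beta=3.2e-7)
   also ranks in the CNR top 10, and the heaviest cell (3.2e-3, 3.2e-3)
   ranks last

A `csmra` CLI mirrors the library (`csmra phantom | mask | recon | metrics |
sweep`); see `csmra --help`.

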
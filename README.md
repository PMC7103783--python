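# fetalrecon

Outlier-robust super-resolution reconstruction of fetal brain MRI from
motion-corrupted stacks of thick 2D slices.

Fetal MRI is acquired as fast 2D single-shot stacks: in-plane detail is
good, but fetal motion between slice acquisitions scrambles the 3D geometry,
and individual slices are corrupted by blur, ghosting and signal dropout.
This package reconstructs a single isotropic high-resolution volume `x`
from several such stacks by modelling each slice as

    y_k = A_k x + e_k

(`A_k`: rigid slice pose + oriented-Gaussian point-spread-function blur +
down-sampling) and solving the robust least-squares problem

    x = argmin_{x >= 0}  sum_{k in K_beta} 1/2 ||y_k - A_k x||^2
                         + alpha/2 ||grad x||^2

where the inlier set `K_beta = {k : NCC(y_k, A_k x_prev) >= beta}` rejects
misregistered or artifact-corrupted slices *completely*, with a single
threshold `beta` (schedule 0.5 / 0.65 / 0.8 over three motion-correction
cycles, alpha = 0.01). Around this core the package provides: rigid
slice-to-volume motion correction, Nadaraya-Watson scattered-data
initialization, brain-volume-matched template selection with
principal-brain-axes (PBA) initialized template-space alignment, the
multi-scale Dice loss and bounding-box localization machinery for
segmentation-driven masking, and a synthetic phantom simulator with full
ground truth (slice poses, outlier labels, intensity distortions).

It is a library first (`import fetalrecon`; see `examples/`), with a thin
`fetalrecon` CLI (`simulate`, `reconstruct`, `align-template`, `evaluate`,
`run`) for shell use. Everything is pure Python on numpy/scipy/nibabel/
scikit-image.

## Worked example

```python
from fetalrecon import outlier_robustness_experiment
out = outlier_robustness_experiment(seed=1)
print(out["outlier_recall"], out["masked_psnr_db"],
      out["masked_psnr_best_stack_db"], out["masked_psnr_no_rejection_db"])
```

This simulates three orthogonal 1.5 x 1.5 x 3.0 mm stacks of a 64^3
textured phantom with per-slice rigid motion (up to 5 deg / 3 mm) and 10%
artifact-corrupted slices, runs the full three-cycle motion-correction +
robust-reconstruction pipeline, and scores it against the known phantom.
With seed 1 it prints

```
1.0 19.48164...  12.65141...  12.86732...
```

meaning: every corrupted slice below the final similarity threshold was
rejected (recall 1.0); the reconstruction reaches 19.5 dB masked PSNR
against the phantom, beating the best single input stack (12.7 dB); and
re-solving with rejection disabled drops quality to 12.9 dB — the corrupted
slices would otherwise contaminate the least-squares fit. (Exact figures
vary slightly with environment BLAS; rerun the snippet for your machine.)

`examples/` contains one short script per capability: simulation, the
forward model + SDA gridding, robust reconstruction, template alignment,
and the multi-scale loss / localization utilities. Each prints the numbers
it computes with a line on what they mean.

## Documentation

`docs/methods.md` describes the models, parameter defaults and units, the
numerical design choices (PSF discretization, registration engine, solver
settings), what the synthetic phantom does and does not emulate, and known
limitations.
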
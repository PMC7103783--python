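"""The slice acquisition model and scattered data approximation.

Forward-projects one slice through the oriented-Gaussian point spread
function (the model y_k = A_k x + e_k), verifies the adjoint identity that
the reconstruction solver relies on, and grids all slices back to a volume
with Nadaraya-Watson kernel regression (the pipeline's initialization).
"""

import numpy as np

from fetalrecon import PhantomSpec, make_phantom, make_psf, \
    forward_project, adjoint_project, sda_reconstruct, masked_psnr, resample
from fetalrecon.geometry import ImageGrid3D, MaskVolume, Volume3D
from fetalrecon.simulate import ArtifactSpec, MotionSpec, simulate_acquisition
from fetalrecon.srr import _slice_geometry

phantom, mask = make_phantom(PhantomSpec(seed=1))
stacks, _ = simulate_acquisition(
    phantom, mask,
    motion=MotionSpec(max_rotation=0, max_translation=0, walk_step_rotation=0,
                      walk_step_translation=0, jump_rotation=0,
                      jump_translation=0),
    artifacts=ArtifactSpec(outlier_fraction=0.0), noise_sd=0.0,
    intensity_scales=[(1, 0)] * 3, seed=1)

psf = make_psf(stacks[0].in_plane_spacing, stacks[0].thickness)
s = stacks[0].slices[len(stacks[0].slices) // 2]
geom = _slice_geometry(s)
y = forward_project(phantom, geom, psf)
print(f"forward projection of one slice: {y.shape} pixels, "
      f"max |simulated - acquired| = {np.abs(y - s.pixels).max():.2e} "
      "(zero: the simulator uses this same acquisition model)")

rng = np.random.default_rng(0)
yr = rng.random(geom.shape)
Ax_y = float((y * yr).sum())
x_Aty = float((phantom.values
               * adjoint_project(yr, geom, psf, phantom.grid).values).sum())
print(f"adjoint identity <Ax, y> vs <x, A^T y>: "
      f"|difference| = {abs(Ax_y - x_Aty):.2e}")

grid = ImageGrid3D((80, 80, 80), (1.2,) * 3, phantom.grid.origin)
slices = [s for st in stacks for s in st.slices]
init = sda_reconstruct(slices, grid, sigma=1.0)
mk = MaskVolume((resample(Volume3D(mask.values, mask.grid), grid)
                 .values > 0.5).astype(float), grid)
print(f"SDA initialization vs phantom: masked PSNR = "
      f"{masked_psnr(init, resample(phantom, grid), mk):.1f} dB "
      "(blurred but well-posed starting point for the SRR solve)")
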
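"""Feature-based deformable registration on segmented images: recover a
known smooth deformation between two tissue maps and compare against the
ground truth (possible because the phantom's field is known)."""

import numpy as np

from infatlas import (
    PhantomConfig,
    SpaceDef,
    deformable_register,
    dice,
    generate_cohort,
    generate_smooth_field,
    invert,
    warp,
)

grid = SpaceDef((48, 48, 48), (1.5, 1.5, 1.5), (24, 24, 24))
cfg = PhantomConfig(n_subjects=1, grid=grid, seed=3, noise_sigma=0.0,
                    bias_amplitude=0.0)
fixed = generate_cohort(cfg)[0].tissues[2]
f_true = generate_smooth_field(grid, 3.0, 8.0, seed=11)
moving = warp(fixed, f_true)  # fixed anatomy pulled through a known warp

truth = fixed.hard().data
before = [dice(moving.hard().data, truth, k) for k in (1, 2, 3)]
phi = deformable_register(moving, fixed)
after = [dice(warp(moving, phi).hard().data, truth, k) for k in (1, 2, 3)]

finv = invert(f_true)
mask = fixed.mask
resid0 = np.linalg.norm(finv.disp / 1.5, axis=-1)[mask].mean()
resid1 = np.linalg.norm((phi.disp - finv.disp) / 1.5, axis=-1)[mask].mean()

print("per-class Dice before registration:", [round(d, 3) for d in before])
print("per-class Dice after registration: ", [round(d, 3) for d in after])
print(f"mean displacement error: {resid0:.2f} -> {resid1:.2f} voxels")
# The driving-voxel/TPS scheme composes correspondence-driven updates and
# only accepts updates that do not lower the tissue overlap, so Dice is
# monotone over accepted steps and the residual error drops below the
# unregistered baseline.
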
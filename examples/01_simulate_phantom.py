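"""Build the digital thorax phantom and its degraded synthetic CBCT.

The phantom is a soft-tissue trunk with two lungs, a spine, ribs, and a
breast protrusion at known HU. The degradation multiplies the attenuation
by a smooth cupping field, shades the unscanned sector of a 200-degree
arc, shifts each tissue class, adds voxel noise, and truncates the field
of view to a 100 mm cylinder — the artifacts the correction targets.
"""

import numpy as np

from cbctprior import DegradationSpec, PhantomSpec, degrade_to_cbct, generate_phantom_ct

ct, masks = generate_phantom_ct(PhantomSpec(seed=0))
print(f"phantom grid: {ct.grid.shape} at {ct.grid.spacing} mm")
for name in ("air", "lung", "soft", "bone"):
    m = masks.class_mask(name)
    print(f"  {name:5s}: {m.sum():7d} voxels, mean {ct.voxels[m].mean():8.1f} HU")

deg = degrade_to_cbct(ct, masks, DegradationSpec(seed=1))
body_fov = masks.body & deg.fov
mae = np.abs(deg.cbct.voxels - ct.voxels)[body_fov].mean()
print(f"\nFOV covers {deg.fov.mean():.0%} of the grid "
      f"({(masks.body & ~deg.fov).sum()} body voxels truncated)")
print(f"degradation severity: MAE(CBCT, CT) = {mae:.1f} HU over body-in-FOV")
print(f"bias field range: {deg.bias_field.voxels[body_fov].min():.3f} "
      f"to {deg.bias_field.voxels[body_fov].max():.3f} (multiplicative, mu scale)")
# The MAE is the image error the correction must remove; the bias range
# shows the cupping deficit (~0.79 at the core) the ratio fields estimate.
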
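"""Recover the rigid CBCT-to-CT alignment with mutual information.

The standard fixture observes the degraded CBCT in a frame offset by
(3, -2, 1) mm and 2 degrees about the axial axis; registration must find
that offset despite the HU bias between the two images.
"""

import numpy as np

from cbctprior import RegistrationSettings, register_rigid, standard_fixture

fx = standard_fixture(0)
transform, metric = register_rigid(fx.ct, fx.cbct, RegistrationSettings(seed=0))

print("recovered rotation (deg):", np.round(transform.rotation_deg, 3))
print("true      rotation (deg):", fx.truth_transform.rotation_deg)
c = np.asarray(fx.truth_transform.center_mm)
eff_translation = transform.apply(c) - c
print("recovered translation at the phantom center (mm):",
      np.round(eff_translation, 2))
print("true      translation (mm):", fx.truth_transform.translation_mm)
print(f"final mutual-information metric: {metric:.4f} (lower is better)")
# Sub-voxel agreement (errors well under the 2.5 mm spacing and 0.1 deg)
# is what makes the per-class ratio estimation downstream reliable.
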
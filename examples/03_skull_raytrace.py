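"""Measure target-to-skull distances along 16 rays and compare two CTs.

Skull stability is the prerequisite for reusing an old planning CT: if
the inner-table distances from each target agree to a sub-voxel level
between the scans, skull-based localization off the old CT is sound.
"""

import numpy as np

import srsrescan as sr

spec = sr.example_spec(seed=0)
ict, _ = sr.make_head_phantom(spec)
target = spec.targets[0]

profile = sr.skull_profile(ict, target)
print(f"target {target.target_id} at {target.centroid} mm")
print("  transverse distances (mm):", np.round(profile.distances[:8], 1))
print("  oblique +45deg  (mm)     :", np.round(profile.distances[8:], 1))

# the same head, rigidly moved and re-registered (known inverse here)
T = sr.RigidTransform.from_params([2.0, -1.0, 1.0, 0.8, -0.5, 0.7], center=tuple(ict.center))
rct = sr.simulate_rescan(ict, T, noise_sigma=3.0, local_hu_offset=20.0, seed=3,
                         targets=spec.targets)
registered_back = sr.transform_volume(rct, sr.invert(T), ict.grid)
cmp_ = sr.profile_difference(
    sr.skull_profile(ict, target), sr.skull_profile(registered_back, target)
)
print(f"\nafter a rigid rescan round trip:")
print(f"  mean |d_iCT - d_rCT| = {cmp_.mean_abs_diff:.2f} mm over "
      f"{cmp_.n_valid_rays} rays (max {cmp_.max_abs_diff:.2f} mm)")
print(f"  voxel diagonal for this grid: {sr.max_voxel_path(ict.spacing):.2f} mm")
print("Sub-voxel mean differences indicate an effectively unchanged skull.")
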
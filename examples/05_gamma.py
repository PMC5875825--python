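"""3D gamma comparison of SRS dose distributions at 1 mm / 1% criteria.

The surrogate plan delivers 20 Gy across the PTV with a steep Gaussian
penumbra.  Gamma folds dose difference (as % of the global max) and
distance-to-agreement into one pass/fail score per point; only points
above 10% of the maximum dose count.
"""

import numpy as np

import srsrescan as sr

target = sr.Target((0.0, 0.0, 0.0), 5.0, target_id="t")
dose = sr.make_srs_dose(target, sr.DoseSpec(spacing=(1.0, 1.0, 1.0)))
cov = sr.coverage(dose, target.ptv_radius, target.centroid, 20.0)
print(f"plan: 20 Gy prescription, PTV coverage {cov:.1%} (objective: > 98%)")

fine = sr.resample_dose_fine(dose, 0.2)
print(f"fine grid: {fine.shape} at 0.2 mm")

crit = sr.GammaCriteria()  # 1 mm DTA, 1% of global max, 10% threshold
self_res = sr.gamma_map(fine, fine, crit)
print(f"\nself-comparison : passing rate {self_res.passing_rate:.3f} "
      f"over {self_res.n_evaluated} points (gamma = 0 everywhere)")

shifted = sr.VolumeImage(np.roll(fine.voxels, 2, axis=0), fine.spacing, fine.origin, "DOSE")
shift_res = sr.gamma_map(fine, shifted, crit)
print(f"0.4 mm shift    : passing rate {shift_res.passing_rate:.3f}, "
      f"max gamma {np.nanmax(shift_res.gamma):.2f} (pure DTA, within 1 mm)")

off = sr.VolumeImage(fine.voxels * 1.02, fine.spacing, fine.origin, "DOSE")
off_res = sr.gamma_map(fine, off, crit)
print(f"+2% dose error  : passing rate {off_res.passing_rate:.3f} "
      "(plateau points fail: dose term alone is 2)")
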
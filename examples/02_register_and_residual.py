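"""Recover a simulated patient motion by rigid registration, then close
the three-registration loop and report the residual displacement.

The residual chain is the core targeting-accuracy statistic: register the
repeat MR to the repeat CT directly (a), to the initial CT via bone (b),
and the initial CT to the repeat CT (c).  If every registration were
perfect the loop would close exactly; what remains is the uncertainty of
placing MR-defined targets on the old CT.
"""

import numpy as np

import srsrescan as sr

spec = sr.example_spec(seed=0)
ict, _ = sr.make_head_phantom(spec)
T_true = sr.RigidTransform.from_params([2.0, -3.0, 1.5, 1.2, -0.8, 0.6],
                                       center=tuple(ict.center))
rct = sr.simulate_rescan(ict, T_true, noise_sigma=3.0, local_hu_offset=20.0,
                         seed=1, targets=spec.targets)
rmr = sr.derive_mr(rct, seed=2)

print("registering rCT -> iCT (all anatomy) ...")
res_c = sr.register_rigid(rct, ict, mode="all_anatomy")
err = res_c.transform.params - sr.invert(T_true).params
print(f"  true inverse : {np.round(sr.invert(T_true).params, 3)}")
print(f"  recovered    : {np.round(res_c.transform.params, 3)}")
print(f"  error        : {np.round(err, 3)}  (mm / deg; sub-0.1 expected)")

print("registering rMR -> rCT (all anatomy) and rMR -> iCT (bone) ...")
res_a = sr.register_rigid(rmr, rct, mode="all_anatomy")
res_b = sr.register_rigid(rmr, ict, mode="bone")
center = tuple(rct.center)
residual = sr.residual_chain(
    sr.recenter(res_a.transform, center),
    sr.recenter(res_b.transform, center),
    sr.recenter(sr.invert(res_c.transform), center),  # iCT -> rCT direction
)
print(f"\nresidual displacement of the rMR routed through the iCT:")
print(f"  |t| = {residual.magnitude:.2f} mm, "
      f"t = ({residual.tx:+.2f}, {residual.ty:+.2f}, {residual.tz:+.2f}) mm, "
      f"rot = ({residual.roll:+.2f}, {residual.pitch:+.2f}, {residual.yaw:+.2f}) deg")
print("A consistent chain stays in the sub-millimetre range that makes the"
      " old CT usable for target localization.")
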
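"""Score scan similarity with NMI and Pearson across comparison groups.

The normalized mutual information equals 1 only for identical image sets
and decreases as scans share less information; the group ordering
(same scan > rescan of the same head > different head) is the
transportable statement — absolute MI values depend on the implementation.
"""

import srsrescan as sr

spec = sr.example_spec(seed=0)
ct, _ = sr.make_head_phantom(spec)
rescan = sr.simulate_rescan(ct, sr.RigidTransform.translation(1.0, -0.5, 0.5),
                            noise_sigma=3.0, local_hu_offset=20.0, seed=4,
                            targets=spec.targets)
other, _ = sr.make_head_phantom(sr.PhantomSpec(
    skull_outer_radii=(55.0, 66.0, 50.0), spacing=ct.spacing, shape=ct.shape,
    noise_sigma=3.0, seed=99,
))

rows = [
    ("same scan (identical copy)", ct),
    ("rescan of the same head", rescan),
    ("a different head", other),
]
print(f"{'comparison':32s} {'NMI':>6s} {'PC':>7s}  context band")
for label, img in rows:
    rep = sr.similarity_report(ct, img, n_bins=64)
    print(f"{label:32s} {rep.mi:6.3f} {rep.pc:7.3f}  {sr.similarity_context(rep)}")
print("\nNMI = 1 and PC = 1 only for the identical set; the monotone drop"
      " across groups mirrors how scan similarity is triaged clinically.")
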
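"""Threshold-robustness of group ordering.

The pipeline's fixed 8-bit threshold (default 30) should not drive the
biology: the ordering of group-mean skeleton length must be the same at
thresholds 10, 30, and 58.  This sweep checks that on a
control / fkrp-like / NAD-treated-fkrp-like phantom triplet.
"""

import zftrunk as z

stacks, regions, groups = {}, {}, {}
for preset, seed in [("control", 1), ("fkrp_like", 2), ("nad_fkrp_like", 3)]:
    ph = z.generate_trunk_phantom(z.preset_params(preset, seed=seed))
    stacks[preset] = ph.stack()
    regions[preset] = ph.masks
    groups[preset] = preset

sweep = z.threshold_sweep(stacks, regions, groups, thresholds=(10, 30, 58))
print(sweep.to_string(index=False))

orders = {
    thr: tuple(sub.sort_values("mean_skeleton_length_px", ascending=False).group)
    for thr, sub in sweep.groupby("threshold")
}
same = len(set(orders.values())) == 1
print(f"\ngroup ordering identical at all thresholds: {same}")
print("ordering:", " > ".join(orders[30]))
# A stable ordering means the measured group differences reflect the laid-down
# innervation, not the choice of threshold.
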
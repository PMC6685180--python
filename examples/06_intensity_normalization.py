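"""Percent mean-gray reporter intensity, normalized within batch.

Each ROI's mean gray value is expressed as a percent of the mean of the
control ROIs acquired in the same batch (intensities are only comparable
under consistent exposure), so the control group averages 100% by
construction.
"""

import numpy as np

import zftrunk as z

rng = np.random.default_rng(1)
sq = [(4, 4), (4, 27), (27, 27), (27, 4)]
images, rois = {}, []
for i in range(5):
    images[f"c{i}"] = rng.normal(70, 8, (32, 32)).clip(0, 255).astype(np.uint8)
    rois.append(z.IntensityROI(f"c{i}", z.PolygonROI(f"c{i}", sq), "control"))
for i in range(5):
    images[f"t{i}"] = rng.normal(105, 8, (32, 32)).clip(0, 255).astype(np.uint8)
    rois.append(z.IntensityROI(f"t{i}", z.PolygonROI(f"t{i}", sq), "stressed"))

df = z.percent_mean_intensity(rois, images, control_group="control")
print(df.to_string(index=False))
print(f"\ncontrol mean percent: {df[df.group == 'control'].percent_intensity.mean():.1f}%")
print(f"stressed mean percent: {df[df.group == 'stressed'].percent_intensity.mean():.1f}%")
# Values above 100% indicate elevated reporter signal relative to the
# batch's controls, e.g. increased stress-pathway activity.
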
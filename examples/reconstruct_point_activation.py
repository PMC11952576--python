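"""Reconstruct a cortical point activation through both arrays.

A 1 uM HbO point source on a lateral brain vertex is projected through
each array's sensitivity matrix and inverted with the spatially
regularized Tikhonov reconstruction (alpha_spatial = alpha_meas = 0.001).
Localization error is the distance from the reconstructed center of mass
(on the point-spread function's half-maximum support) to the seed;
resolution is the intensity-weighted spread. Overlapping multi-distance
channels let the HD array pin the source down more tightly.
"""

import optarray as oa
from optarray.localization import localization_study

probes, mesh, sens = oa.build_arrays(oa.PipelineConfig())
df = localization_study(sens, mesh, n_seeds=20, seed=1)

summary = df.groupby("array")[["localization_error_mm",
                               "resolution_mm"]].mean()
print("mean over 20 lateral point activations:")
print(summary.round(2))
adv = (summary.loc["sparse", "localization_error_mm"]
       - summary.loc["hd", "localization_error_mm"])
print(f"\nHD localization advantage: {adv:.2f} mm "
      "(positive = HD reconstructs closer to the true source)")
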
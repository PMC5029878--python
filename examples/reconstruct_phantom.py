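"""Simulate a forearm acquisition and recover the fat-fraction map.

Builds a single-slice synthetic forearm whose true CSA-weighted
compartment fat fraction is 14.1% (a typical non-ambulant patient
baseline), simulates the three Dixon echoes at magnitude SNR 50 with a
smooth polynomial field-phase map, reconstructs water/fat/f.f. and
summarizes the muscle compartment.  The printed recovered values should
sit within a few hundredths of a percentage point of the truth.
"""

import numpy as np

from musclefat import (
    FatFractionMap,
    LabelMask,
    PhantomSpec,
    build_forearm_phantom,
    compartment_summary,
    noise_sd_for_snr,
    reconstruct,
    scale_ff_to_target,
    simulate_echoes,
)
from musclefat.labels import LABEL_NAMES

spec = scale_ff_to_target(PhantomSpec(n_slices=1), target_total_ff=14.1)
water, fat, mask = build_forearm_phantom(spec)
echoes = simulate_echoes(
    water, fat, noise_sd=noise_sd_for_snr(spec.total_signal, snr=50.0), seed=1
)
pair, ff_map, _ = reconstruct(echoes, vote_mask=mask.labels > 0)

summary = compartment_summary(
    FatFractionMap(ff=ff_map.ff[0], mask=ff_map.mask[0], ff_raw=ff_map.ff_raw[0]),
    LabelMask(labels=mask.labels[0], pixel_area=mask.pixel_area),
)

print(f"true total compartment f.f.   : 14.100 %")
print(f"recovered total compartment   : {summary.total_ff:.3f} %")
print(f"dorsal / volar compartment    : {summary.dorsal_ff:.2f} / {summary.volar_ff:.2f} %")
print(f"total compartment CSA         : {summary.total_csa:.1f} mm^2")
print(f"remaining (non-fat) area      : {summary.remaining_area:.1f} mm^2")
print()
print("per-muscle mean f.f. (recovered vs true):")
for label in sorted(summary.per_roi_ff):
    print(
        f"  {LABEL_NAMES[label]:<8} {summary.per_roi_ff[label]:6.2f} %"
        f"   (true {spec.muscle_ff_true[label]:5.2f} %)"
    )
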
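"""Full single-patient pipeline on a digital phantom.

Builds a small 4D phantom with an artery and two tissue regions whose
ground truth is known, then runs the complete pipeline: arrival
detection, baseline, concentration conversion, AIF extraction,
voxelwise 2CU and empirical-model fitting, and ROI summarization with
physiological validity masking.
"""

import numpy as np

import ultradce as u

shape = (12, 12, 2)
artery = np.zeros(shape, bool); artery[0:2, 0:2, :] = True
lesion = np.zeros(shape, bool); lesion[5:8, 5:8, :] = True
normal = np.zeros(shape, bool); normal[9:11, 2:5, :] = True

spec = u.PhantomSpec(
    shape=shape, artery_mask=artery, noise_sd_rel=0.02, seed=11,
    regions=[
        u.Region("lesion", lesion, "2cu", u.TwoCUParams(vp=0.2, ps=0.4, fp=0.4)),
        u.Region("normal", normal, "2cu", u.TwoCUParams(vp=0.1, ps=0.1, fp=0.2)),
    ],
)
series, masks, aif_truth, truth = u.make_phantom(spec)

result = u.run_patient(
    series, masks["artery"],
    [(masks["lesion"], dict(roi_id="L0", roi_type="lesion", zone="PZ",
                            pirads=4, gg="2")),
     (masks["normal"], dict(roi_id="N0", roi_type="normal", zone="PZ",
                            pirads=1, gg="neg"))],
)

print(f"bolus arrival detected at frame {result.arrival_frame} "
      f"({result.arrival_frame * series.dt_seconds:.1f} s)")
print()
print(f"{'ROI':>8} {'param':>12} {'mean':>8} {'sd':>8} {'valid':>6}")
for rec in result.records:
    for name in ("fp", "ps", "vp", "e", "ktrans", "alpha", "ttp"):
        s = rec.summaries[name]
        print(f"{rec.roi_id:>8} {name:>12} {s.mean:>8.3f} {s.sd:>8.3f} "
          f"{s.n_valid:>6}")
print()
print("Lesion truth was Fp=0.4, PS=0.4, vp=0.2; normal tissue Fp=0.2,")
print("PS=0.1, vp=0.1. ROI means are computed over voxels whose fitted")
print("values lie inside the physiologically credible ranges.")
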
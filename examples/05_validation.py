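"""Validate the detector against simulator ground truth.

Runs a short detection-fidelity sweep (a subset of stimulus kinds and
colors for speed) and reports recall, precision and heading agreement on
well-separated larvae, plus the recovered swim speed against the true
mean step speed.
"""

from zebraplate import experiments as ex

overall, per_condition = ex.detection_fidelity_suite(seed=3, frames_per_condition=3)
print(f"overall: recall = {overall.recall:.3f}, precision = {overall.precision:.3f}, "
      f"heading accuracy = {overall.heading_accuracy:.3f}")
for name in ("blank:none", "bar_up_half:red", "dots_moving_up:yellow", "cross_cw:cyan"):
    fid = per_condition[name]
    print(f"  {name:24s} recall = {fid.recall:.3f}, precision = {fid.precision:.3f}")

speed = ex.swim_speed_recovery(seed=3)
print(f"swim speed: measured {speed['measured_mm_min']:.1f} mm/min "
      f"vs true {speed['true_mm_min']:.1f} mm/min")
# recall/precision are computed on larvae more than one body length apart;
# touching larvae may legitimately merge into one particle
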
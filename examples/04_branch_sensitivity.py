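"""Metabolic control analysis of branch-point flux distributions.

Part 1 uses a toy with an analytic answer: a fraction f of the main flux
condenses with an independently supplied co-substrate; under a background
that halves that supply, the intermediate's steady state is
(1 - f)/(0.5 - f), so both the concentration control coefficient and the
stability boundary at f = 0.5 are known exactly.

Part 2 scans hepatic-triglyceride control coefficients on the multi-tissue
network under a high-calorie background (glucose and triglyceride influx
x10), classifying each branch as high/moderate/low impact.
"""

from hepanet.scenarios import (
    COSUBSTRATE_BACKGROUND,
    HIGH_CALORIE_BACKGROUND,
    cosubstrate_y1_prediction,
    make_cosubstrate_toy,
    make_liver_adipose_network,
)
from hepanet.sensitivity import (
    concentration_control_coefficient,
    records_to_frame,
    scan_branches,
    tolerance_range,
)

toy = make_cosubstrate_toy(0.3)
rec = concentration_control_coefficient(
    toy, "X", "RA", target="Y1", delta=0.1,
    background=COSUBSTRATE_BACKGROUND)
y0, y1 = cosubstrate_y1_prediction(0.3), cosubstrate_y1_prediction(0.33)
analytic = (y1 - y0) / 0.03 * (0.3 / y0)
print(f"toy coefficient: {rec.coefficient:.6f}  (analytic {analytic:.6f}) "
      f"-> impact {rec.impact}")

tr = tolerance_range(toy, "X", "RA", background=COSUBSTRATE_BACKGROUND,
                     resolution=0.1, t_end=1e5)
print(f"stable fraction interval: [{tr.f_lo:.1f}, {tr.f_hi:.1f}]; beyond "
      f"{tr.f_hi:.1f} the mode is '{tr.mode_hi}' (co-substrate starvation)")
print()

net = make_liver_adipose_network()
records = scan_branches(
    net, "tg_l", deltas=(0.1,), background=HIGH_CALORIE_BACKGROUND,
    branches=[("fa_l", "R_CPT1"), ("fa_l", "R_SCD"), ("fa_l", "R_CERS"),
              ("fa_b", "R_FAT_L"), ("fa_b", "R_FAT_A"), ("tg_b", "R_LPL")])
print("hepatic TG sensitivity to flux distributions (high-calorie diet):")
print(records_to_frame(records)[
    ["branch", "child", "f", "coefficient", "class", "stable"]
].to_string(index=False))
print()
print("negative coefficients mean routing more flux into that branch lowers")
print("hepatic triglyceride (e.g. more beta-oxidation), positive the reverse.")
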
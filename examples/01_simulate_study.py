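"""Generate a synthetic 33-subject validation study and save it as CSV.

Each subject contributes nine readings (BPA, BPB, BP1..BP7) alternating
reference and test device; the device here has a +2 mm Hg systolic bias
and a few mm Hg of measurement noise.
"""

import dataclasses

from eshval import GeneratorConfig, simulate_to_csv

config = GeneratorConfig(seed=42)
config = dataclasses.replace(
    config, sbp=dataclasses.replace(config.sbp, device_bias=2.0)
)

sessions = simulate_to_csv(config, "study.csv")

first = sessions[0]
print(f"wrote study.csv: {len(sessions)} subjects x {len(first.readings)} readings")
print(f"subject {first.subject.subject_id}: BMI {first.subject.bmi:.1f} kg/m^2")
for r in first.readings[:4]:
    print(f"  {r.label} ({r.role:9s}) SBP {r.sbp:.0f}  DBP {r.dbp:.0f}  HR {r.hr:.0f}")
print("each reference/test pair of rows is one alternating-device comparison slot")
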
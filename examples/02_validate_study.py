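"""Grade a study CSV against the protocol's part 1/2/3 criteria.

Runs favorable-comparison pairing, classifies the 99 absolute differences
into the 5/10/15 mm Hg bands (3/5/8 bpm for heart rate), and prints the
verdict tables. Run 01_simulate_study.py first to produce study.csv.
"""

from eshval import render_tables, validate_csv

report = validate_csv("study.csv", metrics=("sbp", "dbp", "hr"), out_dir="out")

print(render_tables(report))
print(
    "part 1 counts measurements close to the reference; part 2 requires the"
)
print(
    "closeness to hold per subject; part 3 (the verdict) is their conjunction:"
)
print(f"device {'PASSES' if report.all_pass else 'FAILS'} for all metrics")
print("machine-readable report written to out/report.json")
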
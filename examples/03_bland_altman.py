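"""Bland-Altman agreement analysis of the device-reference differences.

For each comparison the signed difference (test minus reference) is plotted
against the pair mean; agreement is summarized by the bias and the 95%
limits of agreement (bias +/- 1.96 SD). The reference value is the same
favorably chosen flank the grading uses.
"""

from eshval import GeneratorConfig, bland_altman, export_bland_altman, generate_study, pair_study

study = generate_study(GeneratorConfig(seed=42))

for metric, unit in (("sbp", "mm Hg"), ("dbp", "mm Hg"), ("hr", "bpm")):
    records = pair_study(study, metric)
    result = bland_altman(records)
    sidecar = export_bland_altman(result, f"ba_{metric}.csv")
    print(
        f"{metric.upper():3s}: bias {result.bias:+.2f} {unit}, "
        f"limits of agreement [{result.loa_low:.2f}, {result.loa_high:.2f}] {unit} "
        f"over {result.n_pairs} pairs"
    )

print()
print("bias near 0 means no systematic device offset; ~95% of differences")
print("fall between the limits. plot data: ba_<metric>.csv + .json sidecar")
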
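"""Monte-Carlo pass probability as a function of device bias.

How much systematic error can a device carry before the protocol starts
failing it? Each replicate generates a fresh 33-subject study and runs the
full part 1/2/3 grading; the estimate is the fraction of passing replicates.
"""

import dataclasses

from eshval import GeneratorConfig, pass_probability

base = GeneratorConfig(seed=7)

print("SBP bias (mm Hg)   P(part-3 pass)   binomial SE   (50 replicates each)")
for bias in (0.0, 3.0, 5.0, 7.0):
    cfg = dataclasses.replace(
        base, sbp=dataclasses.replace(base.sbp, device_bias=bias)
    )
    result = pass_probability(cfg, n_replicates=50, metric="sbp")
    print(f"{bias:16.1f}   {result.estimate:14.2f}   {result.standard_error:11.3f}")

print()
print("the pass probability collapses within a few mm Hg of bias: the banded")
print("criteria tolerate noise around zero far better than systematic offset")
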
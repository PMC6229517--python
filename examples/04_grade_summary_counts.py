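"""Grade a device directly from published-style summary counts.

Validation reports usually print only the achieved band counts and subject
quotas, not raw readings. The grading rules run on those summaries alone:
here a device achieved 71/95/98 of 99 systolic differences within
5/10/15 mm Hg, 27 of 33 subjects with >=2 of 3 within 5 mm Hg and none
with 0 of 3.
"""

from eshval import (
    ESH_IP2_PART1,
    ESH_IP2_PART2,
    BandCounts,
    grade_part1,
    grade_part3,
)
from eshval.validation import SubjectBandProfile, grade_part2

counts = BandCounts(n_total=99, n_within1=71, n_within2=95, n_within3=98)
part1 = grade_part1(counts, ESH_IP2_PART1)
print(f"part 1 achieved {counts.achieved}: {'pass' if part1 else 'fail'}")
print("  (71 < 73 misses one 'two of' minimum, but 95>=87 and 98>=96 carry it,")
print("   and all three clear the 65/81/93 floors)")

# 27 subjects with 2 of 3 close, 6 with exactly 1, none with 0
profiles = [SubjectBandProfile(f"S{i:02d}", 2 if i < 27 else 1) for i in range(33)]
part2 = grade_part2(profiles, ESH_IP2_PART2)
print(
    f"part 2 achieved ({part2.n_two_of_three}, {part2.n_zero_of_three}): "
    f"{'pass' if part2.passed else 'fail'}  (needs >=24 and <=3)"
)

part3 = grade_part3(part1, part2.passed)
print(f"part 3 verdict: {'pass' if part3 else 'fail'}  (conjunction of parts 1 and 2)")
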
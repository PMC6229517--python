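# Methods

## Protocol model

A validation study is 33 complete nine-reading sessions. Reading roles are
a pure function of the protocol label: BPA, BP1, BP3, BP5, BP7 are
reference-device slots; BPB, BP2, BP4, BP6 are test-device slots. BPA and
BPB are entry/device-detection readings: they are stored and round-tripped
but excluded from the analysis, which uses BP1–BP7 only.

**Favorable pairing.** Each test reading is compared to its two flanking
reference readings (BP2↔{BP1, BP3}, BP4↔{BP3, BP5}, BP6↔{BP5, BP7}) and
the flank with the smaller absolute difference is kept. Three choices here
were genuinely open and are resolved as follows:

* *Per-pair, per-metric selection* (default). The protocol's favorability
  sentence does not say whether SBP and DBP must share a flank; selecting
  independently per metric is the most favorable reading and the
  conventional one. `joint_flank_choice=True` instead picks, per test
  reading, the single flank minimizing the summed SBP+DBP absolute
  difference (HR always selects independently) — a sensitivity switch, not
  a default.
* *Ties break to the preceding flank*: deterministic and time-ordered.
* *Differences are oriented test minus reference* throughout.

The pairing stage introduces no rounding; integer inputs stay integers.

**Banding and grading.** "Within x" is inclusive (|d| ≤ x); a strict-mode
switch (`inclusive=False`) exists for sensitivity checks because protocol
prose never states strictness. Band schemes: (5, 10, 15) mm Hg for SBP and
DBP, (3, 5, 8) bpm for HR. The part-1 minima (two-of 73/87/96, all-of
65/81/93) and part-2 quotas (≥24 subjects with ≥2/3 in band 1, ≤3 with
0/3) are stored as the printed absolute counts, defined for 99 comparisons
over 33 subjects; the engine warns, but proceeds, at other study sizes.
"≥2 of 3" includes subjects with 3 of 3. Part 3 is the conjunction of
parts 1 and 2. The protocol's intermediate Grade 1/2/3 labels are
represented as the three pass booleans with achieved counts attached;
there is no letter grading.

**Summary statistics.** Reports carry mean and sample SD (n−1 denominator)
of both the signed and the absolute differences, because published
summaries of the form "mean difference 3.94 (SD 3.65)" rarely state
whether the sign was dropped first; the package asserts neither convention.
Bland–Altman pairs use the same chosen flank as the grading, so the plot
and the verdict describe identical comparisons; the limits-of-agreement
multiplier defaults to the conventional 1.96 and is configurable. The
export metadata records the flank convention.

## Synthetic-data generator

No raw readings from real validation studies are published, so all
end-to-end behavior is established on synthetic studies. Per subject, each
metric has a latent trajectory over the nine slots: a baseline drawn from
the population distribution plus a Gaussian random walk. Consecutive
readings 30–60 s apart are correlated but not identical; the walk is what
makes flank choice meaningful (with a flat trajectory both flanks differ
only by noise). Reference readings observe the trajectory plus reference
noise; test readings add `device_bias` plus device noise. Readings are
rounded to integers by default, matching oscillometric displays
(`rounding="none"` for calibration studies). Subjects whose observed
readings violate SBP > DBP > 0 or HR > 0 are redrawn, up to 1000 attempts.

Defaults (all per-metric, units of the metric):

| parameter | SBP | DBP | HR | why |
| --- | --- | --- | --- | --- |
| population mean (SD) | 140.64 (16.38) | 77.12 (8.51) | 72 (8) | SBP/DBP describe an obese, hypertensive-leaning cohort; the HR baseline is a conventional resting value, invented |
| drift SD per slot | 2.0 | 1.5 | 1.0 | mild within-session variation, a few mm Hg over nine readings |
| device / reference noise SD | 3.0 / 3.0 | 2.5 / 2.5 | 1.5 / 1.5 | typical oscillometric repeatability |
| device bias | 0 | 0 | 0 | the default device is well behaved |

Generated covariates (age, sex, height, weight with BMI ≥ 30, arm
circumference) make sessions realistic for the obese cohort the defaults
emulate; they do not feed back into measurement error — obesity-specific
cuff artifacts (conical arms) are out of scope beyond the generic bias
term. An optional `stratify_entry_sbp` mode draws entry SBP from generic
low/medium/high recruitment ranges (90–129, 130–160, 161–180 mm Hg,
cycling); it is off by default because the exact recruitment quotas are a
protocol table this package does not reproduce.

**What a green test establishes.** The generator emulates alternation,
within-subject correlation, additive device error and display rounding. It
does not emulate observer disagreement (the emulated reference is a single
automated device), arm-circumference effects on cuff fit, or non-Gaussian
error tails. Green end-to-end tests therefore establish that the *grading
machinery* is correct, not that any physical device would pass.

**Favorable-selection shrinkage.** Because the kept difference is the
minimum-magnitude of two, its SD is *below* √(device² + reference²) when
reference noise is nonzero. Tests compare the generator's output against
an independent direct simulation of the two-flank minimum rule rather than
against the naive quadrature formula.

**Pass probability.** Monte-Carlo over full replicate studies, each from
an independent child seed (`numpy.random.SeedSequence.spawn`), with the
binomial standard error √(p(1−p)/n) attached.

## Numerical and interface choices

* Requirement constants are counts, not proportions, exactly as printed.
* CSV round-trips are exact: integer-valued readings serialize without a
  decimal point, floats via `repr`. A `#` header comment carries
  provenance (generator seed) and is skipped on read.
* `read_sessions` is strict by default (every session complete);
  permissive mode returns incomplete sessions flagged for the caller, but
  the validation engine always requires complete sessions, since the
  protocol counts are defined over exactly 3 comparisons per subject.
* Heights may be ingested as centimeters (`height_unit="cm"`), the common
  clinical-table convention; internally meters are canonical.
* Protocol failure is an outcome, not an exception: batch entry points
  return the report and expose `StudyReport.all_pass`; only malformed
  input raises. All engine options (tie-break, inclusivity, flank mode)
  are echoed into report metadata.
* This is a library, not a command-line tool: the batch entry points
  (`validate_csv`, `simulate_to_csv`) plus the `examples/` scripts are the
  operational surface.

## Known limitations

* The full protocol's recruitment BP-range stratification quotas and
  two-observer auscultatory reference machinery are not implemented.
* The HR extension is a convention transplant (same requirement counts,
  narrower bands), not a standardized protocol.
* Requirement constants are only meaningful at the 33-subject design size;
  the engine deliberately refuses to rescale them and warns instead.
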
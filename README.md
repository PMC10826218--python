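# blindtrial

Blinding-index estimation, precision-based design and trial simulation for
two-arm sham-controlled trials — built around the blinding assessment of a
24-person feasibility RCT of manual soft tissue mobilisation of the back
(11 active, 13 light-touch control; blinding judged by the participants
themselves and by three outcome assessors on a five-level instrument:
strongly/somewhat active, don't know, somewhat/strongly control).

## What it computes

**Bang blinding index** (arm-specific). With `r_c` correct and `r_i`
incorrect directed guesses among `n` respondents of one arm
(`p_c = r_c/n`, `p_i = r_i/n`):

```
BI      = p_c - p_i                      in [-1, 1]
Var(BI) = [p_c + p_i - (p_c - p_i)^2] / n
95% CI  = BI ± 1.96 · sqrt(Var)
```

0 indicates balanced "random guessing"; an arm with no guessers at all makes
the index mathematically undefinable (reported as NaN, never coerced to 0).
The two arm indices sum to a study-level index (variance = sum of arm
variances). Adequacy thresholds: arm index within ±0.2, summed index within
±0.3.

**James blinding index** (study-level, on [0, 1]):

```
BI_J = [1 + P_dk + Σ_ij w_ij p_ij] / 2
```

with `P_dk` the don't-know proportion, `p_ij` the joint proportions of the
four directed guess cells and signed weights −1/−0.5/+0.5/+1 for
strongly-correct/somewhat-correct/somewhat-incorrect/strongly-incorrect.
1 is complete ambivalence; values below 0.5 suggest unblinding (inadequate
blinding is flagged when the CI upper bound is below 0.5). CIs are
percentile bootstrap over respondents.

Around these, the package provides:

- `blindtrial.reconstruction` — an exhaustive-enumeration oracle that
  recovers the (correct, incorrect, don't-know) counts behind a printed
  index + CI, and the fully reconstructed study dataset as a packaged
  fixture (the counts are uniquely determined; the strength-of-belief
  splits are constructed, documented, synthetic choices).
- `blindtrial.design` — CI half-width as a function of n and assumed guess
  behaviour, and the inverse (required n for a target half-width).
- `blindtrial.summaries` — medians/IQRs, counts/percentages, and
  between-group mean differences with Welch–Satterthwaite intervals
  computed from group summaries (mean, SD, n).
- `blindtrial.simulate` — a synthetic trial generator: stratified permuted-
  block randomisation (blocks of 2 and 4), multinomial five-category guess
  behaviour per role, Gaussian range-of-motion outcomes.
- `blindtrial.pipeline` / the `blindtrial` CLI — CSV in, Table-2-style
  report out (JSON/text/markdown).

## Worked example

```
$ blindtrial fixtures --out fx
$ blindtrial analyze fx/study_responses.csv --seed 1
Blinding analysis report
Randomised: 24; analysed (intention to treat): 24; 95% confidence intervals

Participants
  Bang BI, active arm : 0.55 (0.25 to 0.84)  [not_adequate]
  Bang BI, control arm: 0.08 (-0.37 to 0.53)  [adequate]
  Summed Bang BI      : 0.63 (0.09 to 1.17)  [not_adequate]
  James BI            : 0.53 (0.33 to 0.73)  [adequate]

Assessor 1
  Bang BI, active arm : NaN  [undetermined]
  ...
Outcome assessors (pooled)
  Bang BI, active arm : 0.09 (-0.12 to 0.30)  [adequate]
  Bang BI, control arm: -0.10 (-0.29 to 0.08)  [adequate]
  Summed Bang BI      : -0.01 (-0.29 to 0.27)  [adequate]
  James BI            : 0.82 (0.75 to 0.88)  [adequate]
```

Reading: 55% of active-arm participants correctly perceived their assignment
beyond chance — blinding the active manual intervention was not feasible —
while control-arm participants (0.08) and the outcome assessors (pooled 0.09
and −0.10) were adequately blinded. Assessor 1 answered "I do not know"
throughout, so their Bang index is undefinable and their James index is
exactly 1 (complete ambivalence). James bootstrap CIs vary with `--seed`;
all Bang quantities are deterministic.

Other entry points:

```
$ blindtrial design --width 0.2
{"achieved_halfwidth": 0.199..., "required_n": 97, ...}
$ blindtrial reconstruct --point 0.08 --ci=-0.37,0.53 --n 13
{"matches": [{"n": 13, "r_correct": 5, "r_dontknow": 4, "r_incorrect": 4}], "unique": true}
$ blindtrial simulate scenario.json --seed 7 --out sim.csv
```

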
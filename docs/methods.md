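# Methods

## Setting and estimands

A two-parallel-arm trial (1:1, active manual soft tissue mobilisation vs a
light-touch control) asks each respondent — the participant, and each of
three outcome assessors judging that participant — which intervention they
believe was received, on five levels: strongly/somewhat active, don't know,
somewhat/strongly control. Blinding success is summarised per respondent
group by the Bang index (arm-specific) and the James index (study-level).
Analysis is by intention to treat: every randomised respondent is analysed
as allocated, and the report records analysed = randomised.

## Bang index

Strength levels are collapsed: a directed guess is *correct* iff its
direction matches the respondent's actual arm. With `p_c`, `p_i` the correct
and incorrect guess proportions in one arm of size `n`:

- point: `BI = p_c − p_i`;
- variance: `[p_c + p_i − (p_c − p_i)²] / n` (plug-in multinomial variance);
- CI: Wald, `BI ± z·sqrt(Var)` with the exact normal quantile
  (1.959964 at the default 0.95 level). Intervals are *not* clipped to
  [−1, 1]: a summed index near the boundary legitimately prints a bound
  beyond ±1 (the study's summed participant CI reaches 1.17).

If no one in the arm ventures a directed guess (`r_c + r_i = 0`) the index
is mathematically undefinable. We return an estimate with `undefined=True`
and NaN sentinels rather than 0 — one of the study's assessors answered
"don't know" for all 24 participants, and coercing that to 0 would fabricate
evidence of balanced guessing.

**Summed index.** `BI_active + BI_control`, variance the sum of the arm
variances. By default the summands are first rounded to two decimals before
summing, because that is how trial reports print and combine the arm
indices (0.55 + 0.08 = 0.63, whereas the exact sum 6/11 + 1/13 = 0.6224
would print 0.62). The exact-sum mode is available via
`summed_bang(..., rounding_convention=False)`.

**Adequacy.** Arm-level: adequate iff the point lies in the closed interval
[−0.2, 0.2]; summed: [−0.3, 0.3]; James: inadequate blinding is suggested
only when the CI upper bound is below 0.5. Undefined estimates are
classified `undetermined`.

## James index

`BI_J = [1 + P_dk + Σ w_ij p_ij] / 2`, pooled over both arms, with signed
weights −1 (strongly correct), −0.5 (somewhat correct), +0.5 (somewhat
incorrect), +1 (strongly incorrect). This antisymmetric scheme is the unique
conventional choice that simultaneously reproduces all four study-level
values the source report prints (1 for the all-ambivalent assessor, 0.53 for
participants, 0.79/0.67 per assessor, 0.82 pooled); it is an assumption of
this package, not a fact recoverable from the report. Algebraically the
index is the mean of per-respondent scores `(1 + 1[don't know] + w)/2`
(cell scores 0, 0.25, 1, 0.75, 1), so it lies in [0, 1]; note that both
"everyone ambivalent" and "everyone strongly wrong" score 1.

**CI.** The source report does not state its James CI method, so printed
James CIs are treated as non-reproducible (except degenerate ones). We use
a percentile bootstrap over respondents (default 10,000 resamples, seeded);
constant data give a degenerate interval. A closed-form James variance is
deliberately out of scope. On the reconstructed participant data the
bootstrap gives ≈(0.33, 0.73) against the report's (0.35, 0.72) —
qualitatively compatible, asserted only loosely in tests.

## Reconstruction oracle

`reconstruct_counts` enumerates all `(r_c, r_i, r_dk)` with `r_c + r_i ≥ 1`
summing to the known group size and keeps those whose forward-computed point
and CI match the printed two-decimal values (half-away-from-zero rounding;
exact .xx5 ties accepted either way, conservatively). For every per-arm Bang
estimate the study prints, the match is unique, and pooling the three
per-assessor reconstructions reproduces the printed pooled-assessor indices
and CIs — a nontrivial internal-consistency check the test suite enforces.
Strength-of-belief splits are *not* identified (the Bang index is invariant
to them); the packaged fixture fixes them so the printed James points also
reproduce: participants 6 strongly-active + 5 don't-know (active arm) and
5 strongly-control + 3 strongly-active + 1 somewhat-active + 4 don't-know
(control arm); Assessor 2 all "somewhat"; Assessor 3 all "somewhat" except
one strongly-active guess about a control participant. These splits are
synthetic and labelled as such.

Two source-report quirks, resolved here: the Assessor 2 active-arm CI upper
bound is printed 0.63 in the outcome table but 0.64 in the running text, and
the reconstruction supports 0.637 → 0.64, so the text value is used; and the
Assessor 2 *summed* CI prints (−0.45, 0.53) where the Wald sum over the
uniquely reconstructed counts gives (−0.44, 0.52) under either summand
convention — an unresolved rounding artifact of the source, left as
computed (it is within a display unit and affects no adequacy call).

## Precision-based design

With the sample fixed by circumstance, design is by CI width:
`halfwidth(n, p_c, p_i) = z·sqrt([p_c + p_i − (p_c − p_i)²]/n)`, maximal at
`p_c = p_i = 0.5` (worst case `z/√n`, 0.384 at n = 26), and `required_n`
inverts it to the smallest n meeting a target width. The source report's
specific ±0.315 figure at n = 26 rests on assumptions it does not state; it
is reproduced here only as an inverse-consistency example (all respondents
guessing with net correctness 0.573 gives 0.315 at n = 26) and is not a
package constant.

## Descriptive statistics and ROM contrasts

Quantitative variables: median and IQR (linear-interpolation quantiles);
categorical: counts and percentages. Between-group range-of-motion contrasts
use the unequal-variance mean difference with Welch–Satterthwaite degrees of
freedom, computed from group summaries (mean, SD, n). The source report does
not name its interval method; Welch is adopted because it reproduces both
printed ROM CIs at printed precision while a pooled-variance interval does
not reproduce the flexion CI — this inference is itself encoded as a test.
No formal between-group hypothesis tests are performed, matching the
feasibility design. Simulated coverage of the Welch interval at the
published flexion parameters is ≈95% (checked at 5,000 replicates).

## Synthetic trial generator

`simulate_trial` emulates the study design end to end:

- **Randomisation**: 1:1 permuted blocks, sizes drawn uniformly from
  {2, 4} per stratum (the block-ordering rule is not stated in the source;
  uniform draw is this package's choice), stratified by a binary covariate
  (prior manual-therapy experience; default prevalence 7/24). Every block is
  balanced, so within-stratum imbalance never exceeds max(block)/2 at any
  allocation prefix — a property the tests check on 10,000 allocations.
- **Guesses**: per role, multinomial over {correct, incorrect, don't know}
  with probabilities `theta`; directed guesses split strongly/somewhat by an
  independent `strong_fraction` coin (default 0.5). The arm-level Bang index
  converges to `theta_correct − theta_incorrect` (parameter-recovery and
  Wald-coverage tests at n = 10,000 and n = 200 respectively). Defaults
  mirror the observed pooled response proportions of the reconstructed
  study (participants 11/24 correct, 4/24 incorrect; Assessor 1 always
  ambivalent; Assessors 2 and 3 as observed). Assessor guesses are
  independent of participant guesses given the arm; correlated-cue models
  are out of scope.
- **ROM outcomes**: pre ~ Normal, post = pre + change with change ~ Normal;
  defaults (degrees) take locations from the study's baseline medians
  (flexion 127/132, extension 43/44) and spread/change from its published
  summaries (e.g. active flexion change 3.5 ± 7.9).
- All randomness flows through one seeded generator: config + seed
  reproduces the CSV byte for byte.

What the generator does **not** emulate: guess/outcome correlation within a
respondent, shared cues between assessors, longitudinal "evolving hunches"
over repeated sessions, missing data, and non-normal ROM. Passing tests
therefore demonstrate correctness of the estimators and pipeline under the
stated model, not robustness of blinding inference to those real-data
features.

## Numerical choices and problem sizes

Two-decimal half-away-from-zero rounding for displayed indices (one decimal
for ROM), unrounded internal computation. Reconstruction is exact integer
enumeration, O(n²) per query. Simulation-based tests use fixed seeds and
the smallest sizes at which the checked property is stable: LLN/parameter
recovery at n = 10,000, Wald coverage at 2,000 replicates of n = 200,
Welch coverage at 5,000 replicates, block-imbalance at 5,000–10,000
allocations; the full suite runs in well under a minute.

## Known limitations

- James CIs (other than degenerate ones) are bootstrap-based and will not
  numerically match reports that used a closed-form variance.
- The fixture's strength splits are constructed, not observed; any analysis
  of the fixture that depends on strength beyond the James points inherits
  that assumption.
- Raw participant-level ROM and baseline data are not recoverable from the
  published summaries; the fixture carries no ROM values and printed
  medians/IQRs are not reproduction targets.
- Credibility/expectancy-style blinding constructs and qualitative analysis
  of free-text justifications are out of scope.
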
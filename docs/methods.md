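# Methods

## The decision problem

A group of four people each judge, twice, whether a briefly shown
128 × 128 block image is dominated by blue or orange (a 2AFC task). After
the first, independent response, each person sees the other three
responses and answers again. The displayed peer responses are scripted
by the experimental software, not produced by the peers. The quantity of
interest is *informational conformity*: how often the second response
matches the peer majority, and how that depends on the evidence balance.

Net public information (NPI) is the signed count of peers agreeing minus
disagreeing with the first response: +3, +1 (congruent majority), −1, −3
(incongruent majority). With three peers a strict majority always
exists. Conformity is coded per trial as 1 iff the second response
equals the peer-majority response — so on congruent trials *staying* is
conformity, and shifting away from the majority is non-conformity.

## The Bayesian benchmark and the weighted model

Treat every group member as an unbiased observer with the same perceived
correct rate `p_c`. After an incongruent round with `n` members
(including oneself) on one side and `m` on the other, the posterior
probability that following the majority is correct is

    p(correct | n, m) = p_c^m (1 − p_c)^n
                        / [ p_c^m (1 − p_c)^n + (1 − p_c)^m p_c^n ]

the equal-weight Bayesian Nash Equilibrium (BNE) benchmark. In this
four-person task, NPI = −3 maps to (n = 1, m = 3) and NPI = −1 to
(n = 2, m = 2); at `p_c = 0.5524` these give 0.604 and exactly 0.500
(the n = m case is 0.5 for any `p_c`).

Decision makers need not weight their own signal like a peer's. The
weighted model raises the private-signal likelihood terms to a power β:

    p_β(correct | n, m) = p_c^m (1 − p_c)^β (1 − p_c)^(n−1)
        / [ p_c^m (1 − p_c)^β (1 − p_c)^(n−1) + p_c^β p_c^(n−1) (1 − p_c)^m ]

β = 1 recovers the BNE; β > 1 overweights private information (less
conformity); β < 1 overweights social information (more conformity).
Algebraically the posterior is a logistic function of
`(m − n + 1 − β)·[ln p_c − ln(1 − p_c)]`, so for `0.5 < p_c < 1` it is
strictly decreasing in β; the closed-form derivative implemented in
`posterior_beta_derivative` is

    dp_β/dβ = [ln(1 − p_c) − ln p_c] · (1 − p_c)^(β+m+n−1) · p_c^(β+m+n−1)
              / [ p_c^m (1 − p_c)^(β+n−1) + p_c^(β+n−1) (1 − p_c)^m ]²

All posterior expressions are evaluated in log-space (`expit` of a
log-odds difference), so extreme `p_c` never overflows.

**Probability matching.** The package maps the model to behavior by
reading the posterior as the conform *probability* (no threshold rule,
no extra decision noise). This is what makes observed conformity
proportions directly comparable to posterior values, and what makes β
identifiable by inverting or by maximum likelihood.

**A structural range limit.** Under probability matching the conformity
rate at (n, m) is capped at the β → 0 limit
`p_c^m / [p_c^m + (1 − p_c)^m]` — with `p_c = 0.5524` and m = 3 that is
≈ 0.653. Observed rates above this cap (they occur in real data) are
*outside the model's range*: `invert_beta` reports them as such rather
than returning a spurious β, and the simulator's calibration clamps such
groups to `BETA_FLOOR = 0.05` (the nearest attainable behavior). This is
a substantive model limitation, not a numerical artifact.

## β estimation

`BetaWeightEstimator` (an sklearn-style estimator) maximizes the
Bernoulli log-likelihood of conform/non-conform outcomes over
`log β ∈ [−5, 5]` (bounded scalar minimization after collapsing trials
to per-(n, m) sufficient statistics). The standard error comes from the
observed information (central-difference second derivative at the
optimum). Boundary solutions are flagged (`on_boundary_`); all-conform
or all-non-conform samples raise a non-identifiability error, as does
`p_c ≤ 0.5` (the posterior is then non-decreasing in β).
`invert_beta` uses bracketed Brent root-finding on log β — monotonicity
guarantees uniqueness — to 1e−8 absolute tolerance in β.

## Trial schedules

60 trials by default: the four peer-correctness patterns (RRR, RRW, RWW,
WWW) in exact quarters and the two dominant colors in exact halves, in a
seeded random order. Whether patterns are crossed orthogonally with
color is underdetermined at 60 trials (15 per pattern cannot split
evenly over two colors), so the pairing is randomized there and balanced
within color halves whenever the trial count is divisible by 8. Which of
the three peer slots is wrong in mixed patterns is shuffled per trial.
Trial counts not divisible by 4 are rejected. Stimulus grids (exact
dominant-cell counts, default dominant fraction 0.53) are provided as
optional plumbing; no statistic reads the grid — only the true color.

## The synthetic cohort

The simulator replaces unavailable human data with agents whose
structure matches the analysis assumptions:

* first response correct with probability `p_true` (group means
  0.768/0.804/0.775 for anodal/sham/cathodal arms, the reported actual
  accuracies);
* subjective estimate `p_est = 0.5524` everywhere (the reported mean
  self-estimate), used — not `p_true` — in the conform policy, since the
  model concerns *perceived* reliability;
* incongruent trials: conform with probability
  `p_β(correct | n, m)` at the subject's own β and `p_est`;
* congruent trials: repeat the first choice with an empirical
  stay-probability per |NPI| (per-arm values 0.986/0.957, 0.999/0.973,
  0.996/0.977 at |NPI| = 3/1, from the reported congruent-condition
  means; the sham 1.000 is smoothed to 0.999 to avoid a structurally
  degenerate cell). Congruent behavior is parameterized empirically
  because the weighting model targets the information-conflict case;
* response times lognormal (σ = 0.35 on the log scale; log-means set so
  arm means sit near the reported 2.99–3.23 s) with a +0.04 log-shift on
  incongruent trials, matching the reported ~4% congruency slowdown.
  Lognormal was chosen as the minimal strictly-positive right-skewed
  two-parameter family; only means were reported;
* a per-subject `believes_worse` flag (thinks own accuracy below
  others'), Bernoulli with arm probabilities 0.05/0.381/0.35, feeding
  the 2 × 3 chi-square test.

Arm-level β values come from inverting the weighted posterior at the
reported NPI = −3 conformity means (anodal 0.511 → β ≈ 2.79, sham
0.562 → β ≈ 1.82); the cathodal mean 0.711 exceeds the model's range
cap and clamps to the floor (see above). Between-subject heterogeneity
— lognormal β with log-sd 0.35, logit-normal jitter (sd 0.15) on
`p_true` and `p_est`, a small jitter on the RT log-mean — represents
modest individual differences; these sds are design choices, fixed once.
Per-subject seeds are spawned from the master seed, and each subject
gets an independently randomized schedule by default (a shared schedule
is available), since the original per-subject randomization is unstated.

What the simulator does *not* emulate: learning or adaptation across
trials, sequential belief updating, normative (reputation-driven)
conformity, lapses that depend on time-on-task, and the empirical fact
that human NPI = −1 conformity (0.14–0.22) falls far below any
single-β prediction (≥ 0.46 here). Passing tests therefore validate the
pipeline and the model's internal logic, not the claim that humans are
single-β probability matchers.

## Statistical pipeline

All group statistics operate on subject-level summaries (proportions
over the trials where the conditioning event occurred, NaN with a zero
count when a cell is empty) — never pooled trials — so standard errors
are between-subject. The battery: Shapiro-Wilk normality (reported, not
branching), one-sample Wilcoxon of incongruent conformity vs 0 per arm,
paired Wilcoxon congruent vs incongruent, Kruskal-Wallis across arms on
incongruent conformity, mean RT, and accuracy, a Friedman omnibus over
the four NPI levels (the within-subject χ²(3) analogue; subjects missing
a level are excluded with a logged count), pairwise Mann-Whitney arm
contrasts with Benjamini-Hochberg FDR inside three declared families
(incongruent conformity, NPI = −3 conformity, mean RT), paired Wilcoxon
of follow-right vs follow-wrong rates and of incongruent vs congruent
RT (per arm and pooled), and a chi-square on believes-worse × arm.
Wilcoxon tests discard zero differences (Wilcoxon's method) and use the
exact distribution up to n = 25, the normal approximation beyond.
Degenerate cells (zero variance, too few subjects) are reported as
skipped results with a reason, never silently dropped.

`compare_to_bne` tabulates, per arm and incongruent NPI level, the
observed subject-mean conformity, the BNE posterior, and a one-sample
Wilcoxon of subject proportions against that constant.

## Numerical and validation choices

Posteriors in log-space; β searched on a log grid; Brent for inversion,
bounded scalar minimization for the MLE (xatol 1e−10 on log β). CSV is
the single interchange format; `read_trials` recomputes NPI from the
stored responses and rejects inconsistent rows with line numbers. Run
configurations are strictly validated (unknown keys rejected with their
location); every report directory carries the master seed, a config
hash, and the package version in `metadata.json`; identical
configurations produce byte-identical reports.

Test problem sizes are scaled for quick iteration: the null-calibration
check uses 400 simulated experiments at 12 subjects/arm × 40 trials, and
parameter-recovery cohorts use 20 subjects at 60/180/600 trials over ten
seeds — sizes chosen so stochastic checks have tight Monte-Carlo error
while the suite stays fast.

## Known limitations

* The probability-matching cap means the model cannot represent groups
  whose conformity exceeds `p_c^m / [p_c^m + (1 − p_c)^m]`; with the
  calibrated defaults the simulated cathodal arm tops out near 0.65 at
  NPI = −3 (observed: 0.711), compressing the cathodal–sham effect
  relative to the study it emulates.
* β is a single group/subject constant; no hierarchical pooling, no
  trial-order effects.
* The simulator's heterogeneity is stylized (independent lognormal /
  logit-normal jitters); real subject covariance (e.g. confident
  subjects being faster) is not modeled.
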
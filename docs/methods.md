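# Methods

This note documents the statistical procedures, the synthetic-data models
behind the test suite, the numerical conventions, and the design choices
made where the methodology left room.

## Soccer pipeline

**Unit of analysis.**  A *team-match* is one team's participation in one
match; it has exactly one third per condition (wR, Sy, nS).  The
relative-connectivity sample contributes one value per team-match per cRAS
condition, i.e. each team-match yields one Sy and one nS value, both
normalized by its own wR third (`pooling="team_match"`, default).  A
coarser mode averaging the two teams of a match first is available
(`pooling="match_mean"`).  The default is the most granular unit
consistent with the design.

**Connectivity.**  `C = n_p / n_c` is computed from the summed counts of
the (possibly filtered) third.  `n_c = 0` is an undefined statistic and
the team-match is dropped from that bound's sample with a logged warning
— never imputed.  The same applies when the wR reference has `C_wR = 0`.

**Sequence-length filters.**  The "length" of a possession is its number
of completed passes (length 0 = possession without a pass).  Bounds are
inclusive on both sides: a max-bound of 3 keeps possessions with at most
three passes.  After filtering, `n_p`, `n_c` and `C` are recomputed from
the retained possessions only.

**Rank test.**  Two-sided throughout (the hypothesis is "same
distribution", not a direction).  The exact p-value enumerates all
`C(n_x+n_y, n_x)` assignments of the pooled midranks to the first sample;
the enumeration is evaluated with an integer subset-sum dynamic program
over doubled midranks, which is exact with ties and fast enough that the
default cutoff is 10⁶ assignments.  Beyond the cutoff a normal
approximation with tie-corrected variance and a 0.5 continuity correction
is used; a seeded Monte-Carlo permutation method (add-one convention, so
p > 0) can be forced.  Exact and normal p agree to well under 0.01 by
n = 15 + 15.  No multiple-testing correction is applied across bound
sweeps (each bound is reported raw); that choice is deliberate and
documented rather than hidden.

**Scoring statistics.**  The binomial probability is the *point*
probability of the observed favor split, computed in exact rational
arithmetic (`fractions.Fraction`) and converted to float on output.  A
one-sided tail variant (conventional sign test) exists behind the
`tail=True` flag as a clearly labelled extension.  Ties — team-matches
whose goal difference is below D both ways — count for neither side.
Goals are compared per third without duration normalization since thirds
are equally long.  The paired t-test on per-team-match goal pairs is the
parametric counterpart.

## Stroop pipeline

The default selection keeps incongruent trials of the Stroop run in the
music block (block 2).  Groups are compared at the *trial* level (pooled
trials), matching cumulative-distribution plots of all trials; a
per-participant-median mode exists because the pooling level is a genuine
modelling choice (`pooling="participants"`).  The 95% CI of the median is
the distribution-free symmetric order-statistic interval: the widest pair
of ranks `(l, n+1-l)` with binomial coverage ≥ 0.95, which requires
n ≥ 6; a percentile bootstrap is available as an alternative.  No
trimming or outlier filtering is applied by default.  Phase labels are
taken from the input table; no cycle-date arithmetic is implemented.

## Synthetic data generators

The generators emulate the *statistical structure* of the experiments so
that every pipeline stage can be verified against known ground truth.

**Match model.**  Possessions alternate between the two teams; their
total per third is Poisson with mean `2 × possession_rate ×
third_minutes`.  Within a possession, each contact converts into a
completed pass with probability `q = base_pass_success + effect(cond)`
and the possession ends at the first failure, so `n_passes` is geometric
with mean `q/(1−q)` and `n_contacts = n_passes + 1`.  Consequently the
connectivity of a long third converges to `q`, and the injected
ground-truth relative connectivity is `(q_cond − q_wR)/q_wR` exactly.  A
goal ends a possession with a probability that rises with the number of
completed passes (0 / 0.02 / 0.06 / 0.10 / 0.15 for 0/1/2/3/≥4 passes):
build-up play scores, long-distance attempts do not.

Defaults: 5 players, 10-minute thirds, 4 possessions per team per minute
(≈ 40 per third — a plausible tempo for a small-pitch passing exercise;
no possession counts are published, so this is a documented assumption),
`base_pass_success = 0.65`.  The `male16` preset (16 matches, wR thirds
at beginning/middle/end 6/6/4 times) injects `effect_Sy = +0.04·q₀` and
`effect_nS = −0.08·q₀`, i.e. asymptotic relative connectivities +0.04 and
−0.08 — the reported male magnitudes used as generator inputs; the
resulting Sy-vs-nS goal-rate gap is ≈ 30%.  The `female14` preset (14
matches, 5/5/4) injects no effects and serves as the null.  The wR
position counts are honored exactly; which match gets which position is
randomized.  Each match draws from its own spawned substream of the seed,
so any subset of matches is reproducible.

**Stroop model.**  Reaction times are shifted lognormal:
`rt = factor · (0.3 + interference + exp(N(ln 1.2, 0.35)))` seconds, with
`interference = 0.15` s added on incongruent Stroop-run trials and
`factor = 1 + tempo_effect` applied during the music block only.  The
group median of the analysis selection is therefore known in closed form:
`(1+effect) · (0.3 + 0.15 + 1.2) = (1+effect) · 1.65` s, and a −6.5%
effect at 140 bpm shifts the median by ≈ 0.1 s — matching the reported
male effect size on a realistic incongruent-trial RT scale.  Group sizes
default to the study's design (male 20/20/20 per tempo; menstrual
10/10/10; folicular 2/2/5; ovulatory 4/6/3; luteal 8/7/8).  Each
participant completes 3 blocks × 2 runs × 48 trials (24 congruent + 24
incongruent, order randomized), with the tempo recorded only on block-2
rows.

**What the generators do not emulate.**  Trials are i.i.d. within a
group — there is no participant-level random effect, no learning or
fatigue across blocks, and congruent/neutral trials share the incongruent
RT model minus interference.  Teams are homogeneous: no player
heterogeneity, defensive pressure, score effects or within-match
momentum.  Passing tests on these generators therefore validates the
*statistical machinery* (calibration, recovery, coverage) under the
stated models; it does not certify behavior under real-data features such
as clustered trials or heterogeneous team strength.  In particular, the
pooled-trial median CI assumes exchangeable trials; with strong
participant effects its real-data coverage would be lower.

## Numerical conventions and edge cases

- p-values lie in (0, 1]; the exact enumeration always includes the
  observed assignment, the Monte-Carlo method uses the add-one
  convention, and normal-approximation p is clipped.
- All ties in a rank test (pooled sample constant) give p = 1.
- Degenerate variance (all paired differences equal; both samples
  constant) raises a dedicated error instead of returning NaN.
- Config probabilities pushed outside [0, 1] by condition effects are
  clipped with a logged warning.
- CSV dialects are UTF-8 with "." decimals and a mandatory header;
  canonical writes are byte-stable under read/write round-trips.

## Test problem sizes

The heavier verification studies run at sizes chosen to keep the full
suite comfortably interactive while leaving Monte-Carlo error well below
the asserted margins: 1000 seeded replicates for null calibration of the
condition contrast, 16 replicates of 200-match experiments plus 200
replicates at the study's 16 matches for effect recovery, 500 replicates
for Stroop power and null uniformity, and 20,000 vectorized replicates
per group size for median-CI coverage.

## Known limitations

- **Matched-design conservativeness.**  The Sy and nS relative values of
  a team-match share the same wR denominator, which induces a positive
  correlation (≈ 0.5 for equal per-third sampling variances) between the
  two samples.  A two-sample rank test on such paired-by-design samples
  is markedly conservative: the null-calibration study rejects far below
  the nominal 5% rate.  This is a property of normalizing both cRAS
  thirds by the same reference, not of the test implementation (the same
  test is well calibrated on independent samples, which the suite also
  verifies).  Practically it means p-values from this design understate
  significance — observed rejections are, if anything, stronger evidence.
- **Order-statistic CI discreteness.**  At small samples the attained
  coverage of the minimal conservative interval can jump well above the
  nominal level; at n = 48 (2 participants × 24 trials) it is 0.9707,
  while the next narrower interval drops to 0.9394 — no interval attains
  ≈ 95% at that n.  Coverage statements at tiny group sizes should quote
  the attained, not the nominal, level.
- The exact rank test enumerates up to 10⁶ assignments; beyond that the
  normal approximation is used even for moderately small samples with
  many ties, where a Monte-Carlo permutation run (seeded) is the safer
  manual choice.
- The binomial point probability is not a tail test; its calibration
  property is conservativeness (P ≤ α occurs with frequency ≤ α under
  the null), not uniformity.
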
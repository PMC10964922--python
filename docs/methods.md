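# Methods

## Phonotactic probability

All measures are type-based: the unit of counting is the unique phonemic
transcription (word type), never the corpus token count. This follows the
standard finding that phonotactic intuitions track type rather than token
statistics. Word-type identity is the transcription sequence, not the
spelling; rows of a lexicon file that share a transcription are merged and
their token frequencies summed (the merged frequency is carried along but
never used by the measures).

Positional measures (word-initial by default, word-final supported) use the
number of word types as denominator. This convention exactly reproduces
cells of the form 165/51,322 → 0.0032 and 1,452/51,322 → 0.0283 for a
German-adult-lexicon-shaped input, and 142/1,660 → 0.0855 for an
infant-directed one. The published French adult-lexicon probabilities are
*not* consistent with count/47,342 under any rounding we tried (e.g.
3,875/47,342 = 0.0819 vs a printed 0.0832), and no alternative denominator
reproduces them mutually; we therefore implement the type-count denominator
and treat the French cells as non-reproduced rather than fitting an ad-hoc
denominator.

The overall (non-positional) consonant measure divides a consonant's
occurrences across all word types by the total number of consonant
occurrences. The source tables do not print this denominator; ours is a
stated definition, and only orderings (e.g. /s/ > /ʃ/ in a German-shaped
lexicon) are treated as reproducible.

Display rounding is 4 decimals, half-away-from-zero, with nonzero values
below 0.00005 rendered as "<0.0001".

`synthetic_lexicon` builds deterministic lexicons with prescribed
word-initial uniphone/biphone type counts (and optionally prescribed
overall counts) plus arbitrary unique filler material. It exists because
the lexical databases themselves (CELEX, LEXIQUE, CHILDES derivatives) are
not redistributable; only the prescribed counts are meaningful.

## Stimulus and trial design

The nonword space is CCVCV: cluster C1C2 ∈ {s, ʃ} × {t, p}, tail V1C3V2
with V1 ∈ {a, i, o, u, e, y}, C3 ∈ {k, g, d, b, m, n, r}, V2 ∈ {a, i}.
OCP-Place bans C2–C3 pairs sharing place: /p/ with {m, b}, /t/ with {n, d}.
Because tails must combine with *all four* clusters, surviving tails have
C3 ∈ {k, g, r}: exactly 6 × 3 × 2 = 36 candidates, all of which are used at
the default n = 36 (so the 144-item full cross is forced up to ordering).
When fewer tails are requested, selection is stratified round-robin over
(V1, C3) cells, separately within each final vowel to keep the /a/-/i/
halves exact; ties are broken by seeded draws, so generation is a pure
function of (config, seed).

Trial lists hold 12 same-condition items and are padded with silence to
18.000 s. The source procedure varied inter-stimulus intervals without
stating a rule, so the default distributes the silence equally over the 12
post-item gaps (trailing gap included, so a list ends at exactly 18 s); a
`jitter` option perturbs the gaps while preserving the exact total.
Synthetic item durations are Gaussian per condition × pronunciation
(German 779±68 / 676±43 ms, French 461±31 / 441±25 ms for s-/ʃ-initial
items), clipped at ±3 SD.

Experiment versions cross first-block pronunciation × first-test-trial
condition × first-test-trial side (8 versions). Versions are ordered with
pronunciation varying fastest so that round-robin assignment of
participants to versions stays counterbalanced at any sample size — with
the alternative ordering, small simulated samples can make pronunciation
and block perfectly collinear (each block contributes one pronunciation per
participant, so the two factors separate only across participants whose
versions differ in first-block pronunciation). Adjacency rules: at most two
consecutive same-side trials across the whole 28-trial sequence (warm-ups
included, carried across the block boundary) and at most two consecutive
same-condition test trials within a block. Warm-up trials (music, one per
side at each block start) are typed placeholders with no condition or
pronunciation. Sequences are built by sequential feasible sampling with
bounded retries; the validator re-checks every generated version.

## Synthetic looking-time data

For participant j on a test trial with contrast codes (ℓ, f, r, b) for
language, phonotactics, pronunciation, block:

log LT = β₀ + β_L ℓ + β_P^{(g)} f + β_R^{(g)} r + β_B^{(g)} b
         + β_{PR}^{(g)} f·r + β_{PB}^{(g)} f·b + u₀ⱼ + u₁ⱼ r + ε,

with (u₀, u₁) bivariate normal and ε normal; LT = exp(log LT) clipped to
[0.5, 18] s. The natural logarithm is used throughout: exp(1.75) ≈ 5.75 s
is a plausible trial-level geometric mean, whereas base-10 would imply
56 s, beyond the 18 s list cap. Clipping (not resampling) at the ceiling
mirrors the trial mechanics — a look simply cannot outlast the list.

Default fixed effects are the published estimates of the study this
pipeline emulates (intercept 1.75; language 0.03; French/German
phonotactics −0.07/−0.03; pronunciation 0.02/0.02; block −0.23/−0.09;
phonotactics×pronunciation −0.04/−0.04; phonotactics×block −0.01/0.02).
Variance components are *calibration constants*, not published values
(intercept SD 0.15, pronunciation-slope SD 0.05, correlation 0, residual SD
0.35): they put raw per-condition SDs in the observed 1.5–2.5 s range.

Contrast codebook: French = +1, s-initial = −1, French pronunciation = +1,
block 1 = −1. The phonotactics sign makes "longer looks to /s/-initial"
a negative coefficient; the block sign makes the published negative block
coefficient encode the observed attentional *decline* from block 1 to
block 2 (coding block 1 as +1 would invert that, contradicting the decline
the generating values are meant to produce). The codebook is explicit and
overridable; flipping a factor's signs flips the matching estimates and
leaves |t|, p, log-likelihood and BIC unchanged (tested).

Warm-up looking times come from a separate lognormal nuisance distribution
(log-mean 1.9, log-SD 0.4). Dropout is geometric: after each completed
trial from the 14th on (one full block, the inclusion threshold), the
participant stops with hazard 0.013, chosen so that roughly one participant
in six fails to finish — the observed order of magnitude. Dropout never
truncates mid-trial.

What the simulator does *not* emulate: look-away micro-dynamics (the 2 s
look-away termination exists only implicitly through truncated LTs),
fussiness exclusions, session-level drift, or acoustic differences between
items beyond their durations. Passing recovery tests therefore show that
the analysis recovers the generative model's parameters — not that real
infant data satisfy that model.

## Analysis

Preprocessing retains participants completing ≥14 trials (one entire block,
warm-ups included), keeps partial second blocks, drops warm-ups, applies
the natural log, and attaches codebook contrasts. Note a participant with
20 completed trials contributes 16 test rows (20 minus four warm-ups).

The confirmatory model's twelve fixed effects are built explicitly as an
indicator-nested design (per-language columns are indicator(group) × code),
with a correlated random intercept + pronunciation slope per participant,
fit with statsmodels' MixedLM. REML is the default for reported
coefficients; ML is available and is always used for BIC comparisons.
p-values are Wald-normal on estimate/SE; CIs are ±1.96 SE. BIC uses
n = number of observations and k = fixed effects + unique random
(co)variances + residual variance.

Solver robustness: quasi-Newton optimizers occasionally report convergence
short of an optimum on the boundary of the random-effects covariance space
(singular fits are common at infant-study sizes). The fit routine therefore
falls back across solvers, rejects non-finite solutions, and refines any
near-boundary solution with a warm-started derivative-free pass, keeping
the best log-likelihood. Non-convergence is reported via a flag and
captured warnings, never an exception. The test suite pins the ML
log-likelihood to an independent brute-force optimizer (GLS-profiled
Nelder–Mead on the marginal Gaussian likelihood) on small fixtures.

Per-block exploratory fits drop the block terms and — necessarily — the
pronunciation random slope: within one block each participant hears a
single pronunciation, so the slope is confounded with the intercept.

Descriptives report raw (untransformed) per-condition means and SDs over
participant-level condition means, plus counts of participants looking
longer to s-initial, longer to ʃ-initial, or tied. Participant-level
aggregation is the convention that makes SDs ≈ 2 s plausible under an 18 s
ceiling; trial-level SDs would be larger.

## Problem sizes used by the checks

Parameter recovery simulates 500 replicates at 60 participants/group;
null-evidence behavior uses 200 simulations at the study's 24/group with
the null implemented as equal per-language phonotactic effects (−0.05
each); design constraints are validated over 1,000 seeds; the acceptance
script uses lighter summaries (40 recovery replicates, 50 null
simulations) to stay around a minute of runtime.

## Known limitations

- French printed lexicon probabilities are non-reproducible (above); the
  package can compute them from a real LEXIQUE-like file but ships no data.
- Satterthwaite/Kenward–Roger degrees of freedom are not implemented;
  Wald-normal p-values are anticonservative at very small n.
- The BIC Bayes factor is the unit-information approximation; no MCMC.
- The exact 36 tails of the original stimulus list are not reproduced
  (the supplementary list is not bundled); the generator reproduces the
  constraint structure, not the specific draws.
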
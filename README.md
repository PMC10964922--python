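# phonohpp

Tools for a cross-linguistic developmental-psycholinguistics workflow:
computing positional phonotactic probabilities from phonemic lexicons,
generating phonologically constrained nonword stimuli and counterbalanced
headturn-preference-procedure (HPP) trial designs, simulating infant
looking-time data with realistic structure, and analysing looking times
with nested sum-contrast linear mixed models plus a BIC-based Bayes-factor
test for null interactions.

The package is aimed at infant-language researchers who want to (a) quantify
how frequent a phoneme or consonant cluster is at a word edge in a lexicon
— e.g. that word-initial /ʃt/ is frequent in German but word-initial /st/ is
not, and vice versa in French — (b) build HPP experiments around such
contrasts, and (c) analyse or power-simulate the resulting looking-time
data.

## The measures and models

**Phonotactic probability** (all by *type* frequency — each word type counts
once, corpus token counts are ignored):

- positional uniphone probability of phoneme *x* at a word edge:
  `P(x) = #{word types with x at that position} / #{word types}`
- positional biphone probability of an ordered pair *xy*:
  `P(xy) = #{word types beginning (or ending) with xy} / #{word types}`
- overall consonant probability: the share of all consonant tokens across
  word types that are *x* (non-positional).

**Stimulus design**: 144 unique CCVCV nonwords = 4 onset clusters
{/st/, /sp/, /ʃt/, /ʃp/} × 36 shared VCV tails, with an OCP-Place
constraint (no /p/…/m, b/ and no /t/…/n, d/ across C2–C3), tails balanced
over first vowels and split half /a/- and half /i/-final. Nonwords are
packed into 12-item single-condition lists padded with silence to exactly
18 s per speaker, and arranged into 8 counterbalanced 28-trial experiment
versions (2 pronunciation blocks × [2 warm-ups + 12 test trials], ≤2
consecutive same-side trials, ≤2 consecutive same-condition trials).

**Analysis**: with all two-level factors sum-contrast coded (−1/+1), the
confirmatory model is

```
log LT ~ 1 + Language + Language/(Phonotactics × Pronunciation + Block + Phonotactics:Block)
         + (1 + Pronunciation | Participant)
```

i.e. twelve fixed effects (intercept, language, and per-language
phonotactics, pronunciation, block, phonotactics×pronunciation,
phonotactics×block), REML-estimated, Wald CIs and p-values. Null evidence
for the language×phonotactics interaction uses ML fits of
`log LT ~ Language * Phonotactics + (1 | Participant)` with and without the
interaction and converts the BIC difference: `BF01 = exp(ΔBIC/2)`,
`P(H0|data) = BF01 / (1 + BF01)`.

The simulator is the generative mirror of the confirmatory model
(lognormal-like looking times truncated at the 18 s list length,
participant random intercepts and pronunciation slopes, block decline,
geometric dropout after the first block).

## Worked example

```python
import phonohpp as p

inv = p.study_inventory()
# a synthetic stand-in shaped like a German adult lexicon:
# 51,322 word types, 165 /s/-initial, 1,452 /ʃt/-initial
lex = p.synthetic_lexicon(
    51_322, inv,
    initial_biphones={("s", "t"): 8, ("s", "p"): 6, ("ʃ", "t"): 1452, ("ʃ", "p"): 816},
    initial_uniphones={"s": 165, "ʃ": 4478},
    language="German", register="ADS",
)
row = p.positional_uniphone_probability(lex, "s")
print(row.count, row.denominator, p.format_probability(row.probability))
# 165 51322 0.0032   → /s/ begins 0.32% of German word types

df = p.simulate_dataset(p.SimParams(n_per_group=24, seed=42))
table = p.preprocess(df)            # drops warm-ups, logs LT, attaches ±1 codes
fit = p.fit_confirmatory(table)
c = fit.coefficients["Language[French]:Phonotactics"]
print(f"{c.estimate:+.3f} (SE {c.se:.3f}, p={c.p:.3f})")
# -0.073 (SE 0.016, p=0.000)  → French infants look longer at s-initial lists

bc = p.fit_interaction_comparison(table)
print(f"BF01 {bc.bf01:.3f}, P(H0) {bc.posterior_h0:.3f}")
# BF01 7.672, P(H0) 0.885     → the data favour no cross-language difference
```

A negative phonotactics coefficient means longer looking times to
/s/-initial lists (s-initial is coded −1); the posterior P(H0) is the
probability, under equal prior odds, that language groups do not differ in
their phonotactic effect.

The same functionality is available from the shell:
`phonohpp lexstats|stimgen|simulate|analyze --help`.

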
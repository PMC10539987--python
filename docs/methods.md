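# Methods

This note documents the models, conventions and design decisions behind
`painattrib`, in the spirit of a statistical software methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

The pipeline operates on three long-format tables. An **attribution** is
one ranked free-text perceived cause of pain from one participant at one
timepoint (`pre` or `post`); each participant contributes exactly 3
ranks per available timepoint. **Participants** carry arm assignment
(`prt`, `placebo`, `usual_care`) and 0–10 pain intensity at baseline,
posttreatment, and 1-year follow-up. **Codings** attach one codebook
category per attribution per coder. Validators enforce the dialect
(timepoint and arm labels, rank uniqueness, pain bounds) and report
findings structurally rather than failing silently.

## Text preprocessing

One frozen convention shared by every text-facing component: lowercase;
split on any non-alphabetic character (slashed/hyphenated compounds like
"work/lifestyle" or "8-14 h/day" must separate, and numerals carry no
attribution meaning at this corpus size); drop tokens of length < 2 and
stopwords; stem with an English (Porter2-style) stemmer implemented in
the package. Two deliberate strengthenings of the textbook recipe:

* stemming is applied to a fixed point (at most a handful of rounds), and
* stopwords are filtered both before and after stemming,

which together make `preprocess` exactly idempotent on its own output —
a property the test suite checks and downstream serialization relies
on. The stopword list is vendored in `stopwords.py` so that golden
values and serialized document-term matrices are tied to a versioned
artifact. If the stemmer or list ever changes, the golden preprocessing
tests are regenerated with it; they document the package's convention,
not an external standard.

No lemmatization, n-grams, embeddings, or spell correction: attributions
average ~3 words and the analyses are count-based.

## Codebook and mind-brain scores

Eleven mutually exclusive categories (spinal condition, physiological,
injury, activity, neglect, sedentariness, stress, psychological, brain,
hereditary/congenital, age); stress, psychological and brain form the
mind/brain subset. Each attribution gets exactly one category (forced
choice — the score arithmetic requires it; multi-label is unsupported).
A participant's mind-brain attribution score at a timepoint is the count
(0–3) of their attributions in the mind/brain subset; it is invariant to
rank order, and more than 3 attributions per participant-timepoint is an
error, not a cap.

Consensus coding passes unanimous codes through, surfaces disagreements
for external resolution, and refuses to score unresolved attributions.
Printed prevalence percents round half-away-from-zero to integer
percent, with one decimal kept below 1% (so 1/453 prints as 0.2%, not
0%).

**Cohen's κ** uses p_e from the product of marginals. The 95% CI is
κ ± 1.96·SE with the Fleiss–Cohen–Everitt large-sample variance, and the
Z statistic uses the variance under the independence null; the
computation is delegated to `statsmodels` and cross-checked in the test
suite against an independent hand-coded implementation of both variance
formulas. κ on 0–3 score scales is unweighted (nominal) by default —
linear/quadratic weights are available as an option but are not the
default because the score is a count of a 3-trial process, not a rating.

## Automated lexicon scoring

The real expert-generated word list behind this algorithm class is not
public, so the package ships a documented stand-in of 64 clinically
plausible raw terms (stress/strain, emotion, psychological-trait,
developmental-history and neurobiological vocabulary), reduced by the
shared preprocessing to 52 stems. Matching is stem-set membership — no
phrase matching — because the algorithm is word counting and its
characteristic error is word-level: the lexicon deliberately includes
*childhood*, so "childhood injury" is auto-flagged as mind/brain while a
human codes it as injury. Fidelity to that documented failure mode was
preferred over inventing an error-free list; users supply their own
lexicon as JSON to change this. An empty attribution set is treated as
missing, never as a score of 0.

## Word-frequency change

Per-stem counts are normalized to rates per 100 attributions at each
timepoint (pre/post totals differ under dropout), ranked by |post − pre|
with lexicographic tie-breaks; both token counts and document
frequencies are emitted because either could be the quantity of
interest. Words absent pre but present post are flagged novel. No
per-word significance testing: the table is descriptive.

## Regularized Poisson text scaling

The scaling model is the standard Poisson document-scaling (Wordfish
family) likelihood

    y_ij ~ Poisson(μ_ij),  log μ_ij = α_i + ψ_j + β_j θ_i

with document verbosity intercepts α, word frequency intercepts ψ, word
loadings β and document positions θ, plus ridge penalties λ_β Σβ_j² and
λ_θ Σθ_i². This is a *reconstruction* of the "regularized scaling for
short documents" algorithm class, not a replication of any specific
published estimator; equivalence with other implementations is not
claimed. Defaults λ_β = λ_θ = 0.1, tol = 1e-6 (relative penalized
log-likelihood change), max 500 sweeps.

Estimation alternates damped 2×2 Newton updates: per-word (ψ_j, β_j)
given θ, then per-document (α_i, θ_i) given ψ, β, each with per-element
step-halving so every accepted step increases the penalized
log-likelihood (the trace omits the constant Σ log y_ij!). After each
sweep two exact reparametrizations are applied, both leaving every
fitted rate unchanged and neither decreasing the objective: θ is
re-centered (shift absorbed into ψ), and the β/θ scale indeterminacy is
rebalanced by the closed-form c minimizing the total ridge penalty
(β→cβ, θ→θ/c). The rebalancing step matters: without it the alternating
updates crawl along the flat scale direction and convergence stalls.

Identification: after convergence θ is standardized to mean 0, SD 1 once,
with compensating transforms of ψ and β (this is the one step not
measured by the monotone trace, since it re-expresses rather than
improves the fit). The leftover sign is fixed by lexicon anchoring: if
the mean loading over lexicon stems present in the vocabulary is
negative, (θ, β) are jointly negated, so the mind/brain end is positive;
the operation is idempotent and warns when no lexicon stem is in the
vocabulary.

Initialization is deterministic — θ from the first principal component
of the row-standardized log(1+count) matrix, ψ from log mean word
counts, α from log relative document lengths — so fits are reproducible
without random restarts (`seed` only feeds an optional jitter, off by
default). With λ = 0 the fixed point satisfies the unpenalized Poisson
score equations, which the test suite verifies directly.

Documents default to the participant-timepoint unit (the 3 ranked
attributions concatenated): single attributions average ~3 words, too
short to scale reliably, and concatenation triples document length.
Per-attribution documents are supported and the choice is a config
option; which unit the original analyses used is not recoverable, so
the default is documented rather than claimed. Group differences on θ
use Hedges g plus a Wilcoxon rank-sum Z (normal approximation with
midranks, tie-corrected variance, continuity correction). Only the
first latent dimension is estimated; no bootstrap CIs on θ.

## Inferential layer

* **Hedges g**: d = (x̄ − ȳ)/s_pooled, J = 1 − 3/(4·df − 1), g = J·d;
  CI from var(g) = (n1+n2)/(n1·n2) + g²/(2·df). Zero pooled variance
  with equal means gives g = 0; with unequal means the effect is
  infinite and flagged rather than silently truncated.
* **Treatment contrasts** are OLS of the standardized outcome on a 0/1
  arm indicator plus standardized covariates (score-change contrasts
  adjust for the baseline score; pain models adjust for baseline pain
  and condition dummies). The exact model formulas appear in every
  pipeline report because the original covariate sets can only be
  inferred approximately from reported degrees of freedom; transparency
  was preferred over guessed replication.
* **Mediation** standardizes X, M, Y and covariates, estimates a from
  M ~ X + C, b and c′ from Y ~ X + M + C, c from Y ~ X + C, and reports
  indirect = a·b with a percentile bootstrap over participants
  (default 5000 resamples, mandatory seed; replicates with degenerate
  designs — e.g. a single arm drawn — are redrawn, capped at 10·n_boot
  attempts). In this all-linear, same-sample setting indirect = c − c′
  to machine precision, which doubles as an internal consistency check.
  The two-sided p is the bootstrap tail probability
  2·min(P(a·b ≥ 0), P(a·b ≤ 0)). A percentile bootstrap was chosen over
  a structural-equation framework because it is assumption-light and
  produces the asymmetric intervals typical of indirect effects;
  equivalence with any specific published mediation macro is not
  claimed. Missing data are handled by complete-case analysis per model
  (the trial analyses are completer analyses); no imputation, no
  sensitivity analysis for sequential ignorability, and no
  multiple-mediator or mixed-effects extensions.

## Synthetic trial generator

The generator emulates the *statistical structure* the analyses assume,
with every parameter inspectable ground truth. Defaults are set to the
trial's reported marginals: 3 arms (default 50/arm ≈ the 151-participant
trial), baseline pain ~ Normal(4.10, 1.26) truncated to [0,10] (the
0–10 rating-scale bounds), attributions of 1–10 words with mean ≈ 3.1,
baseline category probabilities matching reported pretreatment
prevalences (activity .25, injury .19, physiological .16, stress .07,
psychological .022, brain .002, remainder spread over the unreported
categories), and ~11% missing-completely-at-random dropout at post and
follow-up (completion was reported without a missingness mechanism, so
MCAR is the neutral choice; informative dropout is out of scope).

Reattribution mechanism: pre-treatment (and control post-treatment)
categories draw i.i.d. from the baseline distribution; each treated
post-treatment attribution is instead drawn from a uniformly chosen
mind/brain category with probability `mindbrain_shift_prt` (default 0.46,
which puts ~51% of treated post attributions in mind/brain categories).
The implied treatment effect on the score change is a = 3·shift·(1−p_mb);
because `a_true` and the shift are algebraically the same knob, the
config accepts either and verifies consistency if both are given, rather
than pretending they are independent parameters.

Texts are drawn from per-category pools of 8–15 diagnostic words (seeded
by canonical category exemplars: "scoliosis", "neural pathways",
"stressful job", …) mixed with shared filler vocabulary; every text
contains at least one category-diagnostic token. The pools are built so
the default lexicon separates mind/brain from other categories *except*
for "childhood" in the injury pool — the engineered ambiguity that makes
the automated scorer's documented false-positive behavior reproducible
on synthetic data.

Pain outcomes follow pain_t = pain_pre + direct·1{PRT} + b·Δscore +
noise, truncated to [0,10], at both post and 1-year (defaults
b = −0.8 pain units per score unit, direct = −1.0, noise SD 1.5); a·b is
the built-in indirect effect that the mediation machinery must recover.
A single integer seed drives one named random stream, so generation is
bit-reproducible. Questionnaire item-level responses are not simulated
(TSK/PCS/SOPA enter the schema only as optional participant-level
totals).

What passing tests on this generator do **not** show: real attributions
are messier — misspellings, multi-concept sentences, vocabulary the
lexicon has never seen — so agreement statistics on synthetic data are
optimistic upper bounds (synthetic κ between the automated and human
scorer is far higher than would be seen with real coders), and the MCAR
dropout cannot reveal bias that informative missingness would cause.
The generator validates the *machinery* (estimators, identification,
directionality, coverage), not the field performance of the lexicon.

## Problem sizes used in the checks

The test suite fixes its simulation scales as package policy: scaling
recovery uses 20 corpora of 100 documents × 50 words drawn from the
scaling model itself (expecting |cor(θ̂, θ*)| > 0.9 in ≥ 18/20);
bootstrap coverage of the null indirect effect uses 200 replicates of
100 participants/arm with 500 resamples each (accepting 90–99%
coverage); end-to-end directionality uses 20 trials of 200/arm with a
0.5 reattribution shift. Oracle-equivalence checks (κ variances, Hedges
g, Pearson r, OLS contrasts, rank-sum) run on instances of ≤ 10 rows
against brute-force normal equations, covariance formulas and exact
enumeration.

## Known limitations

* The stemmer is a from-scratch implementation of the Porter2 rule set,
  validated against hand-traced vectors; exotic words may stem
  differently than other implementations, which changes nothing
  downstream as long as the package's own convention is applied
  consistently (it is, everywhere).
* The default lexicon is a stand-in, not the unpublished expert list;
  absolute agreement values on real data will differ.
* The scaling model estimates one dimension; multi-dimensional
  structure, and uncertainty on θ, are future work.
* Mediation assumes linearity and no unmeasured confounding of the
  mediator-outcome path; no sensitivity bounds are computed.
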
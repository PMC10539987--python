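# painattrib

Natural-language analysis of patients' free-text **pain attributions** —
the causes people name, in their own words, for their chronic pain.

In chronic back pain, the belief that pain signals ongoing tissue damage
is often inaccurate: much chronic pain is *primary* (nociplastic),
driven by central nervous-system processes rather than peripheral
pathology. Psychological treatments that reframe pain as a reversible
mind/brain process aim to *reattribute* it — and the degree of
reattribution can be measured directly from short free-text responses
("please list in rank-order the 3 most important factors that you
believe caused your pain"). This package implements that measurement
pipeline for a three-arm randomized trial design (treatment, open-label
placebo, usual care), for biostatisticians and clinical researchers who
want every step reproducible and testable:

1. **Human coding** — an 11-category codebook; per-participant
   *mind-brain attribution scores* (0–3: how many of the 3 attributions
   fall in the stress / psychological / brain categories); prevalence
   tables; inter-coder agreement via Cohen's
   κ = (p_o − p_e)/(1 − p_e) with asymptotic CI and Z test.
2. **Automated lexicon scoring** — an expert word list is stemmed into a
   lexicon; an attribution is flagged iff it contains a lexicon stem;
   flags sum to an automated 0–3 score that is benchmarked against human
   scores (κ, confusion matrix, over/under-flagging asymmetry).
3. **Word-frequency change** — per-stem rates per 100 attributions, pre
   vs post, with novel-vocabulary flags.
4. **Text scaling** — a from-scratch regularized Poisson scaling model
   (Wordfish family): counts y_ij ~ Poisson(exp(α_i + ψ_j + β_j·θ_i)),
   with ridge penalties λ_β‖β‖² and λ_θ‖θ‖² for stability on very short
   documents. θ_i is document *i*'s position on the latent semantic
   dimension, β_j word *j*'s loading; the dimension is sign-anchored so
   the mind/brain end is positive.
5. **Inference** — Hedges g (small-sample-corrected standardized mean
   difference), ANCOVA-style standardized treatment contrasts, score ↔
   pain associations, and longitudinal mediation
   (a = X→ΔM, b = ΔM→Y | X; indirect = a·b with percentile-bootstrap CI).
6. **Synthetic trial generator** — category-structured ~3-word
   attribution texts, arm-dependent reattribution, and pain outcomes
   with a *known* mediated treatment effect, so the whole pipeline is
   verifiable against ground truth without any patient data.

## Worked example

```python
import painattrib as pa

dataset, truth = pa.generate_trial(pa.SimulationConfig(n_per_arm=50, seed=7))

consensus, _ = pa.consensus_assignments(pa.truth_to_codings(truth),
                                        require_two_coders=False)
scores = pa.mind_brain_score(consensus)
wide = scores.pivot(index="participant_id", columns="timepoint", values="score")
data = dataset.participants.merge(wide, on="participant_id")
data["delta_score"] = data["post"] - data["pre"]
data["prt"] = (data["arm"] == "prt").astype(float)

med = pa.mediate(data, x="prt", m="delta_score", y="pain_1yr",
                 covariates=["pain_pre"], n_boot=5000, seed=7)
print(med.a, med.b, med.indirect, med.boot_ci_low, med.boot_ci_high)
```

Running `python examples/06_mediation.py` (the same analysis) prints:

```
complete cases: 120
a  (PRT -> delta score)          = +0.582
b  (delta score -> 1-yr pain)    = -0.212
c  (total PRT effect)            = -0.456
c' (direct effect)               = -0.333
indirect a*b = -0.123 [-0.205, -0.042], p = 0.002
```

All paths are in SD units. The positive `a` says treated participants
shifted toward mind/brain attributions; the negative `b` says larger
shifts predict lower 1-year pain given treatment; their product — with a
bootstrap CI excluding zero — is the mediated part of the treatment
effect, and it equals `c − c'` exactly because all models are linear and
fit on the same sample. The other `examples/` scripts walk through
simulation, human coding, lexicon scoring (including its documented
"childhood injury" false positive), word-frequency deltas, and text
scaling, one capability each.

There is also a thin CLI mirroring the stages:

```bash
painattrib simulate --n-per-arm 50 --seed 7 --out sim/
painattrib run --seed 7 --out run/     # simulate -> code -> autoscore ->
                                       # wordfreq -> scale -> analyze
```

## Layout

```
src/painattrib/    library (corpus, coding, lexicon, wordfreq, scaling,
                   inference, synthetic, pipeline, cli)
examples/          one narrative script per capability
tests/             pytest suite incl. end-to-end acceptance checks
docs/methods.md    models, assumptions, defaults, limitations
```
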
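"""Automated lexicon scoring and its benchmark against human coding.

The word-counting algorithm flags an attribution as mind/brain-related if
any stem matches the expert lexicon; a participant's automated score is
the count over their 3 attributions.  The example also shows the
documented failure mode: "childhood injury" flags because of the word
"childhood", though a human codes it as injury.
"""

import painattrib as pa

lexicon = pa.default_lexicon()
print(f"lexicon: {len(lexicon.raw_terms)} raw terms -> {len(lexicon.stems)} stems")

for text in ("Neural pathways", "Stress", "Degenerative processes", "childhood injury"):
    flag = pa.score_attribution(text, lexicon)
    print(f"  {text!r:<28} -> {flag}")
print('note the false positive on "childhood injury" (human category: injury)')

dataset, truth = pa.generate_trial(pa.SimulationConfig(n_per_arm=50, seed=7))
auto = pa.autoscore_table(dataset.attributions, lexicon)
consensus, _ = pa.consensus_assignments(pa.truth_to_codings(truth),
                                        require_two_coders=False)
human = pa.mind_brain_score(consensus)

for tp in ("pre", "post"):
    bench = pa.benchmark_against_human(auto, human, timepoint=tp)
    print(f"\n{tp}: kappa = {bench.kappa.kappa:.2f} "
          f"[{bench.kappa.ci_low:.2f}, {bench.kappa.ci_high:.2f}] on n={bench.n}")
    print(f"  algorithm scored higher than humans {bench.auto_higher}x, "
          f"lower {bench.human_higher}x")
print("\nthe asymmetry (auto-higher >> human-higher) is the lexicon over-")
print("flagging ambiguous words, exactly the behaviour seen with real coders")
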
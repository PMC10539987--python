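"""Which words change most from pre to post within the treated arm?

Counts are normalized per 100 attributions so pre/post are comparable
despite dropout; 'novel' marks vocabulary absent before treatment.
"""

import painattrib as pa

dataset, _ = pa.generate_trial(pa.SimulationConfig(n_per_arm=50, seed=7))
docs = pa.tokenize_attributions(dataset.attributions, "attribution",
                                dataset.participants)
dtm = pa.build_dtm(docs)
deltas = pa.frequency_change(dtm, "prt")

print("largest pre-to-post frequency changes in the PRT arm")
print(f"(rates per 100 attributions; pre n={deltas.attrs['n_attributions_pre']}, "
      f"post n={deltas.attrs['n_attributions_post']})\n")
print(f"{'stem':<12}{'pre':>7}{'post':>7}{'delta':>8}  novel")
for row in deltas.head(10).itertuples(index=False):
    print(f"{row.stem:<12}{row.rate_pre:>7.1f}{row.rate_post:>7.1f}"
          f"{row.delta:>+8.1f}  {'yes' if row.novel else ''}")
print("\npositive deltas are words patients adopt after treatment (emotion")
print("and brain vocabulary); negative deltas are biomechanical words they drop.")
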
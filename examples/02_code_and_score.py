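"""Human-coder workflow: consensus, mind-brain scores, prevalence, agreement.

Uses the generator's true categories as two simulated coders, engineers a
few disagreements, and walks through consensus coding to per-participant
mind-brain attribution scores (0-3).
"""

import painattrib as pa

dataset, truth = pa.generate_trial(pa.SimulationConfig(n_per_arm=50, seed=7))

codings = pa.truth_to_codings(truth)
# make coder2 disagree on a handful of attributions
flip = codings[codings.coder_id == "coder2"].index[:12]
codings.loc[flip, "category"] = "injury"

n_dis, n_attr, pct = pa.disagreement_rate(codings)
print(f"coded attributions: {n_attr}, disagreements: {n_dis} ({pct}%)")

resolutions = truth.categories  # settle by taking the true category
consensus, disagreements = pa.consensus_assignments(codings, resolutions=resolutions)
scores = pa.mind_brain_score(consensus)
pre = scores[scores.timepoint == "pre"]["score"]
print(f"baseline mind-brain score: mean {pre.mean():.2f}, median {pre.median():.0f}")
print("(a mean far below 1 means patients rarely blame mind or brain at baseline)")

prev = pa.prevalence_table(consensus, group_by=["timepoint"])
top = prev[prev.timepoint == "pre"].nlargest(3, "count")
print("\nmost prevalent baseline categories:")
for row in top.itertuples(index=False):
    print(f"  {row.category:<15} {row.count:>3} attributions ({row.percent:g}%)")

kappa = pa.cohen_kappa(
    codings[codings.coder_id == "coder1"].sort_values(["participant_id", "timepoint", "rank"])["category"],
    codings[codings.coder_id == "coder2"].sort_values(["participant_id", "timepoint", "rank"])["category"],
)
print(f"\ninter-coder agreement: kappa = {kappa.kappa:.2f} "
      f"[{kappa.ci_low:.2f}, {kappa.ci_high:.2f}], Z = {kappa.z:.2f}")
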
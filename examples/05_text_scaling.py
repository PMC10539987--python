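"""Unsupervised text scaling of attribution documents.

Fits the regularized Poisson scaling model
    y_ij ~ Poisson(exp(alpha_i + psi_j + beta_j * theta_i))
to participant-timepoint documents, orients the latent dimension so the
mind/brain end is positive, and tests the posttreatment group difference.
"""

import numpy as np

import painattrib as pa

dataset, _ = pa.generate_trial(pa.SimulationConfig(n_per_arm=50, seed=7))
docs = pa.tokenize_attributions(dataset.attributions, "participant_timepoint",
                                dataset.participants)
dtm = pa.build_dtm(docs, min_doc_freq=2)

fit = pa.fit_scaling(dtm, lambda_beta=0.1, lambda_theta=0.1)
fit = pa.orient_dimension(fit, pa.default_lexicon())
print(f"converged={fit.converged} after {fit.n_iter} sweeps; "
      f"{len(fit.doc_ids)} docs x {len(fit.vocab)} stems")

loadings = fit.loading_table().sort_values("beta")
print("\nmost negative loadings (biomechanical end):",
      ", ".join(loadings.head(5)["stem"]))
print("most positive loadings (mind/brain end):   ",
      ", ".join(loadings.tail(5)["stem"]))

pos = fit.position_table().merge(dtm.meta, on="doc_id")
post = pos[pos.timepoint == "post"]
for other in ("placebo", "usual_care"):
    diff = pa.position_group_difference(
        post.loc[post.arm == "prt", "theta"],
        post.loc[post.arm == other, "theta"],
    )
    print(f"\nposttreatment PRT vs {other}: g = {diff.effect.g:.2f} "
          f"[{diff.effect.ci_low:.2f}, {diff.effect.ci_high:.2f}], "
          f"Z = {diff.z:.2f}, p = {diff.p:.2g}")
print("\npositive g: treated participants sit toward the mind/brain end of")
print("the data-driven semantic dimension, without any use of the codebook.")
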
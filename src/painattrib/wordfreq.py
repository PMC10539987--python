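"""Pre-to-post word-frequency change within a treatment condition.

Counts are normalized per 100 attributions at each timepoint (pre and
post attribution totals differ with dropout), the delta is the post rate
minus the pre rate, and words absent before treatment but present after
are flagged as novel vocabulary.  No per-word significance testing is
done; the output is a ranked descriptive table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .corpus import DocumentTermMatrix


def frequency_change(
    dtm: DocumentTermMatrix,
    condition: str,
    pre: str = "pre",
    post: str = "post",
) -> pd.DataFrame:
    """Ranked per-stem frequency deltas for one condition.

    Returns a table with raw token counts, document frequencies, rates
    per 100 attributions, ``delta`` (post − pre rate) and a ``novel``
    flag, sorted by |delta| descending with lexicographic tie-break.
    """
    meta = dtm.meta
    if condition not in set(meta["arm"].dropna()):
        raise ValueError(f"condition {condition!r} not present in the DTM metadata")
    in_cond = (meta["arm"] == condition).to_numpy()
    masks = {}
    for tp in (pre, post):
        m = in_cond & (meta["timepoint"] == tp).to_numpy()
        if not m.any():
            raise ValueError(f"no documents for condition {condition!r} at timepoint {tp!r}")
        masks[tp] = m

    out = {"stem": np.asarray(dtm.vocab)}
    n_attr = {}
    for tp, label in ((pre, "pre"), (post, "post")):
        sub = dtm.counts[masks[tp]]
        counts = np.asarray(sub.sum(axis=0)).ravel()
        docfreq = np.asarray((sub > 0).sum(axis=0)).ravel()
        n_attr[label] = int(meta.loc[masks[tp], "n_attributions"].sum())
        out[f"count_{label}"] = counts
        out[f"docfreq_{label}"] = docfreq
        out[f"rate_{label}"] = 100.0 * counts / n_attr[label]

    df = pd.DataFrame(out)
    df["delta"] = df["rate_post"] - df["rate_pre"]
    df["novel"] = (df["count_pre"] == 0) & (df["count_post"] > 0)
    df = df.sort_values(
        ["delta", "stem"],
        key=lambda s: -s.abs() if s.name == "delta" else s,
    ).reset_index(drop=True)
    df.attrs["n_attributions_pre"] = n_attr["pre"]
    df.attrs["n_attributions_post"] = n_attr["post"]
    return df
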
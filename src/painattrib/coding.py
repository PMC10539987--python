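"""Human-coder categorization: consensus, mind-brain scores, prevalence,
and inter-rater agreement.

Two masked coders assign each attribution one codebook category; codes
that agree pass straight to consensus, disagreements are surfaced for
external resolution (discussion), and a participant's mind-brain
attribution score at a timepoint is the count (0-3) of their attributions
falling in the stress / psychological / brain categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.inter_rater import cohens_kappa as _sm_cohens_kappa

from .codebook import Codebook, DEFAULT_CODEBOOK

_KEY = ["participant_id", "timepoint", "rank"]


def consensus_assignments(
    codings: pd.DataFrame,
    resolutions: pd.DataFrame | None = None,
    require_two_coders: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge per-coder category assignments into a consensus table.

    ``codings`` has columns participant_id, timepoint, rank, coder_id,
    category.  Unanimous attributions pass through; disagreements are
    returned separately and may be settled by ``resolutions`` (same key
    columns plus a ``category`` column).  Unresolved disagreements appear
    in the consensus table with a null category, which downstream scoring
    refuses to work around.

    Returns ``(consensus, disagreements)``; ``disagreements`` lists every
    attribution the coders split on (including later-resolved ones) with
    one column per coder.
    """
    required = set(_KEY + ["coder_id", "category"])
    missing = required - set(codings.columns)
    if missing:
        raise ValueError(f"codings table missing columns: {sorted(missing)}")
    if codings.duplicated(_KEY + ["coder_id"]).any():
        raise ValueError("duplicate (participant, timepoint, rank, coder) codings")

    n_coders = codings.groupby(_KEY, sort=False)["coder_id"].nunique()
    if require_two_coders:
        n_single = int((n_coders < 2).sum())
        if n_single:
            warnings.warn(
                f"{n_single} attribution(s) coded by a single coder; "
                "their code is taken as consensus",
                stacklevel=2,
            )

    res_map: dict[tuple, str] = {}
    if resolutions is not None:
        res_map = {
            tuple(getattr(r, c) for c in _KEY): r.category
            for r in resolutions.itertuples(index=False)
        }

    consensus_rows, disagreement_rows = [], []
    for key, grp in codings.groupby(_KEY, sort=False):
        cats = grp["category"].unique()
        if len(cats) == 1:
            consensus_rows.append((*key, cats[0]))
        else:
            row = dict(zip(_KEY, key))
            for r in grp.itertuples(index=False):
                row[f"coder_{r.coder_id}"] = r.category
            disagreement_rows.append(row)
            consensus_rows.append((*key, res_map.get(tuple(key))))

    consensus = pd.DataFrame(consensus_rows, columns=_KEY + ["category"])
    disagreements = pd.DataFrame(disagreement_rows)
    return consensus, disagreements


def disagreement_rate(codings: pd.DataFrame) -> tuple[int, int, float]:
    """(n_disagreements, n_attributions, percent) across a codings table."""
    _, disagreements = consensus_assignments(codings, require_two_coders=False)
    n_attr = codings.groupby(_KEY, sort=False).ngroups
    n_dis = len(disagreements)
    return n_dis, n_attr, round_percent(100.0 * n_dis / n_attr)


def mind_brain_score(
    consensus: pd.DataFrame, codebook: Codebook = DEFAULT_CODEBOOK
) -> pd.DataFrame:
    """Per participant × timepoint count of mind/brain-coded attributions.

    Raises if any participant-timepoint carries more than 3 attributions
    or an unresolved (null) consensus category.
    """
    if consensus["category"].isna().any():
        n = int(consensus["category"].isna().sum())
        raise ValueError(
            f"{n} attribution(s) have unresolved consensus; resolve disagreements "
            "before computing mind-brain scores"
        )
    bad = set(consensus["category"]) - set(codebook.categories)
    if bad:
        raise ValueError(f"categories outside the codebook: {sorted(bad)}")

    sizes = consensus.groupby(["participant_id", "timepoint"], sort=False).size()
    if (sizes > 3).any():
        offender = sizes[sizes > 3].index[0]
        raise ValueError(f"more than 3 attributions for participant-timepoint {offender}")

    flagged = consensus.assign(
        is_mindbrain=consensus["category"].isin(codebook.mindbrain_subset)
    )
    out = (
        flagged.groupby(["participant_id", "timepoint"], sort=False)
        .agg(score=("is_mindbrain", "sum"), n_attributions_scored=("is_mindbrain", "size"))
        .reset_index()
    )
    out["score"] = out["score"].astype(int)
    return out


def round_percent(pct: float) -> float:
    """Printing convention for prevalence percents.

    Round half away from zero to the nearest integer percent; below 1%
    keep one decimal (so 1/453 prints as 0.2, not 0).
    """
    if abs(pct) < 1.0:
        return float(np.floor(abs(pct) * 10 + 0.5) / 10 * np.sign(pct))
    return float(np.floor(abs(pct) + 0.5) * np.sign(pct))


def prevalence_table(
    consensus: pd.DataFrame,
    codebook: Codebook = DEFAULT_CODEBOOK,
    group_by: list[str] | None = None,
    participants: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Category counts and percents of attributions, overall or by group.

    Percents are over attributions in the group (each participant
    contributes up to 3); the ``percent`` column follows the integer /
    one-decimal printing convention, ``percent_exact`` keeps full
    precision.  Empty groups yield zero counts with null percents.
    """
    df = consensus.dropna(subset=["category"]).copy()
    if participants is not None and "arm" not in df.columns:
        df = df.merge(
            participants[["participant_id", "arm"]], on="participant_id", how="left"
        )
    group_by = group_by or []
    for col in group_by:
        if col not in df.columns:
            raise ValueError(f"grouping column {col!r} not available")

    def _table(sub: pd.DataFrame) -> pd.DataFrame:
        total = len(sub)
        counts = sub["category"].value_counts()
        rows = []
        for cat in codebook.categories:
            c = int(counts.get(cat, 0))
            exact = 100.0 * c / total if total else np.nan
            rows.append(
                {
                    "category": cat,
                    "count": c,
                    "n_attributions": total,
                    "percent_exact": exact,
                    "percent": round_percent(exact) if total else np.nan,
                }
            )
        return pd.DataFrame(rows)

    if not group_by:
        return _table(df)
    pieces = []
    for key, sub in df.groupby(group_by, sort=True):
        tab = _table(sub)
        key = key if isinstance(key, tuple) else (key,)
        for col, val in zip(group_by, key):
            tab.insert(0, col, val)
        pieces.append(tab)
    return pd.concat(pieces, ignore_index=True)


@dataclass(frozen=True)
class KappaResult:
    """Cohen's κ with its asymptotic precision.

    ``se`` is the Fleiss-Cohen-Everitt large-sample standard error used
    for the confidence interval; ``se0`` is the standard error under the
    independence null used for the Z test.
    """

    kappa: float
    se: float
    se0: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    n: int
    table: np.ndarray
    levels: tuple

    def to_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "z": self.z,
            "p": self.p,
            "n": self.n,
        }


def cohen_kappa(labels_a, labels_b, levels=None, weights: str | None = None) -> KappaResult:
    """Chance-corrected agreement between two raters.

    κ = (p_o − p_e)/(1 − p_e) with p_e from the product of marginals;
    the 95% CI is κ ± 1.96·SE with the standard asymptotic SE, and Z
    tests κ = 0 using the null-hypothesis SE.  ``levels`` fixes the
    category set (useful when some levels are unobserved); ``weights``
    may be ``"linear"`` or ``"quadratic"`` for ordinal scores, default
    unweighted (nominal).
    """
    a = pd.Series(list(labels_a))
    b = pd.Series(list(labels_b))
    if len(a) != len(b):
        raise ValueError("label vectors must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 paired labels")
    if levels is None:
        levels = sorted(set(a) | set(b))
    levels = list(levels)
    unknown = (set(a) | set(b)) - set(levels)
    if unknown:
        raise ValueError(f"labels outside the provided levels: {sorted(unknown)}")

    idx = {lv: i for i, lv in enumerate(levels)}
    k = len(levels)
    table = np.zeros((k, k), dtype=np.int64)
    for x, y in zip(a, b):
        table[idx[x], idx[y]] += 1
    n = int(table.sum())

    p = table / n
    p_e = float(p.sum(axis=1) @ p.sum(axis=0))
    if weights is None and p_e >= 1.0 - 1e-12:
        raise ValueError(
            "kappa undefined: both raters are constant and identical (p_e = 1)"
        )

    wt = {None: None, "linear": "linear", "quadratic": "quadratic"}[weights]
    res = _sm_cohens_kappa(table, wt=wt, return_results=True)
    kappa = float(res.kappa)
    se = float(np.sqrt(res.var_kappa))
    se0 = float(np.sqrt(res.var_kappa0))
    z = kappa / se0 if se0 > 0 else np.nan
    pval = float(2 * scipy.stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
    return KappaResult(
        kappa=kappa,
        se=se,
        se0=se0,
        ci_low=kappa - 1.96 * se,
        ci_high=kappa + 1.96 * se,
        z=z,
        p=pval,
        n=n,
        table=table,
        levels=tuple(levels),
    )
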
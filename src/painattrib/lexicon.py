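"""Automated mind-brain attribution scoring by expert-lexicon word counting.

An expert-derived list of mind/brain-related words is preprocessed into a
stem set; an attribution is flagged (1) when any of its stems is in the
set, and a participant's automated score at a timepoint is the sum of
flags over their up-to-3 attributions.  The default lexicon shipped here
is a documented stand-in built from clinically plausible terms — stress
and emotion words, psychological-trait words, neurobiological words —
and deliberately includes developmental-history terms such as
"childhood", which produces the algorithm's characteristic false
positive: "childhood injury" is flagged as mind/brain even though a
human coder files it under injury.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .coding import KappaResult, cohen_kappa
from .corpus import preprocess

DEFAULT_LEXICON_TERMS: tuple[str, ...] = (
    # stress and strain of daily life
    "stress", "stressful", "stressed", "tension", "pressure", "overwhelm",
    "overwhelmed", "workload", "deadlines", "burnout",
    # emotions and affect
    "anxiety", "anxious", "fear", "fearful", "worry", "worrying", "emotion",
    "emotions", "emotional", "feeling", "feelings", "depression", "depressed",
    "anger", "angry", "guilt", "shame", "grief", "sadness", "mood",
    # psychological traits and history
    "mind", "mental", "psychological", "psychosomatic", "personality",
    "perfectionism", "catastrophizing", "rumination", "trauma", "traumatic",
    "childhood", "upbringing", "outlook",
    # brain and nervous-system processes
    "brain", "neural", "neurons", "pathway", "pathways", "nervous",
    "sensitization", "sensitized", "amygdala", "cortex", "neuroplasticity",
    "plasticity", "learned", "memory", "alarm", "signals", "signaling",
    "overactive", "oversensitive", "hypervigilance", "wiring",
)


@dataclass(frozen=True)
class Lexicon:
    """An expert term list reduced to a deduplicated stem set."""

    raw_terms: tuple[str, ...]
    stems: frozenset[str]
    source: str = "unspecified"

    def __contains__(self, stem: str) -> bool:
        return stem in self.stems

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"source": self.source, "raw_terms": list(self.raw_terms)}, indent=2)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "Lexicon":
        obj = json.loads(Path(path).read_text())
        return compile_lexicon(obj["raw_terms"], source=obj.get("source", str(path)))


def compile_lexicon(raw_terms: Iterable[str], source: str = "unspecified") -> Lexicon:
    """Preprocess raw expert terms and pool the resulting stems.

    Terms sharing a stem collapse ("stress"/"stressful" → one entry);
    terms that vanish under preprocessing contribute nothing, and a term
    list that vanishes entirely is an error.
    """
    raw = tuple(raw_terms)
    if not raw:
        raise ValueError("empty lexicon term list")
    stems: set[str] = set()
    for term in raw:
        stems.update(preprocess(term))
    if not stems:
        raise ValueError("all lexicon terms reduce to stopwords or empty strings")
    return Lexicon(raw_terms=raw, stems=frozenset(stems), source=source)


def default_lexicon() -> Lexicon:
    return compile_lexicon(DEFAULT_LEXICON_TERMS, source="painattrib default expert stand-in")


def score_attribution(text: str, lexicon: Lexicon) -> int:
    """1 if any stem of the attribution is in the lexicon, else 0."""
    return int(any(s in lexicon.stems for s in preprocess(text)))


def automated_mind_brain_score(texts: Sequence[str], lexicon: Lexicon) -> int:
    """Sum of per-attribution flags for one participant-timepoint (0-3).

    An empty attribution set is a missing observation, not a zero;
    callers must not pass it (they should propagate missingness instead).
    """
    if len(texts) == 0:
        raise ValueError("no attributions: automated score is missing, not 0")
    if len(texts) > 3:
        raise ValueError(f"more than 3 attributions ({len(texts)}) for one timepoint")
    return sum(score_attribution(t, lexicon) for t in texts)


def autoscore_table(attributions: pd.DataFrame, lexicon: Lexicon) -> pd.DataFrame:
    """Automated scores for every participant-timepoint in a long table.

    Returns one row per participant × timepoint with the 0-3 score and
    the number of attributions it is based on.
    """
    rows = []
    for (pid, tp), grp in attributions.groupby(["participant_id", "timepoint"], sort=False):
        rows.append(
            {
                "participant_id": pid,
                "timepoint": tp,
                "auto_score": automated_mind_brain_score(list(grp["text"]), lexicon),
                "n_attributions_scored": len(grp),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BenchmarkResult:
    """Agreement between automated and human-coded scores at one timepoint."""

    kappa: KappaResult
    confusion: np.ndarray  # rows: human score 0-3, cols: auto score 0-3
    n: int
    auto_higher: int
    human_higher: int

    def to_dict(self) -> dict:
        return {
            **self.kappa.to_dict(),
            "confusion": self.confusion.tolist(),
            "auto_higher": self.auto_higher,
            "human_higher": self.human_higher,
        }


def benchmark_against_human(
    auto_scores: pd.DataFrame,
    human_scores: pd.DataFrame,
    timepoint: str | None = None,
    weights: str | None = None,
) -> BenchmarkResult:
    """Cohen κ of automated vs human mind-brain scores on shared participants.

    Scores 0-3 are treated as nominal levels (unweighted κ) by default.
    The confusion matrix is human (rows) × automated (columns); the
    off-diagonal asymmetry summary counts participant-timepoints where
    the algorithm scored higher than the human coders and vice versa.
    """
    a = auto_scores if timepoint is None else auto_scores[auto_scores["timepoint"] == timepoint]
    h = human_scores if timepoint is None else human_scores[human_scores["timepoint"] == timepoint]
    merged = a.merge(h, on=["participant_id", "timepoint"], suffixes=("_auto", "_human"))
    if merged.empty:
        raise ValueError("no overlapping participant-timepoints between auto and human scores")
    auto = merged["auto_score"].to_numpy()
    human = merged["score"].to_numpy()
    kres = cohen_kappa(human, auto, levels=[0, 1, 2, 3], weights=weights)
    confusion = kres.table
    return BenchmarkResult(
        kappa=kres,
        confusion=confusion,
        n=len(merged),
        auto_higher=int(np.triu(confusion, k=1).sum()),
        human_higher=int(np.tril(confusion, k=-1).sum()),
    )
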
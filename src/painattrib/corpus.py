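"""Shared text preprocessing and document-term matrix construction.

All text entering the package — free-text pain attributions, expert
lexicon terms — passes through :func:`preprocess`, which applies one
frozen convention: lowercasing, splitting on non-alphabetic characters
(so slashed and hyphenated compounds like "work/lifestyle" or
"8-14 h/day" separate, and numerals drop out), stopword removal, and
English (Porter2) stemming.  Stemming is applied to a fixed point, which
makes ``preprocess`` idempotent on its own output.

Documents can be built per attribution or per participant-timepoint
(the three ranked attributions concatenated); the latter is the default
unit for text scaling because single attributions average only ~3 words.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .stemming import stem
from .stopwords import ENGLISH_STOPWORDS

_TOKEN_SPLIT = re.compile(r"[^a-z]+")

DocUnit = Literal["attribution", "participant_timepoint"]


@dataclass(frozen=True)
class TokenizedDoc:
    """An identified document reduced to an ordered list of stems."""

    doc_id: str
    stems: tuple[str, ...]
    meta: dict = field(default_factory=dict, compare=False)


def _stem_fixpoint(token: str, max_rounds: int = 5) -> str:
    for _ in range(max_rounds):
        out = stem(token)
        if out == token:
            break
        token = out
    return token


def preprocess(text: str) -> list[str]:
    """Normalize raw text into an ordered list of stems.

    Lowercase, split on any non-alphabetic character, drop stopwords
    (both surface forms and resulting stems), stem.  Empty or
    non-substantive input (e.g. ``"???"``) yields an empty list.
    """
    if not isinstance(text, str):
        return []
    stems = []
    for token in _TOKEN_SPLIT.split(text.lower()):
        if len(token) < 2 or token in ENGLISH_STOPWORDS:
            continue
        s = _stem_fixpoint(token)
        if s and s not in ENGLISH_STOPWORDS:
            stems.append(s)
    return stems


def tokenize_attributions(
    attributions: pd.DataFrame,
    doc_unit: DocUnit = "participant_timepoint",
    participants: pd.DataFrame | None = None,
) -> list[TokenizedDoc]:
    """Build tokenized documents from a long attribution table.

    ``attributions`` needs columns participant_id, timepoint, rank, text.
    With ``doc_unit="participant_timepoint"`` the 3 ranked attributions of
    one participant at one timepoint form a single document (ranks
    concatenated in rank order); with ``"attribution"`` each row is its
    own document.  Arm labels are attached from ``participants`` when
    given; every document records how many attributions it covers, which
    downstream rate normalizations rely on.
    """
    arm_of = {}
    if participants is not None:
        arm_of = dict(zip(participants["participant_id"], participants["arm"]))

    docs: list[TokenizedDoc] = []
    if doc_unit == "attribution":
        for row in attributions.itertuples(index=False):
            docs.append(
                TokenizedDoc(
                    doc_id=f"{row.participant_id}|{row.timepoint}|{row.rank}",
                    stems=tuple(preprocess(row.text)),
                    meta={
                        "participant_id": row.participant_id,
                        "timepoint": row.timepoint,
                        "arm": arm_of.get(row.participant_id),
                        "n_attributions": 1,
                    },
                )
            )
    elif doc_unit == "participant_timepoint":
        grouped = attributions.sort_values("rank").groupby(
            ["participant_id", "timepoint"], sort=False
        )
        for (pid, tp), grp in grouped:
            stems: list[str] = []
            for text in grp["text"]:
                stems.extend(preprocess(text))
            docs.append(
                TokenizedDoc(
                    doc_id=f"{pid}|{tp}",
                    stems=tuple(stems),
                    meta={
                        "participant_id": pid,
                        "timepoint": tp,
                        "arm": arm_of.get(pid),
                        "n_attributions": int(len(grp)),
                    },
                )
            )
    else:  # pragma: no cover - guarded by Literal type
        raise ValueError(f"unknown doc_unit: {doc_unit!r}")
    return docs


@dataclass
class DocumentTermMatrix:
    """Docs × vocabulary count matrix with per-document metadata.

    ``counts`` is a CSR sparse integer matrix; ``meta`` is indexed like
    ``doc_ids`` and carries participant_id / arm / timepoint /
    n_attributions where known.  ``dropped_doc_ids`` lists documents
    removed because vocabulary filtering emptied them.
    """

    doc_ids: list[str]
    vocab: list[str]
    counts: sp.csr_matrix
    meta: pd.DataFrame
    min_doc_freq: int = 1
    dropped_doc_ids: list[str] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def doc_lengths(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def subset_docs(self, mask: np.ndarray) -> "DocumentTermMatrix":
        idx = np.flatnonzero(np.asarray(mask))
        return DocumentTermMatrix(
            doc_ids=[self.doc_ids[i] for i in idx],
            vocab=list(self.vocab),
            counts=self.counts[idx],
            meta=self.meta.iloc[idx].reset_index(drop=True),
            min_doc_freq=self.min_doc_freq,
        )


def build_dtm(docs: Sequence[TokenizedDoc], min_doc_freq: int = 1) -> DocumentTermMatrix:
    """Assemble a document-term matrix from tokenized documents.

    The vocabulary is every stem occurring in at least ``min_doc_freq``
    documents, in lexicographic order; documents keep their input order.
    Documents emptied by the frequency filter (or empty to begin with)
    are dropped and reported on the returned matrix.
    """
    if len(docs) < 2:
        raise ValueError("need at least 2 documents to build a document-term matrix")
    if min_doc_freq < 1:
        raise ValueError("min_doc_freq must be >= 1")

    docfreq: dict[str, int] = {}
    for doc in docs:
        for s in set(doc.stems):
            docfreq[s] = docfreq.get(s, 0) + 1
    vocab = sorted(s for s, df in docfreq.items() if df >= min_doc_freq)
    if not vocab:
        raise ValueError(
            f"no stem occurs in at least min_doc_freq={min_doc_freq} documents"
        )
    col = {s: j for j, s in enumerate(vocab)}

    rows, cols, vals = [], [], []
    kept: list[TokenizedDoc] = []
    dropped: list[str] = []
    for doc in docs:
        counts: dict[int, int] = {}
        for s in doc.stems:
            j = col.get(s)
            if j is not None:
                counts[j] = counts.get(j, 0) + 1
        if not counts:
            dropped.append(doc.doc_id)
            continue
        i = len(kept)
        kept.append(doc)
        for j, c in counts.items():
            rows.append(i)
            cols.append(j)
            vals.append(c)

    if not kept:
        raise ValueError(
            f"all documents are empty after filtering at min_doc_freq={min_doc_freq}"
        )
    counts_mat = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(kept), len(vocab)), dtype=np.int64
    )
    meta = pd.DataFrame(
        [
            {
                "doc_id": d.doc_id,
                "participant_id": d.meta.get("participant_id"),
                "arm": d.meta.get("arm"),
                "timepoint": d.meta.get("timepoint"),
                "n_attributions": d.meta.get("n_attributions", 1),
            }
            for d in kept
        ]
    )
    return DocumentTermMatrix(
        doc_ids=[d.doc_id for d in kept],
        vocab=vocab,
        counts=counts_mat,
        meta=meta,
        min_doc_freq=min_doc_freq,
        dropped_doc_ids=dropped,
    )


def save_dtm(dtm: DocumentTermMatrix, directory: str | Path) -> None:
    """Serialize a DTM as MatrixMarket counts plus CSV sidecars."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(directory / "counts.mtx"), dtm.counts.tocoo())
    dtm.meta.to_csv(directory / "docs.csv", index=False)
    pd.DataFrame({"stem": dtm.vocab}).to_csv(directory / "vocab.csv", index=False)


def load_dtm(directory: str | Path) -> DocumentTermMatrix:
    directory = Path(directory)
    counts = sp.csr_matrix(scipy.io.mmread(str(directory / "counts.mtx")), dtype=np.int64)
    meta = pd.read_csv(directory / "docs.csv")
    vocab = pd.read_csv(directory / "vocab.csv")["stem"].tolist()
    return DocumentTermMatrix(
        doc_ids=meta["doc_id"].tolist(),
        vocab=vocab,
        counts=counts,
        meta=meta,
    )
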
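"""The attribution codebook.

Eleven mutually exclusive categories for patients' free-text perceived
causes of chronic back pain, of which three — stress, psychological and
brain — are treated as mind- or brain-related.  Each attribution receives
exactly one category (forced choice).  The default codebook ships with
the package as data and can be overridden from JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass(frozen=True)
class Codebook:
    categories: tuple[str, ...]
    mindbrain_subset: frozenset[str]

    def __post_init__(self) -> None:
        if len(set(self.categories)) != len(self.categories):
            raise ValueError("codebook categories must be unique")
        extra = self.mindbrain_subset - set(self.categories)
        if extra:
            raise ValueError(f"mindbrain_subset not within categories: {sorted(extra)}")

    def is_mindbrain(self, category: str) -> bool:
        if category not in self.categories:
            raise ValueError(f"unknown category: {category!r}")
        return category in self.mindbrain_subset

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "categories": list(self.categories),
                    "mindbrain_subset": sorted(self.mindbrain_subset),
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "Codebook":
        obj = json.loads(Path(path).read_text())
        return cls(tuple(obj["categories"]), frozenset(obj["mindbrain_subset"]))


DEFAULT_CODEBOOK = Codebook(
    categories=(
        "spinal_condition",
        "physiological",
        "injury",
        "activity",
        "neglect",
        "sedentariness",
        "stress",
        "psychological",
        "brain",
        "hereditary_congenital",
        "age",
    ),
    mindbrain_subset=frozenset({"stress", "psychological", "brain"}),
)
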
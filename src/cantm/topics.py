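"""Topic-word extraction from the three decoder weight matrices.

Each decoder row is a distributionless scoring of the vocabulary: the
top-k tokens of row i of R are topic i's words, rows of R_ct are the
class-associated topics (one per class, a global explanation of the
classifier) and rows of R_s are the classification-aware topics.  Ranking
uses the raw decoder weight; the token-global bias is excluded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .corpus_io import Vocabulary
from .model import CantmNetwork

__all__ = ["TopicTable", "extract_topics"]

_SOURCES = {
    "R": "R", "m1": "R",
    "R_ct": "R_ct", "class": "R_ct",
    "R_s": "R_s", "m2": "R_s",
}


@dataclass(frozen=True)
class TopicTable:
    source: str
    rows: list[tuple[str, list[tuple[str, float]]]]

    def to_tsv(self) -> str:
        lines = []
        for name, words in self.rows:
            lines.append(name + "\t" + "\t".join(t for t, _ in words))
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {
                "source": self.source,
                "rows": [
                    {"name": n, "words": [{"token": t, "weight": w} for t, w in ws]}
                    for n, ws in self.rows
                ],
            },
            indent=2,
        )


def extract_topics(
    net: CantmNetwork,
    vocab: Vocabulary,
    source: str = "R_s",
    k: int = 10,
    labels: list[str] | None = None,
) -> TopicTable:
    """Top-k tokens per decoder row, descending weight, ties lexicographic.

    For the class-associated source the rows are named by class label when a
    label list is supplied.  Read-only and deterministic.
    """
    key = _SOURCES.get(source)
    if key is None:
        raise ValueError(f"unknown topic source {source!r}; use one of {sorted(_SOURCES)}")
    if k > vocab.size:
        raise ValueError(f"k={k} exceeds vocabulary size {vocab.size}")
    W = net.params[key]
    tokens = vocab.tokens
    rows = []
    for i, weights in enumerate(W):
        order = sorted(range(len(tokens)), key=lambda j: (-weights[j], tokens[j]))[:k]
        if key == "R_ct" and labels is not None:
            name = labels[i]
        else:
            name = f"topic_{i}"
        rows.append((name, [(tokens[j], float(weights[j])) for j in order]))
    return TopicTable(source=key, rows=rows)
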
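"""Turn claims records into unordered code documents for embedding training.

Codes within an admission are treated as an unordered multiset (claims codes
have no natural sequence); the trainer randomises token order every epoch so
a sliding context window sees random neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .claims_io import Vocabulary


@dataclass
class CodeDocument:
    """All in-vocabulary code tokens of one admission (or admission-day)."""

    document_id: str
    tokens: list[str]

    def __len__(self) -> int:
        return len(self.tokens)


def build_documents(
    records: pd.DataFrame,
    vocabulary: Vocabulary,
    grouping: Literal["admission", "admission_day"] = "admission",
) -> list[CodeDocument]:
    """Group records into code documents, dropping OOV tokens.

    Documents with fewer than two tokens are dropped (no co-occurrence
    signal).  Output is sorted by document id, so the result is
    deterministic for identical inputs.
    """
    if grouping == "admission":
        doc_id = records["admission_id"].astype(str)
    elif grouping == "admission_day":
        doc_id = (
            records["admission_id"].astype(str)
            + ":"
            + records["day_index"].astype(str).str.zfill(3)
        )
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    in_vocab = records["token"].isin(vocabulary.index)
    grouped = records.loc[in_vocab, "token"].groupby(doc_id[in_vocab], sort=True)
    docs = [
        CodeDocument(document_id=str(did), tokens=list(toks))
        for did, toks in grouped
        if len(toks) >= 2
    ]
    if not docs:
        raise ValueError("empty corpus: no document retains >= 2 in-vocabulary tokens")
    return docs


def shuffle_documents(
    docs: Sequence[CodeDocument], seed: int, epoch: int = 0
) -> list[CodeDocument]:
    """Deterministically permute document order and within-document token order.

    The permutation depends on ``(seed, epoch)`` only; token multisets are
    conserved.
    """
    rng = np.random.default_rng([seed, 997, epoch])
    order = rng.permutation(len(docs))
    out = []
    for i in order:
        doc = docs[i]
        perm = rng.permutation(len(doc.tokens))
        out.append(
            CodeDocument(
                document_id=doc.document_id,
                tokens=[doc.tokens[j] for j in perm],
            )
        )
    return out


def save_corpus(docs: Iterable[CodeDocument], path: str | Path) -> None:
    """One document per line, space-separated tokens."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(" ".join(doc.tokens) + "\n")


def load_corpus(path: str | Path) -> list[CodeDocument]:
    """Read a corpus saved by :func:`save_corpus`; line number becomes the id."""
    docs = []
    with open(path, "r", encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            tokens = line.split()
            if tokens:
                docs.append(CodeDocument(document_id=str(i), tokens=tokens))
    return docs
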
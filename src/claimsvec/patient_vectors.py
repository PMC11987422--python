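"""Per-patient covariates: the sum of embedding weights over day-1 codes.

Each patient's admission-day code multiset is compressed into one
k-dimensional vector by summing the code weight vectors (with multiplicity;
an optional ``dedupe`` mode counts each distinct code once, and ``mode="mean"``
is available for sensitivity analyses only — the primary convention is the
plain sum).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .embedding import EmbeddingTable

logger = logging.getLogger(__name__)


@dataclass
class PatientVector:
    patient_id: str | None
    v: np.ndarray
    n_codes_used: int
    n_codes_missing: int


def embedding_columns(k: int) -> list[str]:
    """Canonical column names ``v1..vk`` for patient-vector components."""
    return [f"v{i + 1}" for i in range(k)]


def vectorize_patient(
    day1_tokens: Iterable[str],
    table: EmbeddingTable,
    patient_id: str | None = None,
    dedupe: bool = False,
) -> PatientVector:
    """Sum the weight vectors of a patient's day-1 codes.

    Tokens absent from the table contribute nothing and are counted in
    ``n_codes_missing``; a patient with no matched code gets the zero vector.
    """
    tokens = list(day1_tokens)
    if dedupe:
        tokens = list(dict.fromkeys(tokens))
    v = np.zeros(table.k, dtype=np.float64)
    used = missing = 0
    for tok in tokens:
        if tok in table:
            v += table.vector(tok)
            used += 1
        else:
            missing += 1
    return PatientVector(patient_id, v, used, missing)


def vectorize_cohort(
    records: pd.DataFrame,
    table: EmbeddingTable,
    day_range: tuple[int, int] = (1, 1),
    dedupe: bool = False,
    mode: Literal["sum", "mean"] = "sum",
) -> pd.DataFrame:
    """One summed vector per patient appearing in ``records``.

    Output is indexed by ``patient_id`` with columns ``v1..vk``,
    ``n_codes_used`` and ``n_codes_missing``.  The default ``day_range``
    selects admission-day codes only (``day_index == 1``); patients with
    no code in range get the zero vector (logged).
    """
    lo, hi = day_range
    sel = records[(records["day_index"] >= lo) & (records["day_index"] <= hi)]
    if dedupe:
        sel = sel.drop_duplicates(subset=["patient_id", "token"])

    all_patients = pd.Index(records["patient_id"].unique(), name="patient_id")
    k = table.k
    matrix = np.zeros((len(all_patients), k), dtype=np.float64)
    used = np.zeros(len(all_patients), dtype=np.int64)
    missing = np.zeros(len(all_patients), dtype=np.int64)
    pat_pos = {pid: i for i, pid in enumerate(all_patients)}

    rows = sel["patient_id"].map(pat_pos).to_numpy()
    tok_rows = sel["token"].map(table._row).to_numpy()
    matched = ~pd.isna(tok_rows)
    np.add.at(matrix, rows[matched], table.vectors[tok_rows[matched].astype(int)])
    np.add.at(used, rows[matched], 1)
    np.add.at(missing, rows[~matched], 1)
    if mode == "mean":
        matrix = matrix / np.maximum(used, 1)[:, None]
    elif mode != "sum":
        raise ValueError(f"unknown mode {mode!r}")

    n_empty = int((used + missing == 0).sum())
    if n_empty:
        logger.warning(
            "%d patients have no code in day range %s; zero vectors assigned",
            n_empty, day_range,
        )
    out = pd.DataFrame(matrix, index=all_patients, columns=embedding_columns(k))
    out["n_codes_used"] = used
    out["n_codes_missing"] = missing
    return out


def assemble_features(
    patients: pd.DataFrame,
    vectors: pd.DataFrame | None = None,
    truth: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Patient table merged with patient vectors (and truth severity).

    Returns one row per patient indexed by ``patient_id``; patients missing
    from ``vectors`` get zero components.  Merging the truth record exposes
    latent severity as a covariate for "true model" (complete) adjustment in
    simulations.
    """
    features = patients.set_index("patient_id")
    if truth is not None:
        features = features.join(
            truth.set_index("patient_id")[["severity"]], how="left"
        )
    if vectors is not None:
        vcols = [c for c in vectors.columns if c.startswith("v")]
        features = features.join(vectors[vcols], how="left")
        features[vcols] = features[vcols].fillna(0.0)
    return features
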
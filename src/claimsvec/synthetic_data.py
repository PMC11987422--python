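"""Synthetic inpatient claims cohorts with a known data-generating process.

A single latent severity variable ``s ~ N(0, 1)`` drives everything:

* **Codes.** Each admission emits day-1 codes (and a few later-day codes)
  whose co-occurrence *cluster* is chosen with probability proportional to
  ``exp(-(s - mu_j)^2 / (2 * bandwidth^2))`` for cluster centres ``mu_j``
  spread over ``[-span, span]``.  Severity therefore enters through cluster
  mixture weights, not marginal token frequencies: the signal is relational,
  which is the regime where embeddings of co-occurring codes can act as a
  severity proxy.
* **Measured confounders.** Age, a coma-scale flag, admission ADL
  dependency, systolic blood pressure and a CKD flag all load on severity.
* **Treatment.** Early rehabilitation (start day <= 2) with
  ``logit P(T=1) = alpha + gamma * s``; ``gamma`` is the confounding dial
  and ``gamma = 0`` gives a randomised cohort.
* **Outcomes.** In-hospital death, ADL dependency at discharge (Barthel-like
  proxy), 90-day readmission and log-normal length of stay depend on
  severity only, never on treatment, so the true treatment effect is zero
  by construction and any non-zero naive contrast is confounding bias.

The returned *truth record* carries each patient's severity and true model
probabilities so oracle-adjusted estimates can be computed in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .claims_io import validate_claims, validate_patient_table

_CODE_TYPE_CYCLE = (
    ("DX", "diagnosis"),
    ("RX", "medication"),
    ("PR", "procedure"),
    ("SP", "supply"),
)

#: Measured-confounder columns emitted by the generator (besides age/sex).
MEASURED_CONFOUNDERS = ("jcs_disturbed", "adl_low_admission", "sbp", "ckd")


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic data-generating process.

    Outcome/treatment models are ``(intercept, severity slope)`` pairs on the
    logit scale.  Defaults emulate an elderly heart-failure-like inpatient
    population: ~27% composite outcome rate, median stay ~2 weeks, strongly
    severity-driven prognosis.
    """

    n_patients: int = 20_000
    vocab_size: int = 500
    n_clusters: int = 10
    codes_day1_lambda: float = 12.0
    codes_later_lambda: float = 3.0
    cluster_bandwidth: float = 0.8
    cluster_span: float = 2.0
    # treatment model: logit P(T=1) = treat_intercept + gamma * severity
    gamma: float = 1.0
    treat_intercept: float = -0.4
    # measured confounders
    age_mean: float = 76.0
    age_severity_loading: float = 5.0
    age_noise_sd: float = 9.0
    sex_p: float = 0.45
    jcs_model: tuple[float, float] = (-1.2, 1.2)
    adl_low_model: tuple[float, float] = (-0.8, 1.0)
    sbp_mean: float = 130.0
    sbp_severity_loading: float = -8.0
    sbp_noise_sd: float = 15.0
    ckd_model: tuple[float, float] = (-1.6, 0.6)
    # outcome models
    death_model: tuple[float, float] = (-2.7, 1.4)
    adl_dep_model: tuple[float, float] = (-1.6, 1.6)
    readmit_model: tuple[float, float] = (-1.9, 0.7)
    los_log_mean: float = 2.6
    los_log_severity_slope: float = 0.25
    los_log_sd: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.vocab_size < self.n_clusters:
            raise ValueError("vocab_size must be >= n_clusters")
        if self.codes_day1_lambda <= 0:
            raise ValueError("codes_day1_lambda must be > 0")
        if not 0 < self.sex_p < 1:
            raise ValueError("sex_p must lie in (0, 1)")
        if self.cluster_bandwidth <= 0:
            raise ValueError("cluster_bandwidth must be > 0")


@dataclass
class SyntheticCohort:
    """Claims records, patient table and ground-truth record for one draw."""

    claims: pd.DataFrame
    patients: pd.DataFrame
    truth: pd.DataFrame
    spec: GeneratorSpec

    def __iter__(self) -> Iterator[pd.DataFrame]:
        return iter((self.claims, self.patients, self.truth))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _token_string(token_id: int) -> str:
    prefix, _ = _CODE_TYPE_CYCLE[token_id % len(_CODE_TYPE_CYCLE)]
    return f"{prefix}:{token_id:05d}"


def planted_cluster_labels(spec: GeneratorSpec) -> dict[str, int]:
    """Ground-truth emission cluster of every vocabulary token.

    Tokens are partitioned into ``n_clusters`` contiguous blocks of
    near-equal size; the map is a pure function of the spec (no data draw).
    """
    edges = np.linspace(0, spec.vocab_size, spec.n_clusters + 1).astype(int)
    labels: dict[str, int] = {}
    for j in range(spec.n_clusters):
        for tid in range(edges[j], edges[j + 1]):
            labels[_token_string(tid)] = j
    return labels


def cluster_probabilities(spec: GeneratorSpec, severity: np.ndarray) -> np.ndarray:
    """Per-patient cluster selection probabilities, shape (n, n_clusters)."""
    centers = np.linspace(-spec.cluster_span, spec.cluster_span, spec.n_clusters)
    logw = -((severity[:, None] - centers[None, :]) ** 2) / (
        2.0 * spec.cluster_bandwidth**2
    )
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    return w / w.sum(axis=1, keepdims=True)


def _draw_codes(
    spec: GeneratorSpec,
    severity: np.ndarray,
    counts: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``counts[i]`` token ids for each patient i.

    Returns (patient_row_index, token_id) arrays of length ``counts.sum()``.
    """
    probs = cluster_probabilities(spec, severity)
    rows = np.repeat(np.arange(len(severity)), counts)
    # Gumbel-max trick: one categorical draw per emitted code.
    g = rng.gumbel(size=(len(rows), spec.n_clusters))
    clusters = np.argmax(np.log(probs[rows] + 1e-300) + g, axis=1)
    edges = np.linspace(0, spec.vocab_size, spec.n_clusters + 1).astype(int)
    lo = edges[clusters]
    width = edges[clusters + 1] - lo
    token_ids = lo + rng.integers(0, width)
    return rows, token_ids


def generate_cohort(spec: GeneratorSpec) -> SyntheticCohort:
    """Draw one cohort: claims records, patient table and truth record.

    Deterministic given ``spec`` (including ``spec.seed``).
    """
    rng = np.random.default_rng([spec.seed, 2024])
    n = spec.n_patients
    severity = rng.standard_normal(n)

    # measured confounders
    age = np.clip(
        np.round(
            spec.age_mean
            + spec.age_severity_loading * severity
            + rng.normal(0.0, spec.age_noise_sd, n)
        ),
        21,
        105,
    ).astype(int)
    sex = (rng.random(n) < spec.sex_p).astype(int)
    jcs = (rng.random(n) < _sigmoid(spec.jcs_model[0] + spec.jcs_model[1] * severity)).astype(int)
    adl_low = (
        rng.random(n) < _sigmoid(spec.adl_low_model[0] + spec.adl_low_model[1] * severity)
    ).astype(int)
    sbp = np.round(
        spec.sbp_mean
        + spec.sbp_severity_loading * severity
        + rng.normal(0.0, spec.sbp_noise_sd, n),
        1,
    )
    ckd = (rng.random(n) < _sigmoid(spec.ckd_model[0] + spec.ckd_model[1] * severity)).astype(int)

    # treatment: early rehabilitation (start day <= 2)
    p_treat = _sigmoid(spec.treat_intercept + spec.gamma * severity)
    treatment = (rng.random(n) < p_treat).astype(int)

    # outcomes (severity only; no treatment effect)
    p_death = _sigmoid(spec.death_model[0] + spec.death_model[1] * severity)
    p_adl = _sigmoid(spec.adl_dep_model[0] + spec.adl_dep_model[1] * severity)
    p_readmit = _sigmoid(spec.readmit_model[0] + spec.readmit_model[1] * severity)
    death = (rng.random(n) < p_death).astype(int)
    adl_dep = (rng.random(n) < p_adl).astype(int)
    readmit = (rng.random(n) < p_readmit).astype(int)
    los = np.maximum(
        1,
        np.ceil(
            np.exp(
                spec.los_log_mean
                + spec.los_log_severity_slope * severity
                + rng.normal(0.0, spec.los_log_sd, n)
            )
        ).astype(int),
    )
    # rehabilitation start day consistent with the exposure definition:
    # treated start on day 2, controls on day >= 3
    rehab_start = np.where(treatment == 1, 2, 3 + rng.poisson(2.0, n))

    patient_ids = np.array([f"P{i:06d}" for i in range(n)])
    admission_ids = np.array([f"A{i:06d}" for i in range(n)])

    # day-1 codes (at least 2 per admission)
    n_day1 = np.maximum(2, rng.poisson(spec.codes_day1_lambda, n))
    rows1, tok1 = _draw_codes(spec, severity, n_day1, rng)
    day1 = np.ones(len(rows1), dtype=int)
    # later-day codes for stays longer than one day
    n_later = np.where(los > 1, rng.poisson(spec.codes_later_lambda, n), 0)
    rows2, tok2 = _draw_codes(spec, severity, n_later, rng)
    day2 = rng.integers(2, los[rows2] + 1)

    rows = np.concatenate([rows1, rows2])
    token_ids = np.concatenate([tok1, tok2])
    days = np.concatenate([day1, day2])
    order = np.lexsort((days, rows))
    rows, token_ids, days = rows[order], token_ids[order], days[order]

    type_names = np.array([t for _, t in _CODE_TYPE_CYCLE])
    tokens = np.array([_token_string(t) for t in range(spec.vocab_size)])
    claims = pd.DataFrame(
        {
            "patient_id": patient_ids[rows],
            "admission_id": admission_ids[rows],
            "day_index": days,
            "code_type": type_names[token_ids % len(_CODE_TYPE_CYCLE)],
            "token": tokens[token_ids],
        }
    )

    patients = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "age": age,
            "sex": sex,
            "admission_day_count": los,
            "treatment": treatment,
            "rehab_start_day": rehab_start,
            "outcome_death": death,
            "outcome_adl_dependency": adl_dep,
            "outcome_composite": np.maximum(death, adl_dep),
            "outcome_readmit90": readmit,
            "length_of_stay": los,
            "jcs_disturbed": jcs,
            "adl_low_admission": adl_low,
            "sbp": sbp,
            "ckd": ckd,
        }
    )

    truth = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "severity": severity,
            "p_treat": p_treat,
            "p_death": p_death,
            "p_adl_dependency": p_adl,
            "p_composite": 1.0 - (1.0 - p_death) * (1.0 - p_adl),
            "p_readmit90": p_readmit,
            "day1_discharge": (los == 1).astype(int),
        }
    )

    validate_claims(claims)
    validate_patient_table(patients)
    return SyntheticCohort(claims=claims, patients=patients, truth=truth, spec=spec)
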
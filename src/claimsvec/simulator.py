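"""Bias-injection simulation: randomised truth, prognostic-quartile sampling.

The study design: start from a cohort whose treatment indicator is assigned
at random (so the true risk difference is exactly 0), fit a prognostic model
for the composite outcome once, split the cohort into prognostic-risk
quartiles Q1-Q4, then construct per-replicate cohorts by sampling controls
equally across quartiles and treated units with scenario-specific quartile
weights.  The weight grid runs from (0.4, 0.3, 0.2, 0.1) — treated drawn
preferentially from low-risk quartiles — to (0.1, 0.2, 0.3, 0.4), injecting
confounding of varying sign and intensity.  Each sampled cohort is adjusted
with Models 1-4 and the estimated risk differences, coverage of 0, balance
SMDs and matched c-statistics are summarised across replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .adjustment import (
    MatchedCohort,
    MatchingError,
    ModelSpec,
    estimate_effect,
    fit_propensity,
    match,
    matched_cstat,
    smd,
)

logger = logging.getLogger(__name__)

_EXTREME_LOW_RISK = (0.4, 0.3, 0.2, 0.1)
_EXTREME_HIGH_RISK = (0.1, 0.2, 0.3, 0.4)


@dataclass(frozen=True)
class ScenarioSpec:
    """Treated-cohort sampling weights over prognostic quartiles Q1..Q4."""

    index: int
    weights: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights):
            raise ValueError("scenario weights must be nonnegative")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("scenario weights must sum to 1")


def scenario_grid(n_scenarios: int = 10) -> list[ScenarioSpec]:
    """Linear interpolation between the two extreme sampling scenarios.

    Scenario 1 is exactly (0.4, 0.3, 0.2, 0.1) and the last scenario exactly
    (0.1, 0.2, 0.3, 0.4); intermediate scenarios interpolate component-wise
    at ``t = (i - 1) / (n_scenarios - 1)``.
    """
    if n_scenarios < 2:
        raise ValueError("n_scenarios must be >= 2")
    a = np.array(_EXTREME_LOW_RISK)
    b = np.array(_EXTREME_HIGH_RISK)
    out = []
    for i in range(n_scenarios):
        t = i / (n_scenarios - 1)
        w = (1.0 - t) * a + t * b
        out.append(ScenarioSpec(index=i + 1, weights=tuple(float(x) for x in w)))
    return out


def assign_random_treatment(
    n: int, p: float = 0.5, seed: int | Sequence[int] = 0
) -> np.ndarray:
    """I.i.d. Bernoulli(p) treatment indicator, independent of everything."""
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    return (rng.random(n) < p).astype(int)


@dataclass
class PrognosticFit:
    """Fitted prognostic (outcome) model: risk scores and discrimination."""

    scores: np.ndarray
    cstat: float
    coefficients: pd.Series
    intercept: float


def fit_prognostic_model(
    features: pd.DataFrame,
    outcome: pd.Series,
    covariates: Sequence[str],
) -> PrognosticFit:
    """Main-effects logistic prognosis model for the composite outcome.

    Returns predicted probabilities and the apparent c-statistic.  Reuses
    the propensity machinery (same ML logistic fit), with the outcome in
    place of treatment.
    """
    y = np.asarray(outcome, dtype=int)
    if y.min() == y.max():
        raise ValueError("outcome is degenerate (single class)")
    fit = fit_propensity(features, y, ModelSpec(2, tuple(covariates)))
    return PrognosticFit(
        scores=fit.ps,
        cstat=float(roc_auc_score(y, fit.ps)),
        coefficients=fit.coefficients,
        intercept=fit.intercept,
    )


def quartile_bins(scores: Sequence[float]) -> np.ndarray:
    """Labels 1..4 by quartile of predicted risk (Q1 = lowest risk).

    Cut points are the empirical 25/50/75 percentiles; scores equal to a cut
    point fall in the lower bin.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    cuts = np.percentile(scores, [25, 50, 75])
    labels = np.searchsorted(cuts, scores, side="left") + 1
    if np.ptp(scores) == 0:
        logger.warning("all prognostic scores identical; every unit lands in Q1")
    return labels


def _exact_counts(weights: Sequence[float], total: int) -> np.ndarray:
    """Largest-remainder apportionment so counts sum to ``total`` exactly."""
    raw = np.asarray(weights, dtype=float) * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return base


@dataclass
class SampledCohort:
    """One replicate's simulation cohort with sampling bookkeeping."""

    treated_ids: np.ndarray
    control_ids: np.ndarray
    treated_quartile_counts: dict[int, int]
    control_quartile_counts: dict[int, int]

    def all_ids(self) -> np.ndarray:
        return np.concatenate([self.treated_ids, self.control_ids])


def sample_simulation_cohort(
    ids: Sequence,
    treatment: np.ndarray,
    bins: np.ndarray,
    spec: ScenarioSpec,
    n_control: int = 10_000,
    n_treated: int = 10_000,
    seed: int | Sequence[int] = 0,
) -> SampledCohort:
    """Draw one simulation cohort without replacement.

    Controls: ``n_control`` units with equal counts per quartile from the
    ``treatment == 0`` pool.  Treated: ``n_treated`` units with quartile
    proportions equal to the scenario weights from the ``treatment == 1``
    pool.  Raises when any quartile pool is too small, naming the quartile.
    """
    ids = np.asarray(ids)
    rng = np.random.default_rng(seed)
    ctrl_counts = _exact_counts([0.25] * 4, n_control)
    trt_counts = _exact_counts(spec.weights, n_treated)
    treated_parts, control_parts = [], []
    t_book, c_book = {}, {}
    for q in range(1, 5):
        pool_c = ids[(treatment == 0) & (bins == q)]
        pool_t = ids[(treatment == 1) & (bins == q)]
        need_c, need_t = int(ctrl_counts[q - 1]), int(trt_counts[q - 1])
        if len(pool_c) < need_c:
            raise ValueError(
                f"control pool in Q{q} has {len(pool_c)} units; {need_c} needed"
            )
        if len(pool_t) < need_t:
            raise ValueError(
                f"treated pool in Q{q} has {len(pool_t)} units; {need_t} needed"
            )
        control_parts.append(rng.choice(pool_c, size=need_c, replace=False))
        treated_parts.append(rng.choice(pool_t, size=need_t, replace=False))
        c_book[q], t_book[q] = need_c, need_t
    return SampledCohort(
        treated_ids=np.concatenate(treated_parts),
        control_ids=np.concatenate(control_parts),
        treated_quartile_counts=t_book,
        control_quartile_counts=c_book,
    )


def coverage(replicates: pd.DataFrame | Sequence, truth: float = 0.0) -> float:
    """Fraction of replicates whose 95% CI contains ``truth``."""
    if isinstance(replicates, pd.DataFrame):
        if len(replicates) == 0:
            raise ValueError("no replicates")
        lo = replicates["ci_low"].to_numpy(dtype=float)
        hi = replicates["ci_high"].to_numpy(dtype=float)
    else:
        rows = list(replicates)
        if not rows:
            raise ValueError("no replicates")
        lo = np.array([r[0] for r in rows], dtype=float)
        hi = np.array([r[1] for r in rows], dtype=float)
    return float(np.mean((lo <= truth) & (truth <= hi)))


@dataclass
class SimulationResults:
    """Per-replicate records and per-scenario/model summaries."""

    replicates: pd.DataFrame
    summary: pd.DataFrame
    prognostic_cstat: float
    bins: np.ndarray
    n_failed: int = 0


def run_simulation(
    features: pd.DataFrame,
    model_specs: Mapping[int, ModelSpec],
    outcome_col: str = "outcome_composite",
    prognostic_covariates: Sequence[str] | None = None,
    scenarios: Sequence[ScenarioSpec] | None = None,
    n_reps: int = 100,
    n_control: int = 10_000,
    n_treated: int = 10_000,
    n_boot: int = 200,
    caliper_fraction: float = 0.01,
    treatment_p: float = 0.5,
    seed: int = 0,
    cstat_spec: ModelSpec | None = None,
    compute_cstat: bool = True,
    compute_smd: bool = True,
) -> SimulationResults:
    """Run the full bias-injection simulation.

    ``features`` is a patient-indexed covariate/outcome table (see
    :func:`claimsvec.patient_vectors.assemble_features`).  The prognostic
    model is fit once on the full cohort; each (scenario, replicate) then
    draws a fresh random treatment indicator, samples a cohort, applies
    every model in ``model_specs`` and records the risk difference, 95% CI,
    coverage flag, balance diagnostics and matched c-statistic (computed
    with ``cstat_spec``, default the Model-4 specification, in every model's
    matched cohort — the full sampled cohort for Model 1).

    Replicates where matching yields zero pairs are flagged, excluded from
    summaries and counted.  Fully reproducible under ``seed``.
    """
    if scenarios is None:
        scenarios = scenario_grid(10)
    if prognostic_covariates is None:
        prognostic_covariates = model_specs[2].covariates
    if cstat_spec is None and compute_cstat:
        cstat_spec = model_specs.get(4) or max(
            model_specs.values(), key=lambda s: len(s.covariates)
        )

    n = len(features)
    prog = fit_prognostic_model(
        features, features[outcome_col], prognostic_covariates
    )
    bins = quartile_bins(prog.scores)
    ids = features.index.to_numpy()
    logger.info(
        "prognostic model apparent c-statistic %.3f; running %d scenarios x %d reps",
        prog.cstat, len(scenarios), n_reps,
    )

    rows = []
    n_failed = 0
    for si, scen in enumerate(scenarios):
        for r in range(n_reps):
            # fresh randomised truth each replicate: no treatment-outcome
            # association beyond what the quartile sampling injects
            treatment = assign_random_treatment(
                n, treatment_p, seed=[seed, 1, si, r]
            )
            sampled = sample_simulation_cohort(
                ids, treatment, bins, scen,
                n_control=n_control, n_treated=n_treated,
                seed=[seed, 3, si, r],
            )
            sub_ids = sampled.all_ids()
            sub = features.loc[sub_ids]
            t = pd.Series(
                np.r_[
                    np.ones(len(sampled.treated_ids), dtype=int),
                    np.zeros(len(sampled.control_ids), dtype=int),
                ],
                index=sub_ids,
            )
            y = sub[outcome_col]
            for model_id, mspec in sorted(model_specs.items()):
                row: dict = {
                    "scenario": scen.index,
                    "replicate": r,
                    "model": model_id,
                    "failed": False,
                }
                matched: MatchedCohort | None = None
                try:
                    if model_id != 1:
                        fit = fit_propensity(sub, t, mspec)
                        matched = match(
                            fit.ps, t, ids=sub_ids,
                            caliper_fraction=caliper_fraction,
                            seed=[seed, 5, si, r, model_id],
                        )
                        row["n_pairs"] = matched.n_pairs
                    else:
                        row["n_pairs"] = 0
                    est = estimate_effect(
                        y, t, matched=matched, n_boot=n_boot,
                        seed=[seed, 7, si, r, model_id],
                    )
                except MatchingError as err:
                    logger.warning(
                        "scenario %d rep %d model %d: %s (replicate excluded)",
                        scen.index, r, model_id, err,
                    )
                    row.update(failed=True)
                    n_failed += 1
                    rows.append(row)
                    continue
                row.update(
                    risk_difference=est.point,
                    ci_low=est.ci_low,
                    ci_high=est.ci_high,
                    covered=bool(est.ci_low <= 0.0 <= est.ci_high),
                )
                if compute_smd:
                    pre = [smd(sub[c], t) for c in prognostic_covariates]
                    row["smd_pre_median"] = float(np.median(pre))
                    if matched is not None:
                        post = [
                            smd(sub[c], t, matched) for c in prognostic_covariates
                        ]
                        row["smd_post_median"] = float(np.median(post))
                    else:
                        row["smd_post_median"] = row["smd_pre_median"]
                if compute_cstat:
                    row["cstat"] = matched_cstat(sub, t, cstat_spec, matched)
                rows.append(row)

    replicates = pd.DataFrame(rows)
    ok = replicates[~replicates["failed"]]
    summary = (
        ok.groupby(["scenario", "model"])
        .apply(
            lambda g: pd.Series(
                {
                    "median_rd": g["risk_difference"].median(),
                    "rd_ci_low": g["risk_difference"].quantile(0.025),
                    "rd_ci_high": g["risk_difference"].quantile(0.975),
                    "coverage": g["covered"].mean(),
                    "median_cstat": g["cstat"].median()
                    if "cstat" in g
                    else np.nan,
                    "median_smd_pre": g["smd_pre_median"].median()
                    if "smd_pre_median" in g
                    else np.nan,
                    "median_smd_post": g["smd_post_median"].median()
                    if "smd_post_median" in g
                    else np.nan,
                    "n_replicates": len(g),
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )
    return SimulationResults(
        replicates=replicates,
        summary=summary,
        prognostic_cstat=prog.cstat,
        bins=bins,
        n_failed=n_failed,
    )
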
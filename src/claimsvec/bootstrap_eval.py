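"""Subsample-bootstrap comparison of Models 1-3 against the Model-4 reference.

Each bootstrap iteration draws a fixed fraction of the cohort without
replacement, runs every adjustment model end-to-end on the subsample and
records, per outcome, the model's effect estimate and its CI width (the
efficiency measure).  Models 1-3 are then compared with Model 4 through the
distribution of per-iteration differences (mean and 2.5/97.5 percentile CI).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .adjustment import (
    EffectEstimate,
    MatchingError,
    ModelSpec,
    estimate_effect,
    fit_propensity,
    match,
)

logger = logging.getLogger(__name__)


def ci_width(estimate: EffectEstimate) -> float:
    """Width of the 95% CI (upper minus lower); the efficiency measure."""
    return float(estimate.ci_high - estimate.ci_low)


@dataclass
class BootstrapComparison:
    """Per-model comparison against the reference model for one outcome."""

    outcome: str
    table: pd.DataFrame  # per model: mean/CI of estimate and width differences
    iterations: pd.DataFrame  # per (iteration, model): estimate, ci_width
    n_boot: int
    subsample_fraction: float
    reference_model: int
    n_failed: int


def bootstrap_compare(
    features: pd.DataFrame,
    model_specs: Mapping[int, ModelSpec],
    outcomes: Mapping[str, str],
    treatment_col: str = "treatment",
    n_boot: int = 1000,
    subsample_fraction: float = 0.2,
    n_inner_boot: int = 200,
    caliper_fraction: float = 0.01,
    seed: int = 0,
    reference_model: int = 4,
) -> dict[str, BootstrapComparison]:
    """Run the repeated-subsample comparison framework.

    ``outcomes`` maps a display name to a feature column.  Each iteration
    uses exactly ``round(subsample_fraction * n)`` patients.  Iterations in
    which a model forms zero matched pairs are flagged, excluded from that
    model's comparison and counted.  The reference model compared with
    itself has difference exactly 0.
    """
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must lie in (0, 1]")
    if reference_model not in model_specs:
        raise ValueError(f"reference model {reference_model} not in model_specs")
    n = len(features)
    m = int(round(subsample_fraction * n))
    ids = features.index.to_numpy()

    rows = []
    n_failed = 0
    for it in range(n_boot):
        rng = np.random.default_rng([seed, 13, it])
        sub_ids = rng.choice(ids, size=m, replace=False)
        sub = features.loc[sub_ids]
        t = sub[treatment_col]
        for model_id, mspec in sorted(model_specs.items()):
            matched = None
            try:
                if model_id != 1:
                    fit = fit_propensity(sub, t, mspec)
                    matched = match(
                        fit.ps, t, ids=sub_ids,
                        caliper_fraction=caliper_fraction,
                        seed=[seed, 17, it, model_id],
                    )
            except MatchingError as err:
                logger.warning(
                    "iteration %d model %d: %s (excluded)", it, model_id, err
                )
                n_failed += 1
                continue
            for name, col in outcomes.items():
                est = estimate_effect(
                    sub[col], t, matched=matched, n_boot=n_inner_boot,
                    seed=[seed, 19, it, model_id, hash(name) % (2**31)],
                )
                rows.append(
                    {
                        "iteration": it,
                        "model": model_id,
                        "outcome": name,
                        "estimate": est.point,
                        "ci_width": ci_width(est),
                    }
                )
    iterations = pd.DataFrame(rows)
    if iterations.empty:
        raise RuntimeError("every bootstrap iteration failed")

    out: dict[str, BootstrapComparison] = {}
    for name in outcomes:
        sub_it = iterations[iterations["outcome"] == name]
        ref = sub_it[sub_it["model"] == reference_model].set_index("iteration")
        comp_rows = []
        for model_id in sorted(model_specs):
            mine = sub_it[sub_it["model"] == model_id].set_index("iteration")
            common = mine.index.intersection(ref.index)
            d_est = (
                mine.loc[common, "estimate"] - ref.loc[common, "estimate"]
            ).to_numpy()
            d_w = (
                mine.loc[common, "ci_width"] - ref.loc[common, "ci_width"]
            ).to_numpy()
            comp_rows.append(
                {
                    "model": model_id,
                    "n_iterations": len(common),
                    "mean_estimate_diff": float(d_est.mean()),
                    "estimate_diff_ci_low": float(np.percentile(d_est, 2.5)),
                    "estimate_diff_ci_high": float(np.percentile(d_est, 97.5)),
                    "mean_width_diff": float(d_w.mean()),
                    "width_diff_ci_low": float(np.percentile(d_w, 2.5)),
                    "width_diff_ci_high": float(np.percentile(d_w, 97.5)),
                }
            )
        out[name] = BootstrapComparison(
            outcome=name,
            table=pd.DataFrame(comp_rows).set_index("model"),
            iterations=sub_it.reset_index(drop=True),
            n_boot=n_boot,
            subsample_fraction=subsample_fraction,
            reference_model=reference_model,
            n_failed=n_failed,
        )
    return out
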
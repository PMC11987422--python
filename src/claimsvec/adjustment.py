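"""Propensity-score models 1-4, caliper matching, balance and effects.

The four risk-adjustment models compared throughout the package:

* **Model 1** — no adjustment: the crude risk difference.
* **Model 2** — propensity-score matching on a named list of measured
  confounders (in simulations this is the complete/true model).
* **Model 3** — matching on age, sex and the k summed embedding components
  (the proxy model for unmeasured confounding).
* **Model 4** — the union of Models 2 and 3.

Matching is greedy 1:1 nearest-neighbour without replacement under a caliper
of ``caliper_fraction x SD(PS)`` (probability scale by default, logit scale
optional).  Balance diagnostics are the standardised mean difference and the
c-statistic of a treatment model refit within the matched cohort (0.5 under
full balance).  Effect CIs are percentile bootstrap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logit as _logit_fn
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)


class SeparationError(RuntimeError):
    """Perfect separation in a propensity fit with the ridge fallback disabled."""


class MatchingError(RuntimeError):
    """No matched pair could be formed under the caliper."""


@dataclass(frozen=True)
class ModelSpec:
    """A risk-adjustment model: its id (1-4) and propensity covariates."""

    model_id: int
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.model_id == 1 and self.covariates:
            raise ValueError("Model 1 performs no adjustment and has no covariates")
        if self.model_id != 1 and not self.covariates:
            raise ValueError(f"Model {self.model_id} requires covariates")


def default_model_specs(
    measured: Sequence[str],
    embedding_cols: Sequence[str],
    demographics: Sequence[str] = ("age", "sex"),
) -> dict[int, ModelSpec]:
    """Build the standard Model 1-4 specifications.

    ``measured`` are the Model-2 confounders (beyond demographics);
    ``embedding_cols`` are the patient-vector component columns.
    """
    m2 = tuple(demographics) + tuple(measured)
    m3 = tuple(demographics) + tuple(embedding_cols)
    m4 = tuple(dict.fromkeys(m2 + m3))
    return {
        1: ModelSpec(1, ()),
        2: ModelSpec(2, m2),
        3: ModelSpec(3, m3),
        4: ModelSpec(4, m4),
    }


@dataclass
class PropensityFit:
    """Fitted propensity model: scores plus raw-scale coefficients."""

    ps: np.ndarray
    coefficients: pd.Series
    intercept: float
    ridge_used: bool = False

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.ps, dtype=dtype)


def fit_propensity(
    features: pd.DataFrame,
    treatment: Sequence[int] | pd.Series,
    spec: ModelSpec,
    ridge_on_separation: bool = True,
    ridge_c: float = 1.0,
    max_iter: int = 1000,
    tol: float = 1e-10,
) -> PropensityFit:
    """Maximum-likelihood logistic propensity scores for ``spec``.

    Covariates are standardised internally for conditioning; reported
    coefficients are mapped back to the raw scale.  Perfect separation
    (AUC of the linear predictor exactly 1) triggers an L2 ridge refit when
    ``ridge_on_separation`` is set, otherwise :class:`SeparationError`.
    """
    if spec.model_id == 1:
        raise ValueError("Model 1 has no propensity model")
    t = np.asarray(treatment, dtype=int)
    if t.min() == t.max():
        raise ValueError("both treatment groups must be nonempty")
    X = features[list(spec.covariates)].to_numpy(dtype=np.float64)
    if np.isnan(X).any():
        raise ValueError("missing covariate values in propensity features")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - mean) / scale

    def _fit(C):
        # C = inf is the unpenalised maximum-likelihood fit
        clf = LogisticRegression(C=C, solver="lbfgs", max_iter=max_iter, tol=tol)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(Z, t)
        return clf

    clf = _fit(np.inf)
    linpred = Z @ clf.coef_[0] + clf.intercept_[0]
    ridge_used = False
    if not np.ptp(linpred) == 0 and roc_auc_score(t, linpred) == 1.0:
        if not ridge_on_separation:
            raise SeparationError(
                f"perfect separation in Model {spec.model_id} propensity fit"
            )
        logger.warning(
            "perfect separation in Model %d propensity fit; "
            "refitting with L2 ridge (C=%g)", spec.model_id, ridge_c,
        )
        clf = _fit(ridge_c)
        ridge_used = True
    ps = clf.predict_proba(Z)[:, 1]
    coef_std = clf.coef_[0]
    coef_raw = coef_std / scale
    intercept_raw = float(clf.intercept_[0] - np.sum(coef_std * mean / scale))
    return PropensityFit(
        ps=ps,
        coefficients=pd.Series(coef_raw, index=list(spec.covariates)),
        intercept=intercept_raw,
        ridge_used=ridge_used,
    )


@dataclass
class MatchedCohort:
    """1:1 treated-control pairs under a caliper, without replacement."""

    pairs: pd.DataFrame  # columns: treated_id, control_id, ps_treated, ps_control
    caliper: float
    scale: str
    n_treated_unmatched: int
    treated_order: list  # processing order used (for replay/audit)
    ps: pd.Series  # propensity score of every patient

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def matched_ids(self) -> list:
        return list(self.pairs["treated_id"]) + list(self.pairs["control_id"])


def match(
    ps: Sequence[float] | PropensityFit,
    treatment: Sequence[int] | pd.Series,
    ids: Sequence | None = None,
    caliper_fraction: float = 0.01,
    seed: int | Sequence[int] = 0,
    scale: str = "probability",
) -> MatchedCohort:
    """Greedy 1:1 nearest-neighbour caliper matching without replacement.

    Treated units are processed in seeded random order; each is paired with
    the unmatched control of smallest |PS difference| if that difference is
    within ``caliper_fraction x SD(PS)`` (sample SD over all patients, on
    the chosen scale).  Equidistant candidates are broken by lowest id.
    Unmatched treated units are dropped and counted.
    """
    if caliper_fraction <= 0:
        raise ValueError("caliper_fraction must be > 0")
    if isinstance(ps, PropensityFit):
        ps = ps.ps
    if isinstance(treatment, pd.Series) and ids is None:
        ids = treatment.index
    t = np.asarray(treatment, dtype=int)
    p = np.asarray(ps, dtype=float)
    if not np.isfinite(p).all():
        raise ValueError("propensity scores must be finite")
    if ids is None:
        ids = np.arange(len(p))
    ids = np.asarray(ids)

    if scale == "logit":
        m = _logit_fn(np.clip(p, 1e-12, 1 - 1e-12))
    elif scale == "probability":
        m = p
    else:
        raise ValueError(f"unknown caliper scale {scale!r}")
    caliper = caliper_fraction * float(np.std(m, ddof=1))

    t_idx = np.flatnonzero(t == 1)
    c_idx = np.flatnonzero(t == 0)
    if len(t_idx) == 0 or len(c_idx) == 0:
        raise MatchingError("one treatment group is empty")

    # controls sorted by (score, id) so scanning finds lowest-id ties first
    c_order = np.lexsort((ids[c_idx].astype(str), m[c_idx]))
    c_sorted = c_idx[c_order]
    c_scores = m[c_sorted]
    alive = np.ones(len(c_sorted), dtype=bool)
    n_alive = len(c_sorted)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(t_idx))
    pairs = []
    unmatched = 0
    for oi in order:
        ti = t_idx[oi]
        if n_alive == 0:
            unmatched += 1
            continue
        target = m[ti]
        pos = int(np.searchsorted(c_scores, target))
        left = pos - 1
        while left >= 0 and not alive[left]:
            left -= 1
        if left >= 0:
            # scanning left lands on the highest-id member of an equal-score
            # run; the contract is lowest id, i.e. the run's first alive entry
            run_start = int(np.searchsorted(c_scores, c_scores[left], side="left"))
            while not alive[run_start]:
                run_start += 1
            left = run_start
        right = pos
        while right < len(c_sorted) and not alive[right]:
            right += 1
        best = -1
        if left >= 0 and right < len(c_sorted):
            dl = abs(target - c_scores[left])
            dr = abs(c_scores[right] - target)
            if dl < dr:
                best = left
            elif dr < dl:
                best = right
            else:  # equidistant: lowest id wins
                best = (
                    left
                    if str(ids[c_sorted[left]]) <= str(ids[c_sorted[right]])
                    else right
                )
        elif left >= 0:
            best = left
        elif right < len(c_sorted):
            best = right
        if best < 0 or abs(c_scores[best] - target) > caliper:
            unmatched += 1
            continue
        ci = c_sorted[best]
        alive[best] = False
        n_alive -= 1
        pairs.append((ids[ti], ids[ci], p[ti], p[ci]))

    if not pairs:
        raise MatchingError(
            f"zero pairs formed under caliper {caliper:.3g} ({scale} scale)"
        )
    pairs_df = pd.DataFrame(
        pairs, columns=["treated_id", "control_id", "ps_treated", "ps_control"]
    )
    return MatchedCohort(
        pairs=pairs_df,
        caliper=caliper,
        scale=scale,
        n_treated_unmatched=unmatched,
        treated_order=[ids[t_idx[oi]] for oi in order],
        ps=pd.Series(p, index=ids),
    )


def smd(
    values: pd.Series,
    treatment: pd.Series,
    matched: MatchedCohort | None = None,
) -> float:
    """Standardised mean difference |mean_t - mean_c| / pooled SD.

    Pooled SD is ``sqrt((s_t^2 + s_c^2) / 2)``; binary variables use the
    ``p (1 - p)`` variance.  With ``matched`` supplied, computed over matched
    units only.  Returns 0 when the pooled SD is 0 and the means are equal,
    and ``inf`` when it is 0 but the means differ.
    """
    values = pd.Series(values)
    treatment = pd.Series(treatment)
    if matched is not None:
        x_t = values.loc[matched.pairs["treated_id"]].to_numpy(dtype=float)
        x_c = values.loc[matched.pairs["control_id"]].to_numpy(dtype=float)
    else:
        t = treatment.to_numpy(dtype=int)
        x = values.to_numpy(dtype=float)
        x_t, x_c = x[t == 1], x[t == 0]
    if len(x_t) == 0 or len(x_c) == 0:
        raise ValueError("both groups must be nonempty for an SMD")
    binary = set(np.unique(np.concatenate([x_t, x_c]))) <= {0.0, 1.0}
    if binary:
        v_t = x_t.mean() * (1 - x_t.mean())
        v_c = x_c.mean() * (1 - x_c.mean())
    else:
        v_t = x_t.var(ddof=1) if len(x_t) > 1 else 0.0
        v_c = x_c.var(ddof=1) if len(x_c) > 1 else 0.0
    pooled = np.sqrt((v_t + v_c) / 2.0)
    diff = abs(float(x_t.mean() - x_c.mean()))
    if pooled == 0:
        return 0.0 if diff == 0 else float("inf")
    return diff / pooled


def matched_cstat(
    features: pd.DataFrame,
    treatment: pd.Series,
    spec: ModelSpec,
    matched: MatchedCohort | None = None,
    **fit_kwargs,
) -> float:
    """AUC of a treatment model refit within the matched cohort.

    The propensity model with ``spec``'s covariates is refit on the matched
    subset only and its scores are scored against treatment (ties counted
    half); 0.5 indicates full covariate balance.  With ``matched=None`` the
    model is fit and evaluated on the whole cohort (the unmatched
    c-statistic).
    """
    if matched is not None:
        ids = matched.matched_ids()
        sub = features.loc[ids]
        t = treatment.loc[ids]
    else:
        sub, t = features, treatment
    fit = fit_propensity(sub, t, spec, **fit_kwargs)
    return float(roc_auc_score(np.asarray(t, dtype=int), fit.ps))


@dataclass
class EffectEstimate:
    """Point estimate with percentile-bootstrap 95% CI."""

    estimand: str
    point: float
    ci_low: float
    ci_high: float
    n: int
    n_boot: int


def _boot_mean_diffs(
    y_t: np.ndarray, y_c: np.ndarray, paired: bool, n_boot: int,
    rng: np.random.Generator, chunk: int = 250,
) -> np.ndarray:
    diffs = np.empty(n_boot)
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        if paired:
            idx = rng.integers(0, len(y_t), size=(b, len(y_t)))
            diffs[done : done + b] = y_t[idx].mean(axis=1) - y_c[idx].mean(axis=1)
        else:
            it = rng.integers(0, len(y_t), size=(b, len(y_t)))
            ic = rng.integers(0, len(y_c), size=(b, len(y_c)))
            diffs[done : done + b] = y_t[it].mean(axis=1) - y_c[ic].mean(axis=1)
        done += b
    return diffs


def estimate_effect(
    outcome: pd.Series,
    treatment: pd.Series,
    matched: MatchedCohort | None = None,
    n_boot: int = 1000,
    seed: int | Sequence[int] = 0,
    estimand: str | None = None,
) -> EffectEstimate:
    """Treated-minus-control outcome difference with bootstrap 95% CI.

    Binary outcomes give a risk difference, continuous ones a mean
    difference.  With a matched cohort, matched *pairs* are resampled;
    otherwise patients are resampled within each arm.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    outcome = pd.Series(outcome)
    treatment = pd.Series(treatment)
    if matched is not None:
        y_t = outcome.loc[matched.pairs["treated_id"]].to_numpy(dtype=float)
        y_c = outcome.loc[matched.pairs["control_id"]].to_numpy(dtype=float)
        paired = True
        n = len(y_t)
    else:
        t = treatment.to_numpy(dtype=int)
        y = outcome.to_numpy(dtype=float)
        y_t, y_c = y[t == 1], y[t == 0]
        paired = False
        n = len(y)
    if len(y_t) == 0 or len(y_c) == 0:
        raise ValueError("both groups must be nonempty")
    if estimand is None:
        binary = set(np.unique(np.concatenate([y_t, y_c]))) <= {0.0, 1.0}
        estimand = "risk_difference" if binary else "mean_difference"
    point = float(y_t.mean() - y_c.mean())
    rng = np.random.default_rng(seed)
    diffs = _boot_mean_diffs(y_t, y_c, paired, n_boot, rng)
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return EffectEstimate(
        estimand=estimand,
        point=point,
        ci_low=float(lo),
        ci_high=float(hi),
        n=n,
        n_boot=n_boot,
    )
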
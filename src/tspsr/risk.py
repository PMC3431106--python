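"""Nearest-prototype risk stratification and its clinical evaluation.

A 1-nearest-neighbor classifier (Euclidean distance) is trained on the
normal-adjacent and metastatic samples over the top t-test-ranked
differentially expressed features of the normal-vs-metastasis contrast, then
applied to the primary tumors: each primary is labeled ``normal_like`` or
``metastasis_like`` by its closest prototype.  The two predicted classes are
compared on the biochemical-recurrence (BCR) endpoint with Kaplan–Meier
curves and the log-rank test, and in a multivariable logistic model of the
BCR event adjusted for the nomogram class (probability > 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.spatial.distance import cdist

from .annotation import ExpressionStudy
from .diffexp import ComparisonResult

NORMAL_LIKE = "normal_like"
METASTASIS_LIKE = "metastasis_like"

_LABEL_OF_GROUP = {"NORMAL": NORMAL_LIKE, "METASTASIS": METASTASIS_LIKE}


def rank_features(result: ComparisonResult, n: int) -> list[str]:
    """Top-n DE features of a contrast ranked by ascending p.

    Ties broken by descending |t| then id.  Raises if the contrast produced
    no DE features; warns when fewer than ``n`` exist.
    """
    de = result.table[result.table["de"]].copy()
    if de.empty:
        raise ValueError(
            "no differentially expressed features; relax fdr/mfd thresholds"
        )
    de["neg_abs_t"] = -de["t"].abs()
    de["_id"] = de.index
    ranked = de.sort_values(["p", "neg_abs_t", "_id"]).index.tolist()
    if len(ranked) < n:
        warnings.warn(f"only {len(ranked)} DE features available, fewer than {n}")
    return ranked[:n]


@dataclass
class KnnModel:
    """k=1 Euclidean nearest-prototype model over a fixed feature list."""

    reference: pd.DataFrame  # features x training samples
    labels: pd.Series  # per training sample: NORMAL | METASTASIS
    features: list[str]

    def __post_init__(self) -> None:
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate feature ids")
        unlabeled = set(self.reference.columns) - set(self.labels.index)
        if unlabeled:
            raise ValueError(f"unlabeled reference samples: {sorted(unlabeled)}")


def train_knn(
    study: ExpressionStudy, features: Sequence[str]
) -> KnnModel:
    """Train on the normal-adjacent + metastatic samples of the study."""
    train_ids = study.group_ids("NORMAL") + study.group_ids("METASTASIS")
    labels = pd.Series(
        {s.sample_id: s.group for s in study.samples if s.sample_id in set(train_ids)}
    )
    return KnnModel(
        reference=study.matrix.loc[list(features), train_ids],
        labels=labels,
        features=list(features),
    )


def knn_classify(model: KnnModel, query: pd.DataFrame) -> pd.Series:
    """Label each query column by its single nearest reference column.

    Exact distance ties go to the reference with the lexicographically
    smallest sample id (warned).  Returns ``normal_like``/``metastasis_like``
    per query sample.
    """
    missing = [f for f in model.features if f not in query.index]
    if missing:
        raise ValueError(f"query lacks features: {missing}")
    # stable lexicographic column order makes the argmin tie-break deterministic
    ref_cols = sorted(model.reference.columns)
    ref = model.reference.loc[model.features, ref_cols].to_numpy(dtype=float).T
    q = query.loc[model.features].to_numpy(dtype=float).T
    d = cdist(q, ref, metric="euclidean")
    nearest = d.argmin(axis=1)
    ties = (d == d[np.arange(len(q)), nearest][:, None]).sum(axis=1) > 1
    if ties.any():
        warnings.warn(
            f"{int(ties.sum())} queries at an exact distance tie; "
            "assigned the lexicographically first reference"
        )
    labels = [
        _LABEL_OF_GROUP[model.labels[ref_cols[j]]] for j in nearest
    ]
    return pd.Series(labels, index=query.columns, name="predicted_class")


# ---------------------------------------------------------------------------
# survival


def km_estimate(
    times: Sequence[float],
    events: Sequence[bool],
    group_labels: Sequence[str],
) -> dict[str, pd.DataFrame]:
    """Kaplan–Meier product-limit curves per group.

    Returns, per group, a table with columns time, at_risk, events, survival
    (one row per observed time, survival right-continuous).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    group_labels = np.asarray(group_labels)
    out: dict[str, pd.DataFrame] = {}
    for g in np.unique(group_labels):
        mask = group_labels == g
        if not mask.any():
            raise ValueError(f"group {g} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        table = kmf.event_table
        table = table[table["removed"] > 0]  # drop the t=0 entrance row
        surv = kmf.survival_function_["KM_estimate"]
        out[str(g)] = pd.DataFrame(
            {
                "time": table.index.to_numpy(dtype=float),
                "at_risk": table["at_risk"].to_numpy(dtype=int),
                "events": table["observed"].to_numpy(dtype=int),
                "survival": surv.reindex(table.index).to_numpy(dtype=float),
            }
        ).reset_index(drop=True)
    return out


def logrank(
    times: Sequence[float],
    events: Sequence[bool],
    group_labels: Sequence[str],
) -> dict[str, float]:
    """Two-group log-rank test (1 df chi-square)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    group_labels = np.asarray(group_labels)
    groups = sorted(np.unique(group_labels).tolist())
    if len(groups) != 2:
        raise ValueError(f"log-rank needs exactly two groups, got {groups}")
    m0, m1 = group_labels == groups[0], group_labels == groups[1]
    if not m0.any() or not m1.any():
        raise ValueError("a group has zero subjects")
    res = _ll_logrank(times[m0], times[m1], events[m0], events[m1])
    return {"chi_square": float(res.test_statistic), "p": float(res.p_value)}


@dataclass
class LogisticSummary:
    covariate: str
    odds_ratio: float
    ci95: tuple[float, float]
    p: float
    separation: bool = False


def fit_logistic(
    outcome: Sequence[bool], covariates: pd.DataFrame, maxiter: int = 50, tol: float = 1e-8
) -> list[LogisticSummary]:
    """Multivariable logistic regression with Wald 95% CIs on the OR scale.

    Complete separation is flagged per model (infinite-bound CIs survive in
    the output rather than crashing).
    """
    y = np.asarray(outcome, dtype=float)
    X = sm.add_constant(covariates.astype(float), has_constant="add")
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=maxiter, tol=tol)
        except Exception:
            # perfect separation or singular Hessian: a gradient method still
            # yields (diverging) estimates; Wald machinery degrades gracefully
            separation = True
            fit = sm.Logit(y, X).fit(disp=0, method="bfgs", maxiter=200)
    params = np.asarray(fit.params, dtype=float)
    if np.abs(params).max() > 15:  # coefficients diverging toward +/- infinity
        separation = True
    try:
        cov = np.asarray(fit.cov_params(), dtype=float)
        se = np.sqrt(np.diag(cov))
        pvals = np.asarray(fit.pvalues, dtype=float)
    except Exception:
        se = np.full_like(params, np.inf)
        pvals = np.full_like(params, np.nan)
    out = []
    z = 1.959963984540054  # Phi^{-1}(0.975)
    for i, name in enumerate(X.columns):
        if name == "const":
            continue
        beta, s = params[i], se[i]
        out.append(
            LogisticSummary(
                covariate=str(name),
                odds_ratio=float(np.exp(beta)),
                ci95=(float(np.exp(beta - z * s)), float(np.exp(beta + z * s))),
                p=float(pvals[i]),
                separation=separation,
            )
        )
    return out


# ---------------------------------------------------------------------------
# end-to-end stratification


@dataclass
class RiskStratification:
    predicted_class: pd.Series  # per primary sample
    km: dict[str, pd.DataFrame]
    logrank: dict[str, float]
    logistic: list[LogisticSummary] = field(default_factory=list)
    features: list[str] = field(default_factory=list)


def stratify(
    study: ExpressionStudy,
    nvsm_result: ComparisonResult,
    top_n: int = 100,
    feature_ids: Optional[Sequence[str]] = None,
    matrix: Optional[pd.DataFrame] = None,
    nomogram_cutoff: float = 0.5,
) -> RiskStratification:
    """Train on normal+metastasis, classify primaries, evaluate on BCR.

    ``feature_ids``/``matrix`` override the default TS-PSR features with, e.g.,
    gene-level features and their summarized matrix.
    """
    features = list(feature_ids) if feature_ids is not None else rank_features(
        nvsm_result, top_n
    )
    mat = matrix if matrix is not None else study.matrix
    train_ids = study.group_ids("NORMAL") + study.group_ids("METASTASIS")
    labels = pd.Series({s.sample_id: s.group for s in study.samples}).loc[train_ids]
    model = KnnModel(
        reference=mat.loc[features, train_ids], labels=labels, features=features
    )
    primaries = study.primary_records()
    primary_ids = [s.sample_id for s in primaries]
    predicted = knn_classify(model, mat.loc[features, primary_ids])

    times = [s.bcr_time for s in primaries]
    events = [s.bcr_event for s in primaries]
    groups_present = set(predicted)
    if len(groups_present) == 2:
        km = km_estimate(times, events, predicted.to_numpy())
        lr = logrank(times, events, predicted.to_numpy())
    else:  # degenerate: every primary on one side; report the single curve
        warnings.warn("all primaries classified into one class; log-rank undefined")
        km = km_estimate(times, events, predicted.to_numpy())
        lr = {"chi_square": float("nan"), "p": float("nan")}

    covs = pd.DataFrame(
        {
            "knn_positive": (predicted.loc[primary_ids] == METASTASIS_LIKE).astype(int),
            "nomogram_positive": [
                int(s.nomogram_prob is not None and s.nomogram_prob > nomogram_cutoff)
                for s in primaries
            ],
        },
        index=primary_ids,
    )
    if covs.nunique().min() < 2:
        warnings.warn("a covariate is constant; logistic model skipped")
        logistic: list[LogisticSummary] = []
    else:
        logistic = fit_logistic(events, covs)
    return RiskStratification(
        predicted_class=predicted, km=km, logrank=lr, logistic=logistic, features=features
    )
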
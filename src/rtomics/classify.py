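"""Univariate and multivariate biomarker-panel classification.

Univariate screening treats each feature on its own: the empirical ROC AUC
over all samples (pair-counting, ties half-weighted, reported after
orientation so AUC >= 0.5) and a single-feature logistic regression scored
by leave-one-out cross-validation with balanced accuracy, the mean of
sensitivity (TPR) and specificity (TNR), so group size does not bias it.

The multivariate builder mirrors web-tool style biomarker exploration:
Monte-Carlo cross-validation with balanced subsampling.  Each iteration
draws the same fraction of every class into training, ranks all features
by the absolute weight of a linear SVM fit on the (re-standardized)
training split, then fits one linear SVM per requested panel size on the
top-k features and scores the held-out samples with a logistic link on the
signed decision value.  Per panel size the held-out probabilities are
averaged per sample, the AUC is computed from the averaged probabilities
with a 95% band from the per-iteration AUC distribution, and each
feature's selection frequency across iterations is recorded — the
frequency rank that orders the reported biomarker panel.

The poor-responder class (PR) is the positive class throughout: poor
response is the clinically actionable detection target.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from .tables import CohortMetadata, FeatureTable

logger = logging.getLogger(__name__)

DEFAULT_PANEL_SIZES = (5, 10, 15, 25, 50, 100)
POSITIVE_CLASS = "PR"


@dataclass
class UnivariateClassifierRecord:
    feature_id: str
    auc: float
    tpr: float
    tnr: float
    balanced_accuracy: float
    degenerate: bool = False


@dataclass
class PanelResult:
    panel_size: int
    auc: float
    auc_ci: tuple[float, float]
    predictive_accuracy: float
    per_sample_probability: pd.Series  # averaged P(positive class)
    feature_frequency: pd.Series       # selection frequency in [0, 1]
    mean_weight_rank: pd.Series        # mean |weight| rank over selections
    per_iteration_auc: np.ndarray

    @property
    def top_features(self) -> pd.DataFrame:
        """Features sorted by selection frequency, ties by mean |weight| rank."""
        df = pd.DataFrame({
            "frequency": self.feature_frequency,
            "mean_weight_rank": self.mean_weight_rank,
        })
        return df.sort_values(["frequency", "mean_weight_rank"],
                              ascending=[False, True], kind="stable")


def univariate_auc(values, labels, positive: str = POSITIVE_CLASS) -> tuple[float, str]:
    """Empirical AUC by pair counting, oriented so AUC >= 0.5.

    AUC = (#{positive_i > negative_j} + ties/2) / (n_pos * n_neg) via the
    rank formulation; missing values are dropped pairwise.  Returns
    (oriented AUC, direction) where direction records which class the raw
    statistic favoured ("up-in-<positive>" or "down-in-<positive>").
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    keep = ~np.isnan(x)
    x, y = x[keep], y[keep]
    pos, neg = x[y == positive], x[y != positive]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(np.concatenate([pos, neg]))
    u_pos = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    auc = u_pos / (len(pos) * len(neg))
    direction = f"up-in-{positive}" if auc >= 0.5 else f"down-in-{positive}"
    return float(max(auc, 1.0 - auc)), direction


def loo_single_feature(
    values, labels, positive: str = POSITIVE_CLASS, ridge_c: float = 1e4
) -> UnivariateClassifierRecord:
    """Leave-one-out single-feature logistic regression.

    A fixed small ridge (C = ``ridge_c``) keeps the fit defined under
    complete separation.  Zero-variance features carry no information and
    are scored at chance (0.5) rather than fed through LOO, where the
    intercept-only majority vote would always oppose the held-out sample.
    """
    x = np.asarray(values, dtype=float)
    y = (np.asarray(labels) == positive).astype(int)
    keep = ~np.isnan(x)
    x, y = x[keep], y[keep]
    if y.sum() < 3 or (1 - y).sum() < 3:
        raise ValueError("need >=3 samples per class for LOO")
    fid = ""
    if np.ptp(x) == 0:
        return UnivariateClassifierRecord(fid, 0.5, 0.5, 0.5, 0.5, degenerate=True)
    preds = np.empty(len(y), dtype=int)
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        clf = LogisticRegression(C=ridge_c, solver="liblinear")
        clf.fit(x[mask, None], y[mask])
        preds[i] = int(clf.predict_proba(x[i, None, None])[0, 1] >= 0.5)
    tpr = float(preds[y == 1].mean())
    tnr = float(1.0 - preds[y == 0].mean())
    auc, _ = univariate_auc(x, np.where(y == 1, positive, "other"), positive)
    return UnivariateClassifierRecord(fid, auc, tpr, tnr, (tpr + tnr) / 2.0)


def univariate_screen(
    table: FeatureTable, metadata: CohortMetadata, positive: str = POSITIVE_CLASS
) -> pd.DataFrame:
    """AUC + LOO balanced accuracy for every feature of a transformed table."""
    y = metadata.groups.reindex(table.sample_ids).to_numpy()
    rows = []
    for fid, row in table.values.iterrows():
        try:
            rec = loo_single_feature(row.to_numpy(), y, positive)
        except ValueError:
            continue
        rec.feature_id = fid
        rows.append(vars(rec))
    return pd.DataFrame(rows).set_index("feature_id")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _standardize_split(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def mccv_panels(
    table: FeatureTable,
    metadata: CohortMetadata,
    sizes=DEFAULT_PANEL_SIZES,
    n_iterations: int = 100,
    train_fraction: float = 2.0 / 3.0,
    seed: int = 0,
    c: float = 1.0,
    positive: str = POSITIVE_CLASS,
) -> list[PanelResult]:
    """Monte-Carlo cross-validated linear-SVM biomarker panels.

    ``table`` must already be autoscaled with missing values imputed.
    Features are re-standardized inside every training split so no
    information leaks from the cohort-level scaling.
    """
    X = table.values.to_numpy(dtype=float).T  # samples x features
    if np.isnan(X).any():
        raise ValueError("mccv_panels requires an imputed table (no missing values)")
    feature_ids = pd.Index(table.feature_ids)
    samples = pd.Index(table.sample_ids)
    y = (metadata.groups.reindex(samples).to_numpy() == positive).astype(int)
    classes = [np.flatnonzero(y == 0), np.flatnonzero(y == 1)]
    n_train = [int(round(train_fraction * len(ix))) for ix in classes]
    for ix, nt in zip(classes, n_train):
        if nt < 3:
            raise ValueError("train_fraction leaves <3 training samples in a class")
        if nt >= len(ix):
            raise ValueError("train_fraction must leave >=1 held-out sample per class")
    sizes = sorted(set(sizes))
    eff_sizes = []
    for k in sizes:
        if k >= X.shape[1]:
            logger.warning("panel size %d >= %d features; truncated", k, X.shape[1])
            k = X.shape[1]
        if k not in eff_sizes:
            eff_sizes.append(k)

    rng = np.random.default_rng(seed)
    n_feat = X.shape[1]
    sel_counts = {k: np.zeros(n_feat) for k in eff_sizes}
    rank_sums = {k: np.zeros(n_feat) for k in eff_sizes}
    prob_sum = {k: np.zeros(len(y)) for k in eff_sizes}
    prob_cnt = {k: np.zeros(len(y)) for k in eff_sizes}
    iter_auc = {k: [] for k in eff_sizes}

    for _ in range(n_iterations):
        train_idx = np.concatenate([
            rng.choice(ix, size=nt, replace=False) for ix, nt in zip(classes, n_train)
        ])
        test_mask = np.ones(len(y), dtype=bool)
        test_mask[train_idx] = False
        test_idx = np.flatnonzero(test_mask)
        Xtr, Xte = _standardize_split(X[train_idx], X[test_idx])
        ytr, yte = y[train_idx], y[test_idx]

        ranker = LinearSVC(C=c, max_iter=20000)
        ranker.fit(Xtr, ytr)
        w = np.abs(ranker.coef_.ravel())
        order = np.argsort(-w, kind="stable")  # descending |weight|
        weight_rank = np.empty(n_feat)
        weight_rank[order] = np.arange(1, n_feat + 1)

        for k in eff_sizes:
            top = order[:k]
            sel_counts[k][top] += 1
            rank_sums[k][top] += weight_rank[top]
            clf = LinearSVC(C=c, max_iter=20000)
            clf.fit(Xtr[:, top], ytr)
            p = _sigmoid(clf.decision_function(Xte[:, top]))
            prob_sum[k][test_idx] += p
            prob_cnt[k][test_idx] += 1
            if len(np.unique(yte)) == 2:
                # per-iteration AUC is the raw (unoriented) held-out discrimination
                iter_auc[k].append(_raw_auc(p, yte))

    results = []
    for k in eff_sizes:
        cnt = np.maximum(prob_cnt[k], 1)
        avg_prob = prob_sum[k] / cnt
        seen = prob_cnt[k] > 0
        auc = _raw_auc(avg_prob[seen], y[seen])
        aucs = np.asarray(iter_auc[k])
        ci = (float(np.percentile(aucs, 2.5)), float(np.percentile(aucs, 97.5)))
        pred = (avg_prob >= 0.5).astype(int)
        tpr = pred[(y == 1) & seen].mean() if ((y == 1) & seen).any() else math.nan
        tnr = 1.0 - pred[(y == 0) & seen].mean() if ((y == 0) & seen).any() else math.nan
        freq = pd.Series(sel_counts[k] / n_iterations, index=feature_ids)
        with np.errstate(invalid="ignore"):
            mean_rank = pd.Series(
                np.where(sel_counts[k] > 0, rank_sums[k] / np.maximum(sel_counts[k], 1), np.inf),
                index=feature_ids,
            )
        results.append(PanelResult(
            panel_size=k,
            auc=float(auc),
            auc_ci=ci,
            predictive_accuracy=float((tpr + tnr) / 2.0),
            per_sample_probability=pd.Series(avg_prob, index=samples),
            feature_frequency=freq,
            mean_weight_rank=mean_rank,
            per_iteration_auc=aucs,
        ))
    return results


def _raw_auc(scores: np.ndarray, y01: np.ndarray) -> float:
    ranks = rankdata(scores)
    n1 = int(y01.sum())
    n0 = len(y01) - n1
    u = ranks[y01 == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def panel_report(
    results: list[PanelResult], n_features: int = 20, reporting_size: int | None = None
) -> tuple[PanelResult, pd.DataFrame]:
    """Pick the reporting panel and emit its ranked biomarker table.

    Default reporting size is the panel with maximum AUC (ties broken
    toward the smaller panel); the table lists the top ``n_features`` by
    selection frequency then mean |weight| rank.
    """
    if not results:
        raise ValueError("no panel results")
    if reporting_size is None:
        best = min(results, key=lambda r: (-r.auc, r.panel_size))
    else:
        match = [r for r in results if r.panel_size == reporting_size]
        if not match:
            raise ValueError(f"no panel of size {reporting_size}")
        best = match[0]
    return best, best.top_features.head(n_features)
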
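"""Adaptive univariate differential-abundance analysis.

For each feature the test is chosen from the data: if both groups pass a
Shapiro-Wilk normality gate and a Brown-Forsythe (median-centered Levene)
homoscedasticity gate, the pooled-variance t-test is used; if both pass
normality but variances differ, the Welch test; if either group looks
non-normal, the two-sided Mann-Whitney U test.  Effect sizes are paired to
the test (Hedges' g for t/Welch, rank-biserial correlation for
Mann-Whitney) and two fold-change estimators are reported: the classical
ratio of group means and the Hodges-Lehmann-type median of all pairwise
between-group ratios.  Benjamini-Hochberg adjustment runs once across the
omics layer; features are flagged significant at raw p < alpha and,
separately, at q < alpha.

Features detected in only one group cannot be tested and are reported via
the group-exclusivity rule instead.  Clinical covariates get the matching
classical comparisons: gated t-test for continuous covariates, Fisher's
exact test for 2x2 contingency tables, Pearson chi-square (no continuity
correction) for larger tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables import CohortMetadata, FeatureTable

logger = logging.getLogger(__name__)

TestName = Literal["t", "welch", "mann-whitney"]

EFFECT_BANDS = {
    # |effect| thresholds for medium / high, per effect type
    "hedges_g": (0.5, 0.8),
    "rank_biserial": (0.3, 0.5),
}


@dataclass
class DifferentialRecord:
    feature_id: str
    test_used: str | None
    p_value: float
    p_adjusted: float = math.nan
    effect_type: str | None = None
    effect_value: float = math.nan
    effect_magnitude: str | None = None
    fc_classical: float = math.nan
    fc_hl: float = math.nan
    direction: str | None = None  # up-in-GR | up-in-PR
    exclusive_group: str = "none"
    n_a: int = 0
    n_b: int = 0


@dataclass
class ClinicalComparison:
    covariate: str
    test: str  # t | welch | mann-whitney | fisher-exact | chi-square
    statistic: float
    p_value: float


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[~np.isnan(x)]


def choose_test(group_a, group_b, alpha_gate: float = 0.05) -> TestName:
    """Select t / welch / mann-whitney from normality and variance gates."""
    a, b = _clean(group_a), _clean(group_b)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >=3 observed values per group to gate the test")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return "mann-whitney"  # Shapiro undefined for constant input
    normal = (stats.shapiro(a).pvalue > alpha_gate) and (stats.shapiro(b).pvalue > alpha_gate)
    if not normal:
        return "mann-whitney"
    homosked = stats.levene(a, b, center="median").pvalue > alpha_gate
    return "t" if homosked else "welch"


def compare_feature(group_a, group_b, test: TestName) -> float:
    """Two-sided p-value for the chosen test.

    Mann-Whitney uses the exact null distribution for small groups (either
    n < 8) when the data are tie-free, and the tie-corrected normal
    approximation otherwise.
    """
    a, b = _clean(group_a), _clean(group_b)
    if len(a) and len(b) and np.ptp(np.concatenate([a, b])) == 0:
        return 1.0
    if test == "t":
        p = stats.ttest_ind(a, b, equal_var=True).pvalue
    elif test == "welch":
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
    elif test == "mann-whitney":
        small = min(len(a), len(b)) < 8
        ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = "exact" if (small and not ties) else "asymptotic"
        p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(min(p, 1.0))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j>=i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def hedges_g(group_a, group_b) -> float:
    """Bias-corrected standardized mean difference (a minus b).

    g = J * (mean_a - mean_b) / s_pooled with J = 1 - 3/(4n - 9).
    """
    a, b = _clean(group_a), _clean(group_b)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("need >=2 values per group for Hedges' g")
    s2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if s2 == 0:
        return math.nan
    j = 1.0 - 3.0 / (4.0 * (na + nb) - 9.0)
    return float(j * (a.mean() - b.mean()) / math.sqrt(s2))


def rank_biserial(group_a, group_b) -> float:
    """Rank-biserial correlation, 2*U_a/(n_a*n_b) - 1, with half-weight ties."""
    a, b = _clean(group_a), _clean(group_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("need >=1 value per group")
    u_a = stats.mannwhitneyu(a, b, alternative="two-sided").statistic
    return float(2.0 * u_a / (len(a) * len(b)) - 1.0)


def effect_magnitude(value: float, effect_type: str) -> str | None:
    if math.isnan(value):
        return None
    med, high = EFFECT_BANDS[effect_type]
    v = abs(value)
    return "high" if v >= high else "medium" if v >= med else "small"


def fold_change(group_a, group_b, estimator: str = "classical") -> float:
    """Group-a over group-b abundance ratio.

    ``classical`` is the ratio of group means; ``hodges-lehmann`` the median
    over all n_a*n_b pairwise ratios a_i/b_j (robust to outliers).
    """
    a, b = _clean(group_a), _clean(group_b)
    if len(a) == 0 or len(b) == 0:
        return math.nan
    if estimator == "classical":
        mb = b.mean()
        return float(a.mean() / mb) if mb != 0 else math.nan
    if estimator == "hodges-lehmann":
        if np.any(b == 0):
            b = b[b != 0]
            if len(b) == 0:
                return math.nan
        return float(np.median(np.divide.outer(a, b)))
    raise ValueError(f"unknown estimator {estimator!r}")


def detect_group_exclusive(
    table: FeatureTable,
    metadata: CohortMetadata,
    min_detected: int | None = None,
) -> pd.Series:
    """Flag features observed only in one group.

    A feature is exclusive to group G if it is detected in >= min_detected
    samples of G and zero samples of the other group.  Default
    ``min_detected`` is half the (smaller) group size.
    """
    labels = sorted(metadata.groups.unique())
    det = table.detected()
    counts = {g: det[[s for s in metadata.group_samples(g) if s in det.columns]].sum(axis=1)
              for g in labels}
    if min_detected is None:
        min_detected = min(len(metadata.group_samples(g)) for g in labels) // 2
    flags = pd.Series("none", index=table.values.index, dtype=object)
    g0, g1 = labels
    flags[(counts[g0] >= min_detected) & (counts[g1] == 0)] = g0
    flags[(counts[g1] >= min_detected) & (counts[g0] == 0)] = g1
    return flags


def call_differential(
    table: FeatureTable,
    metadata: CohortMetadata,
    alpha: float = 0.05,
    alpha_gate: float = 0.05,
    group_order: tuple[str, str] = ("GR", "PR"),
    min_detected: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the adaptive procedure across an omics layer.

    Returns a per-feature records table (one :class:`DifferentialRecord`
    per row; fold changes oriented first-listed group over second) and a
    summary dict with DAP/DAM-style counts at raw p < alpha and q < alpha,
    direction tallies, exclusives, and skipped features.
    """
    ga, gb = group_order
    sa = [s for s in metadata.group_samples(ga) if s in table.values.columns]
    sb = [s for s in metadata.group_samples(gb) if s in table.values.columns]
    if not sa or not sb:
        raise ValueError(f"both groups must be present among table samples ({ga}, {gb})")
    exclusive = detect_group_exclusive(table, metadata, min_detected)

    records: list[DifferentialRecord] = []
    n_skipped = 0
    for fid, row in table.values.iterrows():
        a, b = _clean(row[sa]), _clean(row[sb])
        rec = DifferentialRecord(feature_id=fid, test_used=None, p_value=math.nan,
                                 exclusive_group=exclusive[fid], n_a=len(a), n_b=len(b))
        if exclusive[fid] != "none" or len(a) < 3 or len(b) < 3:
            if exclusive[fid] == "none":
                n_skipped += 1
            records.append(rec)
            continue
        loga, logb = np.log(a[a > 0]), np.log(b[b > 0])
        test = choose_test(loga, logb, alpha_gate)
        rec.test_used = test
        rec.p_value = compare_feature(loga, logb, test)
        if test in ("t", "welch"):
            rec.effect_type = "hedges_g"
            rec.effect_value = hedges_g(loga, logb)
        else:
            rec.effect_type = "rank_biserial"
            rec.effect_value = rank_biserial(loga, logb)
        rec.effect_magnitude = effect_magnitude(rec.effect_value, rec.effect_type)
        rec.fc_classical = fold_change(a, b, "classical")
        rec.fc_hl = fold_change(a, b, "hodges-lehmann")
        diff = loga.mean() - logb.mean()
        rec.direction = f"up-in-{ga}" if diff > 0 else f"up-in-{gb}"
        records.append(rec)

    df = pd.DataFrame([vars(r) for r in records]).set_index("feature_id")
    tested = df["p_value"].notna()
    if tested.any():
        df.loc[tested, "p_adjusted"] = bh_adjust(df.loc[tested, "p_value"].to_numpy())
    df["significant_raw"] = df["p_value"] < alpha
    df["significant_fdr"] = df["p_adjusted"] < alpha
    if n_skipped:
        logger.warning("skipped %d feature(s) with <3 observations in a group", n_skipped)

    summary = {
        "n_features": int(len(df)),
        "n_tested": int(tested.sum()),
        "n_skipped": n_skipped,
        "n_significant_raw": int(df["significant_raw"].sum()),
        "n_significant_fdr": int(df["significant_fdr"].sum()),
        f"n_up_in_{ga}_raw": int((df["significant_raw"] & (df["direction"] == f"up-in-{ga}")).sum()),
        f"n_up_in_{gb}_raw": int((df["significant_raw"] & (df["direction"] == f"up-in-{gb}")).sum()),
        f"n_up_in_{ga}_fdr": int((df["significant_fdr"] & (df["direction"] == f"up-in-{ga}")).sum()),
        f"n_up_in_{gb}_fdr": int((df["significant_fdr"] & (df["direction"] == f"up-in-{gb}")).sum()),
        f"n_exclusive_{ga}": int((df["exclusive_group"] == ga).sum()),
        f"n_exclusive_{gb}": int((df["exclusive_group"] == gb).sum()),
    }
    return df, summary


# ---------------------------------------------------------------------------
# Clinical metadata comparisons (Table-1 style)
# ---------------------------------------------------------------------------

def compare_contingency(table_2xk: np.ndarray) -> tuple[str, float, float]:
    """Fisher exact for 2x2 tables, Pearson chi-square (uncorrected) otherwise."""
    t = np.asarray(table_2xk)
    if t.shape == (2, 2):
        res = stats.fisher_exact(t, alternative="two-sided")
        return "fisher-exact", float(res.statistic), float(res.pvalue)
    res = stats.chi2_contingency(t, correction=False)
    return "chi-square", float(res.statistic), float(res.pvalue)


def compare_clinical(
    metadata: CohortMetadata,
    continuous: Iterable[str] | None = None,
    alpha_gate: float = 0.05,
) -> list[ClinicalComparison]:
    """Compare each clinical covariate between the two response groups.

    Continuous covariates get the same gated t/Welch/Mann-Whitney choice as
    features; categorical covariates get Fisher's exact (2 levels) or the
    uncorrected Pearson chi-square (>2 levels).
    """
    df = metadata.table
    labels = sorted(metadata.groups.unique())
    if continuous is None:
        continuous = [c for c in df.columns
                      if c != metadata.group_col and pd.api.types.is_numeric_dtype(df[c])]
    continuous = set(continuous)
    out: list[ClinicalComparison] = []
    for col in df.columns:
        if col == metadata.group_col:
            continue
        if col in continuous:
            a = _clean(df.loc[df[metadata.group_col] == labels[0], col])
            b = _clean(df.loc[df[metadata.group_col] == labels[1], col])
            test = choose_test(a, b, alpha_gate)
            p = compare_feature(a, b, test)
            if test == "t":
                stat = stats.ttest_ind(a, b, equal_var=True).statistic
            elif test == "welch":
                stat = stats.ttest_ind(a, b, equal_var=False).statistic
            else:
                stat = stats.mannwhitneyu(a, b, alternative="two-sided").statistic
            out.append(ClinicalComparison(col, test, float(stat), p))
        else:
            ct = pd.crosstab(df[col], df[metadata.group_col])
            if ct.shape[0] < 2:
                logger.warning("covariate %r has a single level; skipped", col)
                continue
            name, stat, p = compare_contingency(ct.to_numpy())
            out.append(ClinicalComparison(col, name, stat, p))
    return out
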
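"""Pearson correlation analyses across omics layers and clinical covariates.

Two uses mirror the discovery workflow: (1) an all-pairs cross-omics
screen between differential proteins and metabolites, filtered to strong
correlations (|r| > 0.8 by default) that are nominally significant; and
(2) the radiation-dose check — correlating candidate biomarkers with the
delivered dose overall and within each response group separately, the
stratified view that separates a genuine dose effect from confounding by
group membership (a feature that merely tracks the response groups shows a
strong overall dose correlation that vanishes within groups).

Correlations use pairwise-complete observations; p-values come from the
exact t transform with n-2 degrees of freedom, BH-adjusted across the
reported pair list.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust
from .tables import CohortMetadata, FeatureTable

logger = logging.getLogger(__name__)


@dataclass
class CorrelationRecord:
    id_a: str
    id_b: str
    kind_a: str
    kind_b: str
    r: float
    p_value: float
    q_value: float
    n_pairs: int


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    keep = ~(np.isnan(x) | np.isnan(y))
    n = int(keep.sum())
    if n < 3:
        return math.nan, math.nan, n
    xv, yv = x[keep], y[keep]
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return math.nan, math.nan, n
    res = stats.pearsonr(xv, yv)
    return float(res.statistic), float(res.pvalue), n


def correlation_matrix(
    table_a: FeatureTable,
    table_b: FeatureTable | None = None,
    r_threshold: float = 0.8,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Pearson correlations between two tables' features.

    With ``table_b`` None, correlates ``table_a`` against itself (unordered
    pairs, diagonal excluded).  Returns (full long-format frame with BH
    q-values, filtered frame with |r| > r_threshold and p < alpha).
    """
    within = table_b is None
    tb = table_a if within else table_b
    shared = [s for s in table_a.sample_ids if s in tb.values.columns]
    if len(shared) < 3:
        raise ValueError("tables share fewer than 3 samples")
    A = table_a.values[shared]
    B = tb.values[shared]
    if within:
        pairs = list(combinations(A.index, 2))
    else:
        pairs = [(fa, fb) for fa in A.index for fb in B.index]
    rows = []
    for fa, fb in pairs:
        r, p, n = _pearson(A.loc[fa].to_numpy(float), B.loc[fb].to_numpy(float))
        if math.isnan(r):
            continue
        rows.append((fa, fb, table_a.omics_kind, tb.omics_kind, r, p, n))
    df = pd.DataFrame(rows, columns=["id_a", "id_b", "kind_a", "kind_b", "r", "p_value", "n_pairs"])
    if not df.empty:
        df["q_value"] = bh_adjust(df["p_value"].to_numpy())
    else:
        df["q_value"] = []
    filtered = df[(df["r"].abs() > r_threshold) & (df["p_value"] < alpha)]
    return df, filtered.reset_index(drop=True)


def square_matrix(long_df: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long-format correlation frame to a square r matrix."""
    ids = sorted(set(long_df["id_a"]) | set(long_df["id_b"]))
    mat = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for _, row in long_df.iterrows():
        mat.loc[row["id_a"], row["id_b"]] = row["r"]
        mat.loc[row["id_b"], row["id_a"]] = row["r"]
    return mat


def dose_association(
    table: FeatureTable,
    metadata: CohortMetadata,
    feature_ids,
    dose_col: str = "rt_dose_gy",
    per_group: bool = True,
) -> pd.DataFrame:
    """Correlate selected features with radiation dose, overall and per group.

    Emits one row per (feature, stratum) with stratum "all" plus each group
    label when ``per_group``; the per-feature sign summary is the overall
    sign together with the within-group signs, which is what distinguishes
    a dose effect from group confounding.
    """
    if dose_col not in metadata.table.columns:
        raise ValueError(f"metadata lacks dose column {dose_col!r}")
    strata: list[tuple[str, list[str]]] = [("all", list(metadata.sample_ids))]
    if per_group:
        for g in sorted(metadata.groups.unique()):
            strata.append((g, metadata.group_samples(g)))
    rows = []
    for fid in feature_ids:
        x_all = table.values.loc[fid]
        for name, samples in strata:
            samples = [s for s in samples if s in x_all.index]
            dose = metadata.table.loc[samples, dose_col].to_numpy(float)
            if len(dose) == 0 or np.ptp(dose[~np.isnan(dose)]) == 0:
                logger.warning("dose constant/empty in stratum %r; skipped", name)
                continue
            r, p, n = _pearson(x_all[samples].to_numpy(float), dose)
            rows.append((fid, name, r, p, n))
    df = pd.DataFrame(rows, columns=["feature_id", "stratum", "r", "p_value", "n_pairs"])
    if not df.empty:
        df["q_value"] = bh_adjust(df["p_value"].fillna(1.0).to_numpy())
        df["sign"] = np.sign(df["r"]).map({1.0: "positive", -1.0: "negative", 0.0: "zero"})
    return df
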
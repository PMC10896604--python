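"""Feature tables, cohort metadata, and the pipeline's format conventions.

A :class:`FeatureTable` is the object every analysis stage consumes: a
features x samples matrix of non-negative abundances (NaN = not detected),
tagged with the omics layer it came from.  Tables are stored as TSV with
features in rows (the usual omics orientation), a header row of sample ids,
and the feature id in the first column; empty cells or ``NA`` are missing.

Two transformations defined here are used throughout:

* :func:`tic_normalize` — total-ion-current normalization: each sample is
  scaled by its summed intensity, then rescaled to the cohort median total
  so values stay on the original intensity scale.
* :func:`log_autoscale` — natural log followed by per-feature autoscaling
  (mean-center, divide by sample SD), the standard chemometric transform.

Univariate statistics operate on observed values only; multivariate stages
(PCA, HCA, SVM panels) additionally require :func:`half_min_impute`, which
fills missing entries with half the feature's minimum observed value — a
common convention for MS non-detects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OmicsKind = Literal["protein", "metabolite"]

GROUP_LABELS = ("GR", "PR")


class TableError(ValueError):
    """Malformed feature table or metadata (bad header, duplicates, negatives)."""


@dataclass
class FeatureTable:
    """Features x samples abundance matrix for one omics layer.

    ``values`` is a DataFrame indexed by feature id with sample ids as
    columns; entries are non-negative floats or NaN (not detected).
    """

    values: pd.DataFrame
    omics_kind: OmicsKind = "protein"
    transformed: bool = False  # True after log/autoscale: negatives allowed

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise TableError(f"duplicate feature ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise TableError(f"duplicate sample ids: {dups}")
        vals = self.values.to_numpy(dtype=float)
        if not self.transformed and np.nanmin(vals, initial=np.inf) < 0:
            rows, colz = np.where(vals < 0)
            f, s = idx[rows[0]], cols[colz[0]]
            raise TableError(f"negative abundance at feature {f!r}, sample {s!r}")
        self.values = self.values.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def detected(self) -> pd.DataFrame:
        """Boolean detection mask (True where a value was observed)."""
        return self.values.notna()

    def subset_features(self, feature_ids) -> "FeatureTable":
        return FeatureTable(self.values.loc[list(feature_ids)], self.omics_kind, self.transformed)


@dataclass
class CohortMetadata:
    """Per-sample response label (GR/PR) and clinical covariates.

    ``table`` is indexed by sample id and carries a ``group`` column with
    exactly two levels plus any clinical covariates.
    """

    table: pd.DataFrame
    group_col: str = "group"

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise TableError("duplicate sample ids in metadata")
        if self.group_col not in self.table.columns:
            raise TableError(f"metadata lacks group column {self.group_col!r}")
        levels = sorted(self.table[self.group_col].dropna().unique())
        if len(levels) != 2:
            raise TableError(f"expected exactly two group labels, got {levels}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def groups(self) -> pd.Series:
        return self.table[self.group_col]

    def group_samples(self, label: str) -> list[str]:
        return list(self.table.index[self.table[self.group_col] == label])

    def check_covers(self, table: FeatureTable) -> None:
        missing = [s for s in table.sample_ids if s not in self.table.index]
        if missing:
            raise TableError(f"samples absent from metadata: {missing}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_feature_table(path: str | Path, omics_kind: OmicsKind = "protein") -> FeatureTable:
    """Read a TSV feature table (features in rows, header of sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    if df.columns.size == 0:
        raise TableError(f"{path}: header row has no sample ids")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise TableError(f"{path}: non-numeric abundance value ({exc})") from exc
    try:
        return FeatureTable(df, omics_kind)
    except TableError as exc:
        raise TableError(f"{path}: {exc}") from exc


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    table.values.to_csv(path, sep="\t", index_label="feature_id", na_rep="NA")


def read_metadata(path: str | Path, group_col: str = "group") -> CohortMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    return CohortMetadata(df, group_col)


def write_metadata(meta: CohortMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def tic_normalize(table: FeatureTable) -> FeatureTable:
    """Total-ion-current normalization.

    Each sample's observed values are divided by the sample total and
    multiplied by the cohort median total, so per-sample sums are equal
    afterwards and the intensity scale is preserved.  Missing values stay
    missing.  Idempotent up to floating tolerance.
    """
    totals = table.values.sum(axis=0, skipna=True)
    dead = totals[(totals == 0) | table.values.isna().all(axis=0)]
    if len(dead) > 0:
        raise TableError(f"samples with no observed values: {list(dead.index)}")
    target = float(np.median(totals))
    out = table.values.div(totals, axis=1) * target
    return FeatureTable(out, table.omics_kind)


def log_autoscale(table: FeatureTable, drop_zero_variance: bool = True) -> FeatureTable:
    """Natural log then per-feature autoscaling (mean 0, SD 1, ddof=1).

    Zeros are treated as missing (non-detection) before the log.  Features
    with zero variance over observed entries carry no contrast and are
    dropped with a warning.  The result is flagged ``transformed`` so the
    non-negativity invariant of raw abundance tables no longer applies.
    """
    vals = table.values.mask(table.values == 0)
    logged = np.log(vals)
    mean = logged.mean(axis=1, skipna=True)
    sd = logged.std(axis=1, ddof=1, skipna=True)
    keep = sd > 0
    if drop_zero_variance and not keep.all():
        dropped = list(logged.index[~keep.fillna(False)])
        logger.warning("dropping %d zero-variance feature(s): %s", len(dropped), dropped[:10])
        logged, mean, sd = logged.loc[keep], mean[keep], sd[keep]
    scaled = logged.sub(mean, axis=0).div(sd, axis=0)
    return FeatureTable(scaled, table.omics_kind, transformed=True)


def half_min_impute(table: FeatureTable) -> FeatureTable:
    """Fill missing entries with half the feature's minimum observed value."""
    mins = table.values.min(axis=1, skipna=True)
    fill = mins / 2.0
    out = table.values.apply(lambda row: row.fillna(fill[row.name]), axis=1)
    out = out.dropna(how="all")  # features never observed anywhere
    return FeatureTable(out, table.omics_kind)
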
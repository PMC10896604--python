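"""Pathway-level statistics over user-supplied GMT pathway sets.

Three methods, all Benjamini-Hochberg adjusted across pathways per run:

* :func:`ora` — over-representation analysis: one-sided hypergeometric
  upper-tail probability of drawing at least the observed number of
  pathway members among the hit list, given the measured universe.
* :func:`qea` — quantitative enrichment analysis on abundances rather
  than hit lists: a globaltest-style statistic (mean squared covariance
  between the centered outcome and each standardized member feature),
  calibrated by label permutation with a permutation stream shared across
  pathways so pathway p-values are comparable.
* :func:`joint_pathway` — gene + metabolite integration by pooling both
  hit lists and universes (identifiers namespaced per layer) into a single
  ORA; the reported impact is the enrichment ratio observed/expected, with
  an optional node-weight hook for topology-style weighting.

No live pathway-database access: pathway membership comes from GMT files.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust
from .tables import CohortMetadata, FeatureTable

logger = logging.getLogger(__name__)


class GmtError(ValueError):
    """Malformed GMT pathway file."""


@dataclass
class PathwaySet:
    pathway_id: str
    name: str
    members: frozenset[str]


@dataclass
class EnrichmentRecord:
    pathway_id: str
    n_hits: int
    n_members_in_universe: int
    expected_hits: float
    enrichment_ratio: float
    p_value: float
    q_value: float = math.nan
    method: str = "ora"
    impact: float = math.nan
    n_hits_gene: int = 0
    n_hits_metabolite: int = 0
    statistic: float = math.nan


def read_gmt(path: str | Path) -> list[PathwaySet]:
    """Parse a GMT file: name <tab> description <tab> member..."""
    sets: list[PathwaySet] = []
    seen: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise GmtError(f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}")
        name, desc, members = fields[0], fields[1], [m for m in fields[2:] if m]
        if name in seen:
            raise GmtError(f"{path}:{lineno}: duplicate pathway name {name!r}")
        seen.add(name)
        uniq = frozenset(members)
        if len(uniq) < len(members):
            logger.warning("%s:%d: duplicate members in %r deduplicated", path, lineno, name)
        sets.append(PathwaySet(name, desc or name, uniq))
    return sets


def write_gmt(sets: Sequence[PathwaySet], path: str | Path) -> None:
    lines = ["\t".join([s.pathway_id, s.name, *sorted(s.members)]) for s in sets]
    Path(path).write_text("\n".join(lines) + "\n")


def ora(
    hits: Iterable[str],
    universe: Iterable[str],
    pathways: Sequence[PathwaySet],
    method_label: str = "ora",
) -> list[EnrichmentRecord]:
    """Hypergeometric over-representation analysis with BH adjustment."""
    hits = set(hits)
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    stray = hits - universe
    if stray:
        raise ValueError(f"hits not contained in universe: {sorted(stray)[:5]}")
    n, big_n = len(hits), len(universe)
    records: list[EnrichmentRecord] = []
    for ps in pathways:
        members = ps.members & universe
        m = len(members)
        if m == 0:
            logger.warning("pathway %r has no members in universe; skipped", ps.pathway_id)
            continue
        k = len(hits & members)
        # P(X >= k) for X ~ Hypergeom(N, m, n)
        p = float(stats.hypergeom.sf(k - 1, big_n, m, n))
        expected = n * m / big_n
        records.append(EnrichmentRecord(
            pathway_id=ps.pathway_id,
            n_hits=k,
            n_members_in_universe=m,
            expected_hits=expected,
            enrichment_ratio=(k / expected) if expected > 0 else math.nan,
            p_value=min(p, 1.0),
            method=method_label,
        ))
    _attach_q(records)
    return records


def _attach_q(records: list[EnrichmentRecord]) -> None:
    if records:
        qs = bh_adjust([r.p_value for r in records])
        for r, q in zip(records, qs):
            r.q_value = float(q)


def qea(
    table: FeatureTable,
    metadata: CohortMetadata,
    pathways: Sequence[PathwaySet],
    n_permutations: int = 1000,
    seed: int = 0,
    positive: str = "PR",
) -> list[EnrichmentRecord]:
    """Permutation-calibrated quantitative enrichment analysis.

    Per pathway S: z_j = [sum_i (y_i - ybar) x_ij]^2 on internally
    re-standardized features, Q_S = mean_{j in S} z_j; p-value is the
    fraction of label permutations with Q >= observed (add-one smoothed).
    """
    if n_permutations < 100:
        logger.warning("n_permutations=%d is low; p-value resolution is coarse", n_permutations)
    X = table.values.to_numpy(dtype=float).T  # samples x features
    if np.isnan(X).any():
        raise ValueError("qea requires an imputed table (no missing values)")
    # re-standardize so the statistic is scale-invariant regardless of input
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    X = (X - mu) / sd
    y = (metadata.groups.reindex(table.sample_ids).to_numpy() == positive).astype(float)
    yc = y - y.mean()

    fid_index = {f: i for i, f in enumerate(table.feature_ids)}
    rng = np.random.default_rng(seed)
    perm = np.stack([rng.permutation(yc) for _ in range(n_permutations)])
    z_obs = (yc @ X) ** 2                    # per-feature observed scores
    z_perm = (perm @ X) ** 2                 # n_permutations x features

    records: list[EnrichmentRecord] = []
    for ps in pathways:
        cols = [fid_index[m] for m in ps.members if m in fid_index]
        if not cols:
            logger.warning("pathway %r has no measured members; skipped", ps.pathway_id)
            continue
        q_obs = float(z_obs[cols].mean())
        q_null = z_perm[:, cols].mean(axis=1)
        p = (1.0 + np.sum(q_null >= q_obs)) / (1.0 + n_permutations)
        records.append(EnrichmentRecord(
            pathway_id=ps.pathway_id,
            n_hits=len(cols),
            n_members_in_universe=len(cols),
            expected_hits=float(np.mean(q_null)),
            enrichment_ratio=q_obs / float(np.mean(q_null)) if np.mean(q_null) > 0 else math.nan,
            p_value=float(p),
            method="qea",
            statistic=q_obs,
        ))
    _attach_q(records)
    return records


def joint_pathway(
    gene_hits: Iterable[str],
    metabolite_hits: Iterable[str],
    gene_universe: Iterable[str],
    metabolite_universe: Iterable[str],
    joint_pathways: Sequence[PathwaySet],
    node_weights: Mapping[str, float] | None = None,
) -> list[EnrichmentRecord]:
    """Pooled gene+metabolite ORA with an enrichment-ratio impact score.

    Identifiers must be namespaced per layer so a gene and metabolite
    cannot collide.  When ``node_weights`` (e.g. pathway-topology
    centralities) are supplied, impact becomes the weighted hit fraction
    sum(w over hits)/sum(w over members); otherwise impact is the
    enrichment ratio.
    """
    gene_hits, metabolite_hits = set(gene_hits), set(metabolite_hits)
    gene_universe, metabolite_universe = set(gene_universe), set(metabolite_universe)
    overlap = gene_universe & metabolite_universe
    if overlap:
        raise ValueError(f"gene/metabolite identifier collision: {sorted(overlap)[:5]}")
    hits = gene_hits | metabolite_hits
    universe = gene_universe | metabolite_universe
    records = ora(hits, universe, joint_pathways, method_label="joint")
    for r in records:
        ps = next(p for p in joint_pathways if p.pathway_id == r.pathway_id)
        members = ps.members & universe
        r.n_hits_gene = len(gene_hits & members)
        r.n_hits_metabolite = len(metabolite_hits & members)
        if node_weights is not None:
            wm = sum(node_weights.get(m, 0.0) for m in members)
            wh = sum(node_weights.get(m, 0.0) for m in (hits & members))
            r.impact = wh / wm if wm > 0 else math.nan
        else:
            r.impact = r.enrichment_ratio
    return records


def records_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in records])
    if df.empty:
        return df
    return df.set_index("pathway_id").sort_values("p_value")
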
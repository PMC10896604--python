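"""Benchmark experiments the package runs on itself.

These functions reproduce, at desk scale and from scratch, the checks that
validate the pipeline: reproduction of the reference cohort's clinical
group comparisons from its published contingency tables, type-I error
calibration of the adaptive test on null synthetic cohorts, power on
planted effects, MCCV panel recovery of planted biomarkers, and QEA null
uniformity and power.  Both the test suite and ``scripts/acceptance.py``
call them, so every reported number is recomputed at run time.
"""

from __future__ import annotations

import numpy as np

from .classify import mccv_panels, panel_report
from .differential import call_differential, compare_contingency
from .enrichment import PathwaySet, qea
from .simulate import SyntheticConfig, generate_cohort
from .tables import half_min_impute, log_autoscale

# Clinical contingency tables of the 24-patient rectal-cancer neo-RT
# reference cohort (rows = covariate levels, columns = GR, PR counts).
REFERENCE_CLINICAL_TABLES: dict[str, list[list[int]]] = {
    "sex": [[5, 6], [7, 6]],                      # F / M
    "clinical_stage": [[4, 5], [8, 6], [0, 1]],   # II / III / IV
    "rt_scheme": [[4, 7], [3, 5], [5, 0]],        # 39 / 42 / 54 Gy
    "rt_mode": [[4, 8], [8, 4]],                  # RT / RT+CT
    "surgery_mode": [[7, 8], [5, 4]],             # AR / APR
    "ypt": [[4, 2], [8, 10]],                     # ypT 0-2 / 3
    "ypn": [[9, 7], [3, 5]],                      # negative / positive
}


def reference_clinical_pvalues() -> dict[str, tuple[str, float]]:
    """Group-comparison test and p-value for each reference covariate."""
    return {name: (test, p)
            for name, table in REFERENCE_CLINICAL_TABLES.items()
            for test, _, p in [compare_contingency(np.asarray(table))]}


def type_one_error_rate(n_seeds: int = 50, n_features: int = 200,
                        seed_offset: int = 0) -> tuple[float, int]:
    """Raw p<0.05 rate of the adaptive test on null synthetic cohorts."""
    n_sig = n_tested = 0
    for seed in range(n_seeds):
        cfg = SyntheticConfig(n_protein_features=n_features, n_metabolite_features=5,
                              frac_differential=0.0, frac_exclusive=0.0,
                              seed=seed_offset + seed)
        prot, _, meta, _ = generate_cohort(cfg)
        rec, _ = call_differential(prot, meta)
        tested = rec["p_value"].notna()
        n_tested += int(tested.sum())
        n_sig += int((rec.loc[tested, "p_value"] < 0.05).sum())
    return n_sig / n_tested, n_tested


def planted_power(n_seeds: int = 20, n_features: int = 250,
                  effect_size: float = 2.0, seed_offset: int = 1000) -> tuple[float, int]:
    """Fraction of planted g-shifted features recovered at BH q < 0.05."""
    n_hit = n_planted = 0
    for seed in range(n_seeds):
        cfg = SyntheticConfig(n_protein_features=n_features, n_metabolite_features=5,
                              frac_differential=0.2, effect_size=effect_size,
                              frac_exclusive=0.0, seed=seed_offset + seed)
        prot, _, meta, truth = generate_cohort(cfg)
        rec, _ = call_differential(prot, meta)
        planted = [f for f in truth.differential_feature_ids if f.startswith("PROT")]
        n_planted += len(planted)
        n_hit += int((rec.loc[planted, "p_adjusted"] < 0.05).sum())
    return n_hit / n_planted, n_planted


def mccv_recovery(n_seeds: int = 20, n_null: int = 500, n_planted: int = 10,
                  effect_size: float = 3.0, seed_offset: int = 2000) -> tuple[list[int], float]:
    """Planted-panel recovery: how many of the planted biomarkers land in the
    top-10 selection-frequency ranks of a size-10 MCCV panel, per seed."""
    recovered = []
    aucs = []
    n_total = n_null + n_planted
    for seed in range(n_seeds):
        cfg = SyntheticConfig(n_protein_features=n_total, n_metabolite_features=5,
                              frac_differential=n_planted / n_total,
                              effect_size=effect_size, frac_exclusive=0.0,
                              seed=seed_offset + seed)
        prot, _, meta, truth = generate_cohort(cfg)
        table = log_autoscale(half_min_impute(prot))
        res = mccv_panels(table, meta, sizes=(10,), n_iterations=100,
                          seed=seed_offset + seed)[0]
        planted = {f for f in truth.differential_feature_ids if f.startswith("PROT")}
        top10 = set(res.top_features.head(10).index)
        recovered.append(len(top10 & planted))
        aucs.append(res.auc)
    return recovered, float(np.mean(aucs))


def qea_null_pvalues(n_seeds: int = 50, n_pathways: int = 10,
                     n_permutations: int = 500, seed_offset: int = 3000) -> np.ndarray:
    """Pooled QEA p-values from cohorts where the outcome is independent of
    all features; should be approximately uniform."""
    ps = []
    for seed in range(n_seeds):
        cfg = SyntheticConfig(n_protein_features=5, n_metabolite_features=60,
                              frac_differential=0.0, frac_exclusive=0.0,
                              missing_rate=0.0, seed=seed_offset + seed)
        _, met, meta, _ = generate_cohort(cfg)
        table = log_autoscale(half_min_impute(met))
        ids = table.feature_ids
        pws = [PathwaySet(f"pw{i}", "", frozenset(ids[i * 5:(i + 1) * 5]))
               for i in range(n_pathways)]
        recs = qea(table, meta, pws, n_permutations=n_permutations,
                   seed=seed_offset + seed)
        ps.extend(r.p_value for r in recs)
    return np.asarray(ps)


def qea_planted_power(n_seeds: int = 20, effect_size: float = 2.0,
                      n_permutations: int = 1000, seed_offset: int = 4000) -> float:
    """Fraction of seeds in which a fully planted 5-member pathway reaches
    BH q < 0.05 among null pathways."""
    n_hit = 0
    for seed in range(n_seeds):
        cfg = SyntheticConfig(n_protein_features=5, n_metabolite_features=60,
                              frac_differential=0.25, effect_size=effect_size,
                              frac_exclusive=0.0, missing_rate=0.0,
                              seed=seed_offset + seed)
        _, met, meta, truth = generate_cohort(cfg)
        table = log_autoscale(half_min_impute(met))
        planted = sorted(f for f in truth.differential_feature_ids
                         if f.startswith("MET") and f in table.values.index)
        nulls = [f for f in table.feature_ids if f not in planted]
        pws = [PathwaySet("planted", "", frozenset(planted[:5]))] + [
            PathwaySet(f"null{i}", "", frozenset(nulls[i * 5:(i + 1) * 5]))
            for i in range(5)]
        recs = {r.pathway_id: r for r in qea(table, meta, pws, n_permutations,
                                             seed=seed_offset + seed)}
        n_hit += int(recs["planted"].q_value < 0.05)
    return n_hit / n_seeds
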
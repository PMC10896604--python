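"""Synthetic cohort generator with known ground truth.

Emulates the study design the pipeline targets: a two-arm rectal-cancer
cohort (12 good responders GR, 12 poor responders PR by default), a
proteome layer of ~2741 features and a metabolome layer of ~119 features,
TIC-normalized log-normal abundances, a configurable fraction of features
carrying a planted standardized group shift (Hedges'-g units on the log
scale), a small fraction detectable in only one group, missing-at-random
dropout, and a Table-1-like clinical covariate table.

Every downstream stage (differential testing, effect sizes, MCCV panels,
enrichment, correlations) is testable against the emitted
:class:`GroundTruth` without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import CohortMetadata, FeatureTable, tic_normalize

# fixed child-seed offsets: adding a layer never reshuffles another
_OFFSET_PROTEOME = 1
_OFFSET_METABOLOME = 2
_OFFSET_CLINICAL = 3


class ConfigError(ValueError):
    """Invalid synthetic-cohort configuration; message names the field."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design knobs for the generator.

    Defaults mirror the target design: 12 samples per response group, 2741
    protein and 119 metabolite features.  ``effect_size`` is the planted
    standardized mean shift in Hedges'-g units on the log scale;
    ``frac_exclusive`` features are detectable in only one group (and count
    as differential); ``frac_nonnormal`` features get right-skewed
    log-scale noise so the Shapiro-Wilk gate routes them to the rank test.
    """

    n_per_group: int = 12
    n_protein_features: int = 2741
    n_metabolite_features: int = 119
    frac_differential: float = 0.2
    effect_size: float = 2.0
    frac_nonnormal: float = 0.2
    frac_exclusive: float = 0.01
    missing_rate: float = 0.05
    seed: int = 0
    # hyperprior on per-feature log-intensity location and spread
    loc_mean: float = 12.0
    loc_sd: float = 2.0
    sd_low: float = 0.3
    sd_high: float = 0.7

    def validate(self) -> None:
        for name in ("n_per_group", "n_protein_features", "n_metabolite_features"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("frac_differential", "frac_nonnormal", "frac_exclusive", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.effect_size < 0:
            raise ConfigError(f"effect_size must be >= 0, got {self.effect_size}")
        if self.sd_low <= 0 or self.sd_high < self.sd_low:
            raise ConfigError(f"sd_low/sd_high must satisfy 0 < sd_low <= sd_high")


@dataclass
class GroundTruth:
    """What was planted: differential ids, direction, exclusives, effect sizes."""

    differential_feature_ids: set[str] = field(default_factory=set)
    direction_per_feature: dict[str, str] = field(default_factory=dict)  # up-in-GR | up-in-PR
    exclusive_feature_ids: dict[str, str] = field(default_factory=dict)  # id -> owning group
    planted_effect_size: dict[str, float] = field(default_factory=dict)

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        return GroundTruth(
            self.differential_feature_ids | other.differential_feature_ids,
            {**self.direction_per_feature, **other.direction_per_feature},
            {**self.exclusive_feature_ids, **other.exclusive_feature_ids},
            {**self.planted_effect_size, **other.planted_effect_size},
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "differential_feature_ids": sorted(self.differential_feature_ids),
            "direction_per_feature": self.direction_per_feature,
            "exclusive_feature_ids": self.exclusive_feature_ids,
            "planted_effect_size": self.planted_effect_size,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            set(d["differential_feature_ids"]),
            d["direction_per_feature"],
            d["exclusive_feature_ids"],
            d["planted_effect_size"],
        )


def _child_rng(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(offset,)))


def _simulate_layer(
    cfg: SyntheticConfig,
    n_features: int,
    prefix: str,
    omics_kind: str,
    rng: np.random.Generator,
) -> tuple[FeatureTable, GroundTruth]:
    n = cfg.n_per_group
    n_samples = 2 * n
    ids = [f"{prefix}{i:04d}" for i in range(n_features)]
    samples = [f"GR{i+1:02d}" for i in range(n)] + [f"PR{i+1:02d}" for i in range(n)]
    gr_cols = np.arange(n)
    pr_cols = np.arange(n, n_samples)

    loc = rng.normal(cfg.loc_mean, cfg.loc_sd, size=n_features)
    sd = rng.uniform(cfg.sd_low, cfg.sd_high, size=n_features)

    n_diff = int(round(cfg.frac_differential * n_features))
    n_excl = min(int(round(cfg.frac_exclusive * n_features)), n_diff)
    diff_idx = rng.choice(n_features, size=n_diff, replace=False)
    excl_idx = diff_idx[:n_excl]  # exclusives are a subset of the differential set
    up_in_gr = rng.random(n_diff) < 0.5

    nonnormal = rng.random(n_features) < cfg.frac_nonnormal
    # log-scale noise: normal, or a centered/scaled exponential (skewed) that
    # deterministically fails the Shapiro-Wilk gate at moderate n
    noise = rng.normal(0.0, 1.0, size=(n_features, n_samples))
    skew = rng.exponential(1.0, size=(n_features, n_samples)) - 1.0
    noise[nonnormal] = skew[nonnormal]
    logx = loc[:, None] + sd[:, None] * noise

    truth = GroundTruth()
    for k, (fi, up) in enumerate(zip(diff_idx, up_in_gr)):
        shift = cfg.effect_size * sd[fi]
        cols = gr_cols if up else pr_cols
        logx[fi, cols] += shift
        fid = ids[fi]
        truth.differential_feature_ids.add(fid)
        truth.direction_per_feature[fid] = "up-in-GR" if up else "up-in-PR"
        truth.planted_effect_size[fid] = cfg.effect_size

    x = np.exp(logx)

    # missing-at-random dropout, applied before exclusivity and TIC
    drop = rng.random((n_features, n_samples)) < cfg.missing_rate
    x[drop] = np.nan

    for k, fi in enumerate(excl_idx):
        own_gr = up_in_gr[k]
        dead_cols = pr_cols if own_gr else gr_cols
        x[fi, dead_cols] = np.nan
        truth.exclusive_feature_ids[ids[fi]] = "GR" if own_gr else "PR"

    df = pd.DataFrame(x, index=ids, columns=samples)
    # guard: a sample losing every value to dropout would break TIC; at the
    # configured rates this cannot occur, but fail loudly rather than NaN out
    table = tic_normalize(FeatureTable(df, omics_kind))
    return table, truth


def generate_clinical_table(
    config: SyntheticConfig, association_strength: float = 0.0
) -> CohortMetadata:
    """Emit a Table-1-like clinical covariate table.

    At ``association_strength`` 0 every covariate is independent of the
    response group; at strength ``s`` the group-associated covariates (RT
    scheme/dose most prominently, mirroring the real cohort's imbalance)
    shift between groups in expectation, with ``s`` scaling log-odds /
    standardized-mean offsets.
    """
    config.validate()
    if association_strength < 0:
        raise ConfigError(f"association_strength must be >= 0, got {association_strength}")
    s = association_strength
    rng = _child_rng(config.seed, _OFFSET_CLINICAL)
    n = config.n_per_group
    samples = [f"GR{i+1:02d}" for i in range(n)] + [f"PR{i+1:02d}" for i in range(n)]
    group = np.array(["GR"] * n + ["PR"] * n)
    is_pr = (group == "PR").astype(float)

    def cat(levels, base_p, tilt):
        # tilt: per-level log-weight added for PR samples, scaled by s
        base = np.asarray(base_p, dtype=float)
        out = []
        for pr in is_pr:
            w = base * np.exp(s * pr * np.asarray(tilt))
            out.append(rng.choice(levels, p=w / w.sum()))
        return out

    sex = cat(["F", "M"], [0.46, 0.54], [0.0, 0.0])
    age = np.round(rng.normal(66.0 + s * 2.5 * is_pr, 10.9)).astype(int)
    bmi = np.round(rng.normal(26.2 + s * 1.1 * is_pr, 4.2), 1)
    stage = cat(["II", "III", "IV"], [0.375, 0.583, 0.042], [0.2, -0.1, 0.5])
    # PR under-represented at the high-dose scheme, as in the real cohort
    scheme = cat(["39Gy", "42Gy", "54Gy"], [0.458, 0.333, 0.208], [0.5, 0.4, -2.0])
    rt_dose = np.array([float(x[:2]) for x in scheme])
    rt_mode = cat(["RT", "RT/CT"], [0.5, 0.5], [0.7, -0.7])
    time_rt_s = np.round(rng.normal(57.0, 22.0)).astype(int).clip(14)
    surgery = cat(["AR", "APR"], [0.625, 0.375], [0.1, -0.1])
    ypt = cat(["0-2", "3"], [0.25, 0.75], [-0.5, 0.2])
    ypn = cat(["negative", "positive"], [0.667, 0.333], [-0.3, 0.3])
    lny = np.round(rng.normal(11.2 + s * 0.9 * is_pr, 5.1)).astype(int).clip(0)

    df = pd.DataFrame(
        {
            "group": group,
            "sex": sex,
            "age": age,
            "bmi": bmi,
            "clinical_stage": stage,
            "rt_scheme": scheme,
            "rt_dose_gy": rt_dose,
            "rt_mode": rt_mode,
            "time_rt_to_surgery_days": time_rt_s,
            "surgery_mode": surgery,
            "ypt": ypt,
            "ypn": ypn,
            "lny": lny,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return CohortMetadata(df)


def generate_cohort(
    config: SyntheticConfig, association_strength: float = 0.0
) -> tuple[FeatureTable, FeatureTable, CohortMetadata, GroundTruth]:
    """Generate (proteome, metabolome, metadata, ground truth).

    Same config and seed give bit-identical output; each layer draws from
    its own child stream so changing one layer's size leaves the others
    untouched.
    """
    config.validate()
    proteome, t1 = _simulate_layer(
        config, config.n_protein_features, "PROT", "protein",
        _child_rng(config.seed, _OFFSET_PROTEOME),
    )
    metabolome, t2 = _simulate_layer(
        config, config.n_metabolite_features, "MET", "metabolite",
        _child_rng(config.seed, _OFFSET_METABOLOME),
    )
    metadata = generate_clinical_table(config, association_strength)
    return proteome, metabolome, metadata, t1.merge(t2)
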
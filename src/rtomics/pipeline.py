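"""End-to-end orchestration: one config in, a run directory of outputs out.

``run_all`` executes the full discovery workflow in the order a study
would: TIC normalization, unsupervised chemometrics on all features,
adaptive differential analysis per omics layer, supervised clustering on
the significant features, the univariate classifier screen, MCCV/SVM
biomarker panels, enrichment (ORA / QEA / joint), and the correlation
analyses — writing every stage's tables under the output directory and a
JSON manifest listing them all, with the config and seed echoed so a run
is reproducible from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .associate import correlation_matrix, dose_association
from .chemometrics import cluster_agreement, hca, pca
from .classify import DEFAULT_PANEL_SIZES, mccv_panels, panel_report, univariate_screen
from .differential import call_differential, compare_clinical
from .enrichment import ora, qea, read_gmt, records_frame
from .simulate import SyntheticConfig, generate_cohort
from .tables import (
    CohortMetadata,
    FeatureTable,
    half_min_impute,
    log_autoscale,
    read_feature_table,
    read_metadata,
    tic_normalize,
    write_feature_table,
    write_metadata,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything one run needs: inputs (paths or synthetic), thresholds, seed."""

    outdir: str | Path = "rtomics_run"
    proteome_path: str | None = None
    metabolome_path: str | None = None
    metadata_path: str | None = None
    pathways_path: str | None = None
    synthetic: SyntheticConfig | None = None
    group_order: tuple[str, str] = ("GR", "PR")
    alpha: float = 0.05
    alpha_gate: float = 0.05
    r_threshold: float = 0.8
    min_detected: int | None = None
    panel_sizes: tuple[int, ...] = DEFAULT_PANEL_SIZES
    mccv_iterations: int = 100
    train_fraction: float = 2.0 / 3.0
    qea_permutations: int = 1000
    seed: int = 0
    max_correlation_features: int = 50  # cap the all-pairs cross-omics screen

    def validate(self) -> None:
        has_paths = self.proteome_path or self.metabolome_path
        if not has_paths and self.synthetic is None:
            raise PipelineError("config: provide input paths or a synthetic config")
        if has_paths and self.synthetic is not None:
            raise PipelineError("config: input paths and synthetic config are mutually exclusive")
        if not 0 < self.alpha < 1:
            raise PipelineError(f"config: alpha must be in (0,1), got {self.alpha}")
        if not 0 < self.train_fraction < 1:
            raise PipelineError(f"config: train_fraction must be in (0,1), got {self.train_fraction}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if syn is not None:
            cfg.synthetic = SyntheticConfig(**syn)
        return cfg


def _child_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(100 + k,)).generate_state(1)[0] % (2**31))


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("rtomics")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": _jsonable(config),
        "stages": {},
        "outputs": [],
        "complete": False,
    }
    t0 = time.time()

    def emit(name: str, frame: pd.DataFrame, **kw) -> str:
        path = outdir / name
        frame.to_csv(path, sep="\t", na_rep="NA", **kw)
        manifest["outputs"].append(name)
        return name

    def stage(name):
        logger.info("stage %s starting (t=%.1fs)", name, time.time() - t0)
        manifest["stages"][name] = {"t_start": round(time.time() - t0, 2)}
        return name

    try:
        # ---- inputs -------------------------------------------------------
        stage("input")
        truth = None
        if config.synthetic is not None:
            proteome, metabolome, metadata, truth = generate_cohort(config.synthetic)
            truth.to_json(outdir / "ground_truth.json")
            manifest["outputs"].append("ground_truth.json")
            write_feature_table(proteome, outdir / "proteome.tsv")
            write_feature_table(metabolome, outdir / "metabolome.tsv")
            write_metadata(metadata, outdir / "metadata.tsv")
            manifest["outputs"] += ["proteome.tsv", "metabolome.tsv", "metadata.tsv"]
        else:
            proteome = (read_feature_table(config.proteome_path, "protein")
                        if config.proteome_path else None)
            metabolome = (read_feature_table(config.metabolome_path, "metabolite")
                          if config.metabolome_path else None)
            if config.metadata_path is None:
                raise PipelineError("input: metadata_path required with table inputs")
            metadata = read_metadata(config.metadata_path)
        layers = {k: t for k, t in [("proteome", proteome), ("metabolome", metabolome)]
                  if t is not None}
        for lname, t in layers.items():
            metadata.check_covers(t)

        # ---- normalization ------------------------------------------------
        stage("normalize")
        layers = {k: tic_normalize(t) for k, t in layers.items()}
        transformed = {}
        for lname, t in layers.items():
            transformed[lname] = log_autoscale(half_min_impute(t))

        # ---- clinical comparisons ----------------------------------------
        stage("clinical")
        clin = compare_clinical(metadata, alpha_gate=config.alpha_gate)
        emit("clinical_comparisons.tsv",
             pd.DataFrame([vars(c) for c in clin]).set_index("covariate"))

        # ---- chemometrics (all features) ---------------------------------
        stage("chemometrics")
        for lname, t in transformed.items():
            res = pca(t, n_components=5)
            emit(f"{lname}_pca_scores.tsv", res.scores)
            emit(f"{lname}_pca_loadings.tsv", res.loadings)
            tree = hca(t)
            (outdir / f"{lname}_hca.nwk").write_text(tree.to_newick() + "\n")
            manifest["outputs"].append(f"{lname}_hca.nwk")
            agree = cluster_agreement(tree.cut(2), metadata.groups)
            manifest["stages"]["chemometrics"][f"{lname}_2cluster_agreement"] = agree

        # ---- differential analysis ---------------------------------------
        stage("differential")
        diff = {}
        for lname, t in layers.items():
            records, summary = call_differential(
                t, metadata, alpha=config.alpha, alpha_gate=config.alpha_gate,
                group_order=config.group_order, min_detected=config.min_detected)
            diff[lname] = records
            emit(f"{lname}_differential.tsv", records)
            manifest["stages"]["differential"][lname] = summary

        # ---- supervised clustering on significant features ----------------
        stage("supervised_hca")
        for lname, records in diff.items():
            sig = records.index[records["significant_raw"].fillna(False)]
            sig = [f for f in sig if f in transformed[lname].values.index]
            if len(sig) >= 2:
                tree = hca(transformed[lname].subset_features(sig))
                (outdir / f"{lname}_hca_significant.nwk").write_text(tree.to_newick() + "\n")
                manifest["outputs"].append(f"{lname}_hca_significant.nwk")

        # ---- univariate classifier screen ---------------------------------
        stage("univariate_screen")
        screens = {}
        for lname, t in transformed.items():
            scr = univariate_screen(t, metadata)
            screens[lname] = scr
            emit(f"{lname}_univariate_screen.tsv", scr)
            manifest["stages"]["univariate_screen"][lname] = {
                "n_auc_1": int((scr["auc"] == 1.0).sum()),
                "n_auc_ge_0.8": int((scr["auc"] >= 0.8).sum()),
            }

        # ---- MCCV panels ---------------------------------------------------
        stage("mccv_panels")
        panels = {}
        for k, (lname, t) in enumerate(transformed.items()):
            res = mccv_panels(
                t, metadata, sizes=config.panel_sizes,
                n_iterations=config.mccv_iterations,
                train_fraction=config.train_fraction,
                seed=_child_seed(config.seed, k))
            panels[lname] = res
            summ = pd.DataFrame(
                [(r.panel_size, r.auc, *r.auc_ci, r.predictive_accuracy) for r in res],
                columns=["panel_size", "auc", "auc_lo", "auc_hi", "balanced_accuracy"],
            ).set_index("panel_size")
            emit(f"{lname}_panel_summary.tsv", summ)
            best, top = panel_report(res, n_features=20)
            emit(f"{lname}_panel_top_features.tsv", top)
            emit(f"{lname}_panel_sample_probabilities.tsv",
                 best.per_sample_probability.rename("p_PR").to_frame())
            manifest["stages"]["mccv_panels"][lname] = {
                "reporting_size": best.panel_size,
                "auc": best.auc,
                "balanced_accuracy": best.predictive_accuracy,
            }

        # ---- enrichment ----------------------------------------------------
        stage("enrichment")
        if config.pathways_path:
            pathways = read_gmt(config.pathways_path)
            hits_by_layer, universe_by_layer = {}, {}
            for lname, records in diff.items():
                tested = records[records["p_value"].notna()]
                hits_by_layer[lname] = set(tested.index[tested["significant_raw"]])
                universe_by_layer[lname] = set(tested.index)
                rec = ora(hits_by_layer[lname], universe_by_layer[lname], pathways)
                emit(f"{lname}_ora.tsv", records_frame(rec))
            if "metabolome" in transformed:
                rec = qea(transformed["metabolome"], metadata, pathways,
                          n_permutations=config.qea_permutations,
                          seed=_child_seed(config.seed, 10))
                emit("metabolome_qea.tsv", records_frame(rec))
            if len(diff) == 2:
                from .enrichment import joint_pathway
                rec = joint_pathway(
                    hits_by_layer.get("proteome", set()),
                    hits_by_layer.get("metabolome", set()),
                    universe_by_layer.get("proteome", set()),
                    universe_by_layer.get("metabolome", set()),
                    pathways)
                emit("joint_pathway.tsv", records_frame(rec))

        # ---- correlations --------------------------------------------------
        stage("correlations")
        if len(diff) == 2:
            def top_sig(lname, n):
                rec = diff[lname]
                sig = rec[rec["significant_raw"].fillna(False)].sort_values("p_value")
                return list(sig.index[:n])

            n_cap = config.max_correlation_features
            prot_ids = [f for f in top_sig("proteome", n_cap)
                        if f in transformed["proteome"].values.index]
            met_ids = [f for f in top_sig("metabolome", n_cap)
                       if f in transformed["metabolome"].values.index]
            if prot_ids and met_ids:
                full, strong = correlation_matrix(
                    transformed["proteome"].subset_features(prot_ids),
                    transformed["metabolome"].subset_features(met_ids),
                    r_threshold=config.r_threshold, alpha=config.alpha)
                emit("cross_omics_correlations.tsv", full, index=False)
                emit("cross_omics_correlations_strong.tsv", strong, index=False)
                manifest["stages"]["correlations"]["n_strong"] = int(len(strong))
            if "rt_dose_gy" in metadata.table.columns:
                sel = {}
                for lname in transformed:
                    best, top = panel_report(panels[lname], n_features=10)
                    sel[lname] = [f for f in top.index
                                  if f in transformed[lname].values.index]
                dose = pd.concat([
                    dose_association(transformed[lname], metadata, ids)
                    for lname, ids in sel.items() if ids
                ], ignore_index=True)
                emit("dose_associations.tsv", dose, index=False)

        manifest["complete"] = True
        manifest["elapsed_seconds"] = round(time.time() - t0, 2)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage-named rewrap
        current = list(manifest["stages"])[-1] if manifest["stages"] else "setup"
        raise PipelineError(f"stage {current!r} failed: {exc}") from exc
    finally:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        root.removeHandler(handler)
        handler.close()
    return manifest


def _jsonable(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["outdir"] = str(d["outdir"])
    return d
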
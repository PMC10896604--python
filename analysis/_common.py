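"""Shared setup for the analysis drivers: one full-scale synthetic cohort.

Every numbered script analyses the same cohort — 24 samples (12 GR / 12 PR),
2741 protein and 119 metabolite features, 20% of features carrying a planted
g=2 shift — generated deterministically from COHORT_SEED so the scripts can
run independently and still agree.
"""

from pathlib import Path

from rtomics import SyntheticConfig, generate_cohort, half_min_impute, log_autoscale

COHORT_SEED = 7
RESULTS = Path(__file__).resolve().parent.parent / "results"


def load_cohort():
    cfg = SyntheticConfig(seed=COHORT_SEED)
    proteome, metabolome, metadata, truth = generate_cohort(cfg)
    return cfg, proteome, metabolome, metadata, truth


def transformed(table):
    return log_autoscale(half_min_impute(table))


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
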
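"""Shared study configuration for the numbered analysis drivers.

The benchmark study: three pancreatic tissues (fetal-like iPSC-PPC, adult
islets, adult whole pancreas) of 150 samples each, ten genes per tissue-sharing
category plus ten tissue-unique singletons and ten null genes, |effect| = 0.8
SD per genotype SD, MAF 0.1-0.5, within-block r2 ~ 0.9, 600 variants per gene
window.
"""

from pathlib import Path

from eqtlshare.config import (
    MODULE_CATEGORIES,
    PipelineConfig,
    SimulationConfig,
    flip_prob_for_r2,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"

SEED = 1


def benchmark_config(seed: int = SEED) -> SimulationConfig:
    counts = {c: 10 for c in MODULE_CATEGORIES}
    counts["singleton-unique"] = 10
    counts["null"] = 10
    return SimulationConfig(
        n_samples=150,
        n_blocks=24,
        variants_per_block=25,
        maf_range=(0.1, 0.5),
        within_block_flip_prob=flip_prob_for_r2(0.9),
        effect_size=0.8,
        category_counts=counts,
        seed=seed,
    )


def pipeline_config() -> PipelineConfig:
    return PipelineConfig()
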
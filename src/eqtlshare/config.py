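"""Configuration objects for simulation and for the analysis pipeline.

All thresholds used downstream live in :class:`PipelineConfig`; the defaults are
the values used throughout the analysis (variant filters, the two-step FDR cut,
colocalization posteriors and overlap filter, module validation rules, LD rules,
and the GWAS significance filter).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

#: The three pancreatic tissues modelled throughout: fetal-like pancreatic
#: progenitors and the two adult tissues.
TISSUES: tuple[str, str, str] = ("iPSC-PPC", "adult-islet", "adult-whole-pancreas")

FETAL = "iPSC-PPC"
ISLET = "adult-islet"
WHOLE_PANCREAS = "adult-whole-pancreas"

#: The seven module sharing categories, by the set of tissues whose eQTLs the
#: module contains.
CATEGORY_TISSUES: Mapping[str, frozenset[str]] = {
    "iPSC-PPC-unique": frozenset({FETAL}),
    "adult-islet-unique": frozenset({ISLET}),
    "adult-whole-pancreas-unique": frozenset({WHOLE_PANCREAS}),
    "adult-shared": frozenset({ISLET, WHOLE_PANCREAS}),
    "fetal-islet": frozenset({FETAL, ISLET}),
    "fetal-whole-pancreas": frozenset({FETAL, WHOLE_PANCREAS}),
    "fetal-adult": frozenset({FETAL, ISLET, WHOLE_PANCREAS}),
}

MODULE_CATEGORIES: tuple[str, ...] = tuple(CATEGORY_TISSUES)

#: Tissues whose signals must show *no* LD with any module member for the module
#: to keep its category (the fetal-adult category needs no exclusion check).
CATEGORY_LD_EXCLUSIONS: Mapping[str, frozenset[str]] = {
    "iPSC-PPC-unique": frozenset({ISLET, WHOLE_PANCREAS}),
    "adult-islet-unique": frozenset({WHOLE_PANCREAS, FETAL}),
    "adult-whole-pancreas-unique": frozenset({ISLET, FETAL}),
    "adult-shared": frozenset({FETAL}),
    "fetal-islet": frozenset({WHOLE_PANCREAS}),
    "fetal-whole-pancreas": frozenset({ISLET}),
    "fetal-adult": frozenset(),
}

PLANTABLE_CATEGORIES: tuple[str, ...] = MODULE_CATEGORIES + ("singleton-unique", "null")

GENE_EXPRESSION = "gene-expression"
ISOFORM_USAGE = "isoform-usage"


class ConfigurationError(ValueError):
    """An invalid configuration value, naming the offending field."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic multi-tissue study.

    The genotype model is block LD: each gene window carries ``n_blocks``
    latent haplotype blocks of ``variants_per_block`` variants; each variant
    copies its block haplotype except with probability ``within_block_flip_prob``
    it is re-drawn from the block allele frequency, so pairwise within-block
    r² = (1 - flip_prob)^4 while the marginal MAF is preserved.
    """

    n_samples: int = 150
    n_blocks: int = 24
    variants_per_block: int = 25
    maf_range: tuple[float, float] = (0.1, 0.5)
    within_block_flip_prob: float = 0.026
    effect_size: float = 0.8
    noise_sd: float = 1.0
    polygenic_sd: float = 0.3
    n_sibling_pairs: int = 0
    category_counts: Mapping[str, int] = field(default_factory=dict)
    seed: int = 1

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not (0.0 <= self.within_block_flip_prob <= 0.5):
            raise ConfigurationError(
                f"within_block_flip_prob must be in [0, 0.5], got {self.within_block_flip_prob}"
            )
        for name in ("n_samples", "n_blocks", "variants_per_block", "n_sibling_pairs"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.noise_sd < 0 or self.polygenic_sd < 0:
            raise ConfigurationError("noise_sd and polygenic_sd must be >= 0")
        for cat in self.category_counts:
            if cat not in PLANTABLE_CATEGORIES:
                raise ConfigurationError(
                    f"category_counts key {cat!r} not one of {PLANTABLE_CATEGORIES}"
                )
            if self.category_counts[cat] < 0:
                raise ConfigurationError(f"category_counts[{cat!r}] must be >= 0")
        if self.n_sibling_pairs * 2 > self.n_samples:
            raise ConfigurationError("n_sibling_pairs exceeds half the sample count")

    @property
    def variants_per_gene(self) -> int:
        return self.n_blocks * self.variants_per_block


def flip_prob_for_r2(r2: float) -> float:
    """Flip probability giving a target within-block pairwise r²."""
    if not (0.0 < r2 <= 1.0):
        raise ConfigurationError(f"target r2 must be in (0, 1], got {r2}")
    return 1.0 - r2 ** 0.25


@dataclass(frozen=True)
class ColocPriors:
    """Per-variant prior probabilities for the five-hypothesis colocalization."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        if not (0.0 < self.p12 <= min(self.p1, self.p2) < 1.0):
            raise ConfigurationError(
                f"require 0 < p12 <= min(p1, p2) < 1, got p1={self.p1} p2={self.p2} p12={self.p12}"
            )


@dataclass(frozen=True)
class AbfPriors:
    """Prior on the standardized effect size for the Wakefield approximate BF.

    ``w_sd`` is the prior standard deviation of the effect per standardized
    trait unit: 0.15 for quantitative traits, 0.2 for case-control.
    """

    w_sd: float = 0.15
    trait_type: str = "quantitative"

    def __post_init__(self) -> None:
        if self.w_sd <= 0:
            raise ConfigurationError(f"w_sd must be > 0, got {self.w_sd}")
        if self.trait_type not in ("quantitative", "case-control"):
            raise ConfigurationError(f"unknown trait_type {self.trait_type!r}")

    @classmethod
    def for_trait(cls, trait_type: str) -> "AbfPriors":
        return cls(w_sd=0.2 if trait_type == "case-control" else 0.15, trait_type=trait_type)


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and priors for every stage of the analysis."""

    # variant filters
    maf_min: float = 0.05
    hwe_p_min: float = 1e-6
    call_rate_min: float = 0.99
    cis_window_bp: int = 500_000
    # expressed-feature filters
    tpm_min: float = 1.0
    usage_min: float = 0.10
    expressed_fraction: float = 0.10
    # association / FDR
    q_cut: float = 0.01
    max_conditional: int = 5
    eigenmt_window: int = 200
    eigenmt_var_explained: float = 0.99
    # fine-mapping
    credible_level: float = 0.99
    candidate_pp_min: float = 0.01
    enrichment_pp_min: float = 0.05
    # colocalization
    nsnps_min: int = 500
    pp_h4_cut: float = 0.8
    pp_h3_cut: float = 0.8
    coloc_window_bp: int = 3_000_000
    coloc_priors: ColocPriors = field(default_factory=ColocPriors)
    abf_priors: AbfPriors = field(default_factory=AbfPriors)
    # modules
    module_h4_fraction: float = 0.3
    h4_h3_ratio: float = 2.0
    leiden_resolution: float = 0.3
    leiden_iterations: int = 500
    leiden_seed: int = 1
    count_all_pairs: bool = True
    # LD / tissue-sharing rules
    ld_r2_min: float = 0.2
    ld_window_bp: int = 500_000
    # GWAS
    gwas_p_cut: float = 5e-8

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Stable short hash of the configuration, recorded in output headers."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _from_mapping(cls, data: Mapping):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigurationError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    kwargs = dict(data)
    if cls is PipelineConfig:
        if isinstance(kwargs.get("coloc_priors"), Mapping):
            kwargs["coloc_priors"] = ColocPriors(**kwargs["coloc_priors"])
        if isinstance(kwargs.get("abf_priors"), Mapping):
            kwargs["abf_priors"] = AbfPriors(**kwargs["abf_priors"])
    if cls is SimulationConfig and isinstance(kwargs.get("maf_range"), list):
        kwargs["maf_range"] = tuple(kwargs["maf_range"])
    if cls is SimulationConfig and isinstance(kwargs.get("category_counts"), Mapping):
        # YAML reads the bare key `null:` as None; it means the "null" category
        kwargs["category_counts"] = {
            ("null" if k is None else k): v for k, v in kwargs["category_counts"].items()
        }
    return cls(**kwargs)


def load_config(path: str | Path) -> tuple[SimulationConfig, PipelineConfig]:
    """Load a YAML/JSON config with optional ``simulation:`` and ``pipeline:`` blocks."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    sim = _from_mapping(SimulationConfig, data.get("simulation", {}))
    pipe = _from_mapping(PipelineConfig, data.get("pipeline", {}))
    return sim, pipe
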
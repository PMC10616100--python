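"""GWAS integration: colocalize trait associations with eQTL signals and
modules, apply the eligibility filters, and build per-locus 99% credible sets.

An eQTL-GWAS colocalization is accepted only if (i) the pair shares at least
500 variants and (ii) the top shared candidate causal variant is genome-wide
significant for the GWAS trait (p <= 5e-8). A module colocalizes with a trait
when at least 30% of its members individually colocalize (PP.H4 >= 0.8) and
the member-level H4 count is at least twice the H3 count. Each accepted
(eQTL unit, trait) combination is one GWAS locus; for modules, the reported
99% credible set comes from the member whose colocalization yields the fewest
candidate variants (ties broken by the highest PP.H4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AbfPriors, ConfigurationError, PipelineConfig
from .coloc import INSUFFICIENT_OVERLAP, SHARED, ColocResult, coloc_pair

REJECTED_OVERLAP = "rejected_overlap"
REJECTED_GWAS_SIGNIFICANCE = "rejected_gwas_significance"


@dataclass
class GwasColoc:
    """Outcome of one eQTL-signal vs GWAS-trait colocalization."""

    signal_id: str
    trait: str
    result: ColocResult
    status: str  # shared | distinct | underpowered | rejected_*
    lead_shared_variant: str = ""
    lead_gwas_p: float = np.nan

    @property
    def accepted(self) -> bool:
        return self.status not in (REJECTED_OVERLAP, REJECTED_GWAS_SIGNIFICANCE)


@dataclass
class GwasLocus:
    """One (colocalized eQTL unit, trait) combination."""

    locus_id: str
    trait: str
    unit_id: str  # signal id or module id
    unit_kind: str  # "singleton" | "module"
    pp_h4: float
    source_signal: str
    credible_set: pd.DataFrame  # variant, pos, pp
    lead_shared_variant: str
    lead_gwas_p: float

    @property
    def credible_set_size(self) -> int:
        return len(self.credible_set)

    @property
    def size_bucket(self) -> str:
        k = self.credible_set_size
        return "1" if k == 1 else ("2-10" if k <= 10 else ">10")


def coloc_eqtl_gwas(
    eqtl_table: pd.DataFrame,
    gwas_table: pd.DataFrame,
    signal_id: str,
    trait: str,
    config: PipelineConfig | None = None,
    gwas_priors: AbfPriors | None = None,
) -> GwasColoc:
    """Colocalize one eQTL signal with one GWAS trait and apply both filters.

    The GWAS trait's ABF prior follows its declared trait type (quantitative
    by default). The significance filter applies to the maximum-posterior
    shared variant from the colocalization output.
    """
    config = config or PipelineConfig()
    gwas_priors = gwas_priors or config.abf_priors
    result = coloc_pair(eqtl_table, gwas_table, config, config.abf_priors, gwas_priors)
    if result.classification == INSUFFICIENT_OVERLAP:
        return GwasColoc(signal_id, trait, result, REJECTED_OVERLAP)
    shared_pp = result.shared_variant_posteriors()
    lead_idx = int(np.argmax(shared_pp["pp"].to_numpy()))
    lead_variant = str(shared_pp["variant"].iloc[lead_idx])
    gwas_p = float(
        gwas_table.loc[gwas_table["variant"] == lead_variant, "p"].iloc[0]
    )
    if gwas_p > config.gwas_p_cut:
        return GwasColoc(
            signal_id, trait, result, REJECTED_GWAS_SIGNIFICANCE, lead_variant, gwas_p
        )
    return GwasColoc(signal_id, trait, result, result.classification, lead_variant, gwas_p)


def call_module_gwas(
    member_colocs: list[GwasColoc], config: PipelineConfig | None = None
) -> bool:
    """Module-level colocalization call for one trait.

    True iff the fraction of members with an accepted H4 colocalization is at
    least ``module_h4_fraction`` of *all* members, and the H4 count is at
    least ``h4_h3_ratio`` times the H3 count. Members rejected on overlap
    count toward the denominator (the stricter reading).
    """
    config = config or PipelineConfig()
    if not member_colocs:
        return False
    n = len(member_colocs)
    n_h4 = sum(1 for c in member_colocs if c.accepted and c.status == SHARED)
    n_h3 = sum(1 for c in member_colocs if c.accepted and c.status == "distinct")
    return (n_h4 / n) >= config.module_h4_fraction and n_h4 >= config.h4_h3_ratio * n_h3


def gwas_credible_set(
    coloc: GwasColoc, level: float = 0.99
) -> pd.DataFrame:
    """99% credible set over the shared causal variant, from the per-variant
    joint posteriors of the eQTL-GWAS colocalization."""
    pp = coloc.result.shared_variant_posteriors()
    pp = pp.sort_values(["pp", "pos"], ascending=[False, True], kind="mergesort")
    cum = pp["pp"].cumsum().to_numpy()
    k = min(int(np.searchsorted(cum, level - 1e-12) + 1), len(pp))
    return pp.iloc[:k].reset_index(drop=True)


def select_locus_credible_set(
    candidates: list[GwasColoc],
    trait: str,
    unit_id: str,
    unit_kind: str,
    config: PipelineConfig | None = None,
) -> GwasLocus:
    """Build the locus from the member colocalization giving the smallest 99%
    credible set; ties broken by the highest PP.H4."""
    config = config or PipelineConfig()
    shared = [c for c in candidates if c.accepted and c.status == SHARED]
    if not shared:
        raise ConfigurationError("locus has no accepted shared colocalization")
    scored = [(gwas_credible_set(c, config.credible_level), c) for c in shared]
    scored.sort(key=lambda sc: (len(sc[0]), -sc[1].result.pp_h4))
    cs, best = scored[0]
    return GwasLocus(
        locus_id=f"{trait}|{unit_id}",
        trait=trait,
        unit_id=unit_id,
        unit_kind=unit_kind,
        pp_h4=best.result.pp_h4,
        source_signal=best.signal_id,
        credible_set=cs,
        lead_shared_variant=best.lead_shared_variant,
        lead_gwas_p=best.lead_gwas_p,
    )


def define_gwas_loci(loci: list[GwasLocus]) -> pd.DataFrame:
    """Locus report: one row per (unit, trait) with the credible-set size
    bucket (1, 2-10, >10)."""
    rows = [
        {
            "locus_id": l.locus_id,
            "trait": l.trait,
            "unit_id": l.unit_id,
            "unit_kind": l.unit_kind,
            "pp_h4": l.pp_h4,
            "source_signal": l.source_signal,
            "credible_set_size": l.credible_set_size,
            "size_bucket": l.size_bucket,
            "lead_shared_variant": l.lead_shared_variant,
            "lead_gwas_p": l.lead_gwas_p,
        }
        for l in loci
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "locus_id", "trait", "unit_id", "unit_kind", "pp_h4", "source_signal",
            "credible_set_size", "size_bucket", "lead_shared_variant", "lead_gwas_p",
        ],
    )


def bucket_histogram(report: pd.DataFrame) -> dict[str, int]:
    counts = {"1": 0, "2-10": 0, ">10": 0}
    for b in report.get("size_bucket", []):
        counts[b] += 1
    return counts
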
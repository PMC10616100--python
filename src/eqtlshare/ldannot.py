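"""LD-based tissue-specificity annotation.

Signals that colocalize with nothing are candidate tissue-unique singletons;
before accepting that label, each is checked for LD against every other signal
of the same phenotype class (conditional leads included) using representative
candidate causal variants in a reference panel. Two signals are "in LD" when
their representative variants lie within 500 Kb and have r^2 >= 0.2 — or when
r^2 cannot be computed (variant absent from the panel), in which case distance
alone decides. Singletons in LD with any other signal become "ambiguous".

Validated modules are classified into seven tissue-sharing categories from
their member tissues, then subjected to per-category LD exclusions (e.g. a
fetal-islet module requires that no member is in LD with any whole-pancreas
signal); violations make the whole module ambiguous. Modules spanning fetal
and adult tissues additionally get per-adult-tissue eGene-overlap labels
(zero / same / partial / different) summarising regulatory plasticity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import (
    CATEGORY_LD_EXCLUSIONS,
    CATEGORY_TISSUES,
    FETAL,
    ISLET,
    WHOLE_PANCREAS,
    PipelineConfig,
)
from .finemap import FineMapResult
from .network import Module
from .synth import GenotypePanel

SINGLETON = "singleton"
COMBINATORIAL = "combinatorial"
AMBIGUOUS = "ambiguous"
INELIGIBLE = "ineligible"

TISSUE_UNIQUE_CATEGORY = {
    FETAL: "iPSC-PPC-unique",
    ISLET: "adult-islet-unique",
    WHOLE_PANCREAS: "adult-whole-pancreas-unique",
}

ADULT_TISSUES = (ISLET, WHOLE_PANCREAS)


@dataclass(frozen=True)
class RepVariant:
    """A signal's representative candidate causal variant for LD checks."""

    variant: str
    chrom: str
    pos: int
    in_panel: bool


@dataclass
class TissueAnnotation:
    signal_id: str
    mode: str  # singleton | combinatorial | ambiguous | ineligible
    category: str = ""
    module_id: str = ""


def ld_r2(panel: GenotypePanel, v1: str, v2: str) -> float | None:
    """Squared Pearson correlation of the two dosage vectors in the reference
    panel; None when either variant is absent or monomorphic."""
    if not (panel.has_variant(v1) and panel.has_variant(v2)):
        return None
    a, b = panel.dosage_of(v1), panel.dosage_of(v2)
    if a.std() == 0 or b.std() == 0:
        return None
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def representative_variant(
    result: FineMapResult,
    panel: GenotypePanel,
    chrom: str,
    pp_min: float = 0.01,
) -> RepVariant | None:
    """Highest-posterior variant genotyped in the reference panel.

    Walks the pp-descending order over variants with pp >= ``pp_min``; if none
    is genotyped, returns the top variant flagged panel-absent. Returns None
    when the signal has no variant with pp >= ``pp_min`` at all (the signal is
    then ineligible for annotation)."""
    df = result.table[result.table["pp"] >= pp_min]
    if df.empty:
        return None
    df = df.sort_values(["pp", "pos"], ascending=[False, True], kind="mergesort")
    for _, row in df.iterrows():
        if panel.has_variant(str(row["variant"])):
            return RepVariant(str(row["variant"]), str(chrom), int(row["pos"]), True)
    top = df.iloc[0]
    return RepVariant(str(top["variant"]), str(chrom), int(top["pos"]), False)


def eqtls_in_ld(
    a: RepVariant,
    b: RepVariant,
    panel: GenotypePanel,
    config: PipelineConfig | None = None,
) -> bool:
    """True iff the representative variants are within 500 Kb and either
    r^2 >= 0.2 or r^2 is unavailable (distance fallback). Distance beyond
    500 Kb is never in LD, whatever the r^2."""
    config = config or PipelineConfig()
    if a.chrom != b.chrom:
        return False
    if abs(a.pos - b.pos) > config.ld_window_bp:
        return False
    r2 = ld_r2(panel, a.variant, b.variant)
    if r2 is None:
        return True
    return r2 >= config.ld_r2_min


@dataclass(frozen=True)
class SignalContext:
    """What the annotator needs to know about one significant signal."""

    signal_id: str
    tissue: str
    feature_class: str
    gene: str
    rep: RepVariant | None  # None -> ineligible
    has_h4: bool  # at least one shared colocalization


def annotate_singleton(
    signal: SignalContext,
    all_signals: Iterable[SignalContext],
    panel: GenotypePanel,
    config: PipelineConfig | None = None,
) -> TissueAnnotation:
    """Annotate a candidate singleton (a signal with zero H4 classifications).

    Ambiguous if in LD with any other signal of the same phenotype class in
    any tissue; otherwise a tissue-unique singleton of its own tissue.
    """
    config = config or PipelineConfig()
    if signal.rep is None:
        return TissueAnnotation(signal.signal_id, INELIGIBLE)
    if signal.has_h4:
        return TissueAnnotation(signal.signal_id, COMBINATORIAL)
    for other in all_signals:
        if other.signal_id == signal.signal_id:
            continue
        if other.feature_class != signal.feature_class or other.rep is None:
            continue
        if eqtls_in_ld(signal.rep, other.rep, panel, config):
            return TissueAnnotation(signal.signal_id, AMBIGUOUS)
    return TissueAnnotation(
        signal.signal_id, SINGLETON, TISSUE_UNIQUE_CATEGORY[signal.tissue]
    )


def categorize_module(
    module: Module,
    contexts: Mapping[str, SignalContext],
    all_signals: Iterable[SignalContext],
    panel: GenotypePanel,
    config: PipelineConfig | None = None,
) -> str:
    """Seven-way category from member tissues, then the per-category LD
    exclusion: every member must show no LD with any signal of the excluded
    tissue(s) (same phenotype class); violations return "ambiguous"."""
    config = config or PipelineConfig()
    members = [contexts[m] for m in module.members]
    tissues = frozenset(m.tissue for m in members)
    category = next(
        (c for c, ts in CATEGORY_TISSUES.items() if ts == tissues), None
    )
    if category is None:  # cannot happen with the three modelled tissues
        return AMBIGUOUS
    excluded = CATEGORY_LD_EXCLUSIONS[category]
    if not excluded:
        return category
    member_ids = set(module.members)
    foreign = [
        s
        for s in all_signals
        if s.tissue in excluded
        and s.feature_class == module.feature_class
        and s.signal_id not in member_ids
        and s.rep is not None
    ]
    for m in members:
        if m.rep is None:
            return AMBIGUOUS
        for s in foreign:
            if eqtls_in_ld(m.rep, s.rep, panel, config):
                return AMBIGUOUS
    return category


def egene_overlap_label(
    module: Module, contexts: Mapping[str, SignalContext]
) -> dict[str, str]:
    """Per-adult-tissue eGene-overlap label for a module.

    "zero": no member from that tissue; "same": identical gene sets between
    fetal and adult members; "different": disjoint; "partial": otherwise.
    Splicing signals are compared through their parent gene.
    """
    members = [contexts[m] for m in module.members]
    fetal_genes = {m.gene for m in members if m.tissue == FETAL}
    labels = {}
    for tissue in ADULT_TISSUES:
        adult_genes = {m.gene for m in members if m.tissue == tissue}
        if not adult_genes:
            labels[tissue] = "zero"
        elif fetal_genes == adult_genes:
            labels[tissue] = "same"
        elif fetal_genes.isdisjoint(adult_genes):
            labels[tissue] = "different"
        else:
            labels[tissue] = "partial"
    return labels


def plasticity_category(labels: Mapping[str, str]) -> str | None:
    """A-E plasticity scheme for a fetal-sharing module from its two
    per-adult-tissue overlap labels.

    A: same eGenes with exactly one adult tissue (other absent); B: same with
    both; C: partial overlap (any partial, or mixed same/different); D:
    different genes with one adult tissue; E: different with both. None for
    modules without any adult-tissue comparison.
    """
    vals = [v for v in labels.values() if v != "zero"]
    if not vals:
        return None
    if all(v == "same" for v in vals):
        return "A" if len(vals) == 1 else "B"
    if all(v == "different" for v in vals):
        return "D" if len(vals) == 1 else "E"
    return "C"


def summarize_plasticity(labels_per_module: Mapping[str, Mapping[str, str]]) -> pd.Series:
    """Counts of plasticity categories A-E over fetal-sharing modules."""
    counts = {c: 0 for c in "ABCDE"}
    for labels in labels_per_module.values():
        cat = plasticity_category(labels)
        if cat is not None:
            counts[cat] += 1
    return pd.Series(counts)
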
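"""End-to-end orchestration of the synthetic multi-tissue eQTL study.

Stages: simulate cohorts -> per-tissue mixed-model scan with two-step FDR and
stepwise conditional rounds -> per-signal fine-mapping -> pairwise
colocalization of nearby signals (within phenotype class) -> colocalization
network modules -> LD-based tissue-sharing annotation -> GWAS integration.
Ground truth travels alongside, so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ldannot
from .coloc import SHARED, coloc_pair
from .config import (
    GENE_EXPRESSION,
    TISSUES,
    PipelineConfig,
    SimulationConfig,
)
from .finemap import FineMapResult, finemap_posteriors
from .gwas import (
    GwasColoc,
    GwasLocus,
    call_module_gwas,
    coloc_eqtl_gwas,
    select_locus_credible_set,
)
from .ldannot import (
    AMBIGUOUS,
    COMBINATORIAL,
    SINGLETON,
    SignalContext,
    TissueAnnotation,
    annotate_singleton,
    categorize_module,
    egene_overlap_label,
    representative_variant,
)
from .network import (
    VALIDATED,
    Module,
    assign_module_ids,
    build_coloc_graph,
    detect_communities,
    validate_module,
)
from .scan import (
    EqtlSignal,
    KinshipSpectral,
    effective_tests,
    genomewide_fdr,
    lmm_scan,
    quantile_normalize,
    select_lead,
)
from .synth import (
    GenotypePanel,
    KinshipMatrix,
    compute_kinship,
    plant_sharing_structure,
    simulate_genotype_panel,
    simulate_phenotypes,
)

REF_PANEL_INDEX = 99  # sample-draw index of the LD reference panel


@dataclass
class StudyData:
    """A complete simulated study: per-tissue cohorts plus ground truth."""

    sim_config: SimulationConfig
    panels: dict[str, GenotypePanel]
    kinships: dict[str, KinshipMatrix]
    phenotypes: dict[str, pd.DataFrame]
    truth: pd.DataFrame
    ref_panel: GenotypePanel


def simulate_study(sim_config: SimulationConfig) -> StudyData:
    """Independent genotype cohorts per tissue (same variant map), kinship,
    planted truth, per-tissue phenotypes, and an LD reference panel."""
    panels = {
        t: simulate_genotype_panel(sim_config, panel_index=i)
        for i, t in enumerate(TISSUES)
    }
    ref_panel = simulate_genotype_panel(sim_config, panel_index=REF_PANEL_INDEX)
    kinships = {t: compute_kinship(p) for t, p in panels.items()}
    truth = plant_sharing_structure(sim_config, panels[TISSUES[0]])
    phenotypes = {
        t: simulate_phenotypes(panels[t], truth, kinships[t], sim_config, t)
        for t in TISSUES
    }
    return StudyData(sim_config, panels, kinships, phenotypes, truth, ref_panel)


@dataclass
class PipelineResult:
    """Everything downstream stages and the scorer need."""

    signals: dict[str, EqtlSignal] = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    finemaps: dict[str, FineMapResult] = field(default_factory=dict)
    pair_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    modules: list[Module] = field(default_factory=list)
    module_categories: dict[str, str] = field(default_factory=dict)
    overlap_labels: dict[str, dict[str, str]] = field(default_factory=dict)
    annotations: dict[str, TissueAnnotation] = field(default_factory=dict)
    contexts: dict[str, SignalContext] = field(default_factory=dict)
    gwas_loci: list[GwasLocus] = field(default_factory=list)
    gwas_colocs: list[GwasColoc] = field(default_factory=list)

    def signals_table(self) -> pd.DataFrame:
        rows = []
        for sid, s in self.signals.items():
            ann = self.annotations.get(sid)
            rows.append(
                {
                    "signal_id": sid,
                    "tissue": s.tissue,
                    "feature": s.feature,
                    "feature_class": s.feature_class,
                    "rank": s.rank,
                    "lead_variant": s.lead_variant,
                    "lead_beta": s.lead_beta,
                    "p_gene_corrected": s.p_gene_corrected,
                    "q": s.q,
                    "mode": ann.mode if ann else "",
                    "category": ann.category if ann else "",
                    "module_id": ann.module_id if ann else "",
                }
            )
        return pd.DataFrame(rows)


def scan_tissue(
    panel: GenotypePanel,
    kinship: KinshipMatrix,
    phenotypes: pd.DataFrame,
    tissue: str,
    config: PipelineConfig,
    covariates: np.ndarray | None = None,
    feature_class: str = GENE_EXPRESSION,
) -> tuple[dict[str, EqtlSignal], dict[str, pd.DataFrame]]:
    """Round-wise scan of one tissue: each round scans every still-active
    feature (conditioning on its prior leads), applies the gene-level M_eff
    correction, then Benjamini-Hochberg across the round's feature leads;
    features stop when their lead is no longer significant or after five
    conditional rounds.

    The random-effect covariance is the leave-one-chromosome-out kinship for
    each scanned chromosome (the tested cis variants must not contribute to
    the kinship, or the random effect absorbs the signal); where the panel
    offers no off-chromosome variants the cohort kinship is used as given.
    """
    from .synth import standardized_dosages

    x_all, poly = standardized_dosages(panel.dosages)
    s_full = x_all @ x_all.T
    m_full = int(poly.sum())
    chroms = panel.variants["chrom"].astype(str).to_numpy()
    spectral_by_chrom: dict[str, KinshipSpectral] = {}

    def spectral_for(chrom: str) -> KinshipSpectral:
        if chrom not in spectral_by_chrom:
            on = (chroms == chrom) & poly
            m_loco = m_full - int(on.sum())
            if m_loco >= 2:
                x_c = x_all[:, on]
                k = (s_full - x_c @ x_c.T) / m_loco
                k = KinshipMatrix((k + k.T) / 2.0, list(panel.sample_ids))
            else:
                k = kinship
            spectral_by_chrom[chrom] = KinshipSpectral.from_kinship(k)
        return spectral_by_chrom[chrom]

    gene_chrom = {
        str(r["gene"]): str(r["chrom"]) for _, r in panel.genes.iterrows()
    }
    genes = list(phenotypes.columns)
    norm = quantile_normalize(phenotypes.to_numpy())
    gene_idx = {g: panel.gene_variant_indices(g) for g in genes}
    gene_vars = {g: panel.variants.iloc[gene_idx[g]].reset_index(drop=True) for g in genes}
    m_eff = {
        g: effective_tests(
            panel.dosages[:, gene_idx[g]],
            window=config.eigenmt_window,
            var_explained=config.eigenmt_var_explained,
        )
        for g in genes
        if gene_idx[g].size
    }

    signals: dict[str, EqtlSignal] = {}
    tables: dict[str, pd.DataFrame] = {}
    lead_dosages: dict[str, list[np.ndarray]] = {g: [] for g in genes}
    active = [g for g in genes if gene_idx[g].size]
    for rank in range(config.max_conditional + 1):
        if not active:
            break
        round_leads: dict[str, pd.Series] = {}
        round_tables: dict[str, pd.DataFrame] = {}
        for g in active:
            j = genes.index(g)
            cov = covariates
            if lead_dosages[g]:
                extra = np.column_stack(lead_dosages[g])
                cov = extra if cov is None else np.column_stack([cov, extra])
            table = lmm_scan(
                norm[:, j],
                panel.dosages[:, gene_idx[g]],
                gene_vars[g],
                cov,
                spectral_for(gene_chrom[g]),
            )
            table["p_gene_corrected"] = np.minimum(1.0, table["p"] * m_eff[g])
            round_tables[g] = table
            round_leads[g] = select_lead(table)
        fdr = genomewide_fdr(
            pd.Series({g: round_leads[g]["p_gene_corrected"] for g in active}),
            config.q_cut,
        )
        next_active = []
        for g in active:
            if not bool(fdr.loc[g, "significant"]):
                continue
            lead = round_leads[g]
            sig = EqtlSignal(
                tissue=tissue,
                feature=g,
                feature_class=feature_class,
                rank=rank,
                lead_variant=str(lead["variant"]),
                lead_beta=float(lead["beta"]),
                p_gene_corrected=float(lead["p_gene_corrected"]),
                q=float(fdr.loc[g, "q"]),
            )
            signals[sig.signal_id] = sig
            tables[sig.signal_id] = round_tables[g]
            var_index = pd.Index(gene_vars[g]["id"])
            lead_dosages[g].append(
                panel.dosages[:, gene_idx[g]][:, var_index.get_loc(sig.lead_variant)]
            )
            next_active.append(g)
        active = next_active
    return signals, tables


def _gene_body(panel: GenotypePanel) -> dict[str, tuple[str, int, int]]:
    return {
        str(r["gene"]): (str(r["chrom"]), int(r["body_start"]), int(r["body_end"]))
        for _, r in panel.genes.iterrows()
    }


def colocalize_signals(
    result: PipelineResult, panel: GenotypePanel, config: PipelineConfig
) -> pd.DataFrame:
    """Test every candidate signal pair: same phenotype class, same chromosome,
    gene bodies within the 3 Mb colocalization window."""
    bodies = _gene_body(panel)
    sids = sorted(result.signals)
    rows = []
    for i, a in enumerate(sids):
        sa = result.signals[a]
        ca, sa_start, sa_end = bodies[sa.feature]
        for b in sids[i + 1 :]:
            sb = result.signals[b]
            cb, sb_start, sb_end = bodies[sb.feature]
            if sa.feature_class != sb.feature_class or ca != cb:
                continue
            gap = max(sb_start - sa_end, sa_start - sb_end, 0)
            if gap > config.coloc_window_bp:
                continue
            res = coloc_pair(result.tables[a], result.tables[b], config)
            rows.append(
                {
                    "signal_a": a,
                    "signal_b": b,
                    "chrom": ca,
                    "feature_class": sa.feature_class,
                    "pp_h3": res.pp_h3,
                    "pp_h4": res.pp_h4,
                    "nsnps": res.nsnps,
                    "classification": res.classification,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "signal_a", "signal_b", "chrom", "feature_class",
            "pp_h3", "pp_h4", "nsnps", "classification",
        ],
    )


def build_modules(result: PipelineResult, config: PipelineConfig) -> list[Module]:
    modules: list[Module] = []
    if result.pair_table.empty:
        return modules
    strata = result.pair_table.groupby(["chrom", "feature_class"]).groups
    for (chrom, fclass) in strata:
        graph = build_coloc_graph(result.pair_table, chrom, fclass, config)
        for module in detect_communities(
            graph, config.leiden_resolution, config.leiden_iterations, config.leiden_seed
        ):
            modules.append(validate_module(module, graph, config))
    positions = {
        sid: _lead_pos(result, sid) for sid in result.signals
    }
    return assign_module_ids(modules, positions)


def _lead_pos(result: PipelineResult, sid: str) -> int:
    t = result.tables[sid]
    lead = result.signals[sid].lead_variant
    return int(t.loc[t["variant"] == lead, "pos"].iloc[0])


def annotate_sharing(
    result: PipelineResult, ref_panel: GenotypePanel, config: PipelineConfig
) -> None:
    """Build signal contexts (representative variants, H4 flags) and assign
    every significant signal a mode and (where applicable) a category."""
    has_h4: dict[str, bool] = {sid: False for sid in result.signals}
    for _, row in result.pair_table.iterrows():
        if row["classification"] == SHARED:
            has_h4[str(row["signal_a"])] = True
            has_h4[str(row["signal_b"])] = True

    for sid, sig in result.signals.items():
        fm = result.finemaps[sid]
        chrom = str(result.tables[sid]["chrom"].iloc[0])
        rep = representative_variant(fm, ref_panel, chrom, config.candidate_pp_min)
        result.contexts[sid] = SignalContext(
            signal_id=sid,
            tissue=sig.tissue,
            feature_class=sig.feature_class,
            gene=sig.feature,
            rep=rep,
            has_h4=has_h4[sid],
        )

    all_ctx = list(result.contexts.values())
    in_module: dict[str, Module] = {}
    for module in result.modules:
        if module.status == VALIDATED:
            for m in module.members:
                in_module[m] = module

    for module in result.modules:
        if module.status != VALIDATED:
            continue
        category = categorize_module(module, result.contexts, all_ctx, ref_panel, config)
        result.module_categories[module.module_id] = category
        result.overlap_labels[module.module_id] = egene_overlap_label(
            module, result.contexts
        )

    for sid, ctx in result.contexts.items():
        if sid in in_module:
            module = in_module[sid]
            category = result.module_categories.get(module.module_id, "")
            mode = AMBIGUOUS if category == AMBIGUOUS else COMBINATORIAL
            result.annotations[sid] = TissueAnnotation(
                sid, mode, "" if category == AMBIGUOUS else category, module.module_id
            )
        elif ctx.has_h4:
            # shared with something, but its community failed validation
            result.annotations[sid] = TissueAnnotation(sid, COMBINATORIAL, "")
        else:
            result.annotations[sid] = annotate_singleton(ctx, all_ctx, ref_panel, config)


def run_pipeline(
    study: StudyData, config: PipelineConfig | None = None
) -> PipelineResult:
    """Scan all tissues, fine-map, colocalize, build modules, annotate."""
    config = config or PipelineConfig()
    result = PipelineResult()
    for tissue in TISSUES:
        signals, tables = scan_tissue(
            study.panels[tissue],
            study.kinships[tissue],
            study.phenotypes[tissue],
            tissue,
            config,
        )
        result.signals.update(signals)
        result.tables.update(tables)
    for sid, table in result.tables.items():
        result.finemaps[sid] = finemap_posteriors(
            table, config.abf_priors, config.credible_level
        )
    result.pair_table = colocalize_signals(result, study.panels[TISSUES[0]], config)
    result.modules = build_modules(result, config)
    annotate_sharing(result, study.ref_panel, config)
    return result


# ---------------------------------------------------------------------------
# GWAS integration over a pipeline result


def integrate_gwas(
    result: PipelineResult,
    gwas_tables: dict[str, pd.DataFrame],
    config: PipelineConfig | None = None,
    trait_types: dict[str, str] | None = None,
) -> list[GwasLocus]:
    """Colocalize each GWAS trait with every singleton signal and module.

    ``gwas_tables`` maps trait name -> association table. Returns the accepted
    loci (one per colocalized unit x trait); member-level colocalizations are
    kept on the result for audit.
    """
    from .config import AbfPriors

    config = config or PipelineConfig()
    trait_types = trait_types or {}
    loci: list[GwasLocus] = []

    module_of: dict[str, str] = {}
    validated_modules = [
        m
        for m in result.modules
        if m.status == VALIDATED
        and result.module_categories.get(m.module_id, "") != AMBIGUOUS
    ]
    for m in validated_modules:
        for sid in m.members:
            module_of[sid] = m.module_id

    for trait, gtable in gwas_tables.items():
        priors = AbfPriors.for_trait(trait_types.get(trait, "quantitative"))
        colocs: dict[str, GwasColoc] = {}
        for sid in result.signals:
            gc = coloc_eqtl_gwas(result.tables[sid], gtable, sid, trait, config, priors)
            colocs[sid] = gc
            result.gwas_colocs.append(gc)
        # module-level calls
        for m in validated_modules:
            member_colocs = [colocs[sid] for sid in m.members if sid in colocs]
            if call_module_gwas(member_colocs, config):
                loci.append(
                    select_locus_credible_set(
                        member_colocs, trait, m.module_id, "module", config
                    )
                )
        # singleton-level calls (signals outside validated modules)
        for sid, gc in colocs.items():
            if sid in module_of:
                continue
            ann = result.annotations.get(sid)
            if ann is not None and ann.mode not in (SINGLETON, COMBINATORIAL):
                continue
            if gc.accepted and gc.status == SHARED:
                loci.append(
                    select_locus_credible_set([gc], trait, sid, "singleton", config)
                )
    result.gwas_loci.extend(loci)
    return loci


# ---------------------------------------------------------------------------
# recovery scoring against the planted truth


def expected_category(truth: pd.DataFrame, gene: str) -> str | None:
    """The category the pipeline is expected to recover for a planted gene."""
    rows = truth[truth["gene"] == gene]
    cat = str(rows["category"].iloc[0])
    if cat == "null":
        return None
    if cat == "singleton-unique":
        active = rows[rows["causal_variant"].notna()]["tissue"]
        return ldannot.TISSUE_UNIQUE_CATEGORY[str(active.iloc[0])]
    return cat


def inferred_category(result: PipelineResult, gene: str) -> str | None:
    """The category the pipeline assigned to a gene, via its module if any,
    else via a singleton annotation."""
    gene_sids = [sid for sid, s in result.signals.items() if s.feature == gene]
    for sid in gene_sids:
        ann = result.annotations.get(sid)
        if ann and ann.module_id:
            cat = result.module_categories.get(ann.module_id, "")
            if cat and cat != AMBIGUOUS:
                return cat
    for sid in gene_sids:
        ann = result.annotations.get(sid)
        if ann and ann.mode == SINGLETON and ann.category:
            return ann.category
    return None


def score_category_recovery(
    study: StudyData, result: PipelineResult
) -> pd.DataFrame:
    """Per-gene planted vs inferred category, with a correctness flag."""
    rows = []
    for gene in study.truth["gene"].unique():
        expected = expected_category(study.truth, gene)
        inferred = inferred_category(result, gene)
        rows.append(
            {
                "gene": gene,
                "planted": str(study.truth[study.truth["gene"] == gene]["category"].iloc[0]),
                "expected": expected or "",
                "inferred": inferred or "",
                "is_null": expected is None,
                "correct": (expected == inferred) if expected else (inferred is None),
            }
        )
    return pd.DataFrame(rows)
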
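"""Synthetic multi-tissue eQTL study generator.

Generates block-LD genotype panels, kinship, per-tissue phenotypes with planted
causal variants realising every tissue-sharing category, and summary-statistic
tables (for colocalization-only and GWAS use) — so every downstream stage of the
pipeline can be tested against known ground truth.

Genotype model
--------------
Each gene owns a window of ``n_blocks`` LD blocks of ``variants_per_block``
variants. Per sample, each block draws two latent haplotype bits at the block's
allele frequency; every variant copies its block haplotype per haploid genome,
except with probability ``within_block_flip_prob`` the allele is re-drawn from
the block frequency. Dosages are coded 0 / 0.5 / 1 (heterozygote = 0.5). The
re-draw preserves the marginal MAF at any flip probability and gives a pairwise
within-block r² of ``(1 - flip_prob)^4``; across blocks variants are
independent.

Effect convention: ``effect_size`` multiplies the *standardized* causal dosage,
i.e. it is the association strength in phenotype-SD units per genotype SD, so
power is MAF-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .config import (
    CATEGORY_TISSUES,
    PLANTABLE_CATEGORIES,
    TISSUES,
    ConfigurationError,
    SimulationConfig,
)

# rng stream salts, so each generated artefact has its own independent stream
_SALT_PANEL = 11
_SALT_TRUTH = 17
_SALT_PHENO = 23
_SALT_SUMSTAT = 29

REGION_SPACING_BP = 10_000_000
GENE_BODY_BP = 10_000


class DegenerateInputError(ValueError):
    """Input carries no usable information (e.g. an all-monomorphic panel)."""


class ReferentialIntegrityError(KeyError):
    """A referenced identifier (causal variant, sample) does not exist."""


class CapacityError(ValueError):
    """The requested structure does not fit in the configured panel."""


@dataclass
class GenotypePanel:
    """A genotype dosage panel with block-LD structure.

    ``dosages`` is samples x variants with values in {0, 0.5, 1} (missing as
    NaN). ``variants`` has one row per variant: id, chrom, pos (1-based), ref,
    alt, gene, block. ``genes`` has one row per gene region: gene, chrom,
    body_start, body_end.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        self._index = pd.Index(self.variants["id"])
        if not self._index.is_unique:
            raise ConfigurationError("variant identifiers must be unique")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_pos(self, variant_id: str) -> tuple[str, int]:
        row = self.variants.iloc[self._index.get_loc(variant_id)]
        return str(row["chrom"]), int(row["pos"])

    def dosage_of(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self._index.get_loc(variant_id)]

    def has_variant(self, variant_id: str) -> bool:
        return variant_id in self._index

    def gene_variant_indices(self, gene: str) -> np.ndarray:
        return np.flatnonzero((self.variants["gene"] == gene).to_numpy())


@dataclass
class KinshipMatrix:
    """Symmetric sample-by-sample relatedness matrix (self ~ 1)."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.sample_ids),) * 2:
            raise ConfigurationError("kinship shape does not match sample count")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ConfigurationError("kinship matrix must be symmetric")


def gene_layout(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic genomic layout: one well-separated region per simulated gene.

    Genes are striped across the 22 autosomes with regions 10 Mb apart, so that
    colocalization candidate pairs arise only within a gene's own window.
    """
    n_genes = max(1, sum(config.category_counts.values()))
    rows = []
    span = 999_000
    m = max(config.variants_per_gene, 1)
    for idx in range(n_genes):
        chrom = str(1 + idx % 22)
        region_start = 1 + (idx // 22) * REGION_SPACING_BP
        center = region_start + span // 2
        rows.append(
            {
                "gene": f"gene{idx + 1:04d}",
                "chrom": chrom,
                "region_start": region_start,
                "body_start": center - GENE_BODY_BP // 2,
                "body_end": center + GENE_BODY_BP // 2,
                "step": max(span // max(m, 1), 1),
            }
        )
    return pd.DataFrame(rows)


def _block_frequencies(config: SimulationConfig, n_genes: int) -> np.ndarray:
    rng = np.random.default_rng([config.seed, 5])
    lo, hi = config.maf_range
    return rng.uniform(lo, hi, size=(n_genes, config.n_blocks))


def simulate_genotype_panel(
    config: SimulationConfig, panel_index: int = 0
) -> GenotypePanel:
    """Draw one genotype panel; ``panel_index`` selects an independent sample
    draw (tissue cohorts, LD reference) over the same variant map."""
    if config.variants_per_gene < 1:
        raise ConfigurationError("n_blocks x variants_per_block must be >= 1")
    if config.n_samples < 1:
        raise ConfigurationError("n_samples must be >= 1")
    layout = gene_layout(config)
    freqs = _block_frequencies(config, len(layout))
    rng = np.random.default_rng([config.seed, _SALT_PANEL, panel_index])

    n = config.n_samples
    v = config.variants_per_block
    flip = config.within_block_flip_prob
    var_rows: list[dict] = []
    dosage_cols: list[np.ndarray] = []
    for g_idx, gene_row in layout.iterrows():
        pos = int(gene_row["region_start"])
        step = int(gene_row["step"])
        for b in range(config.n_blocks):
            f = freqs[g_idx, b]
            latent = rng.random((n, 2)) < f  # two haploid block haplotypes
            for k in range(v):
                hap = latent.copy()
                redraw = rng.random((n, 2)) < flip
                if redraw.any():
                    hap[redraw] = rng.random(int(redraw.sum())) < f
                dosage_cols.append(hap.sum(axis=1) / 2.0)
                var_rows.append(
                    {
                        "id": f"{gene_row['gene']}_b{b:02d}_v{k:02d}",
                        "chrom": gene_row["chrom"],
                        "pos": pos,
                        "ref": "A",
                        "alt": "G",
                        "gene": gene_row["gene"],
                        "block": b,
                    }
                )
                pos += step

    dosages = np.column_stack(dosage_cols) if dosage_cols else np.empty((n, 0))

    if config.n_sibling_pairs:
        # sibling-pair injection: the second member of each pair re-draws its
        # genome with one haplotype copied from the first (half-sib-like).
        for k in range(config.n_sibling_pairs):
            a, b = 2 * k, 2 * k + 1
            share = rng.random(dosages.shape[1]) < 0.5
            shift = dosages[a, share] - dosages[b, share]
            dosages[b, share] += np.clip(shift, -0.5, 0.5)
            dosages[b] = np.clip(np.round(dosages[b] * 2) / 2, 0, 1)

    sample_ids = [f"s{panel_index}_{i:04d}" for i in range(n)]
    variants = pd.DataFrame(var_rows)
    genes = layout[["gene", "chrom", "body_start", "body_end"]].copy()
    return GenotypePanel(sample_ids, variants, dosages, genes)


def standardized_dosages(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centre each dosage column by its allele frequency and scale by the
    binomial dosage SD sqrt(f(1-f)/2); returns (X, polymorphic mask)."""
    f = np.nanmean(dosages, axis=0)
    sd = np.sqrt(np.maximum(f * (1 - f) / 2.0, 0.0))
    keep = sd > 0
    x = np.zeros_like(dosages)
    x[:, keep] = (dosages[:, keep] - f[keep]) / sd[keep]
    return np.nan_to_num(x), keep


def compute_kinship(panel: GenotypePanel, exclude_chrom: str | None = None) -> KinshipMatrix:
    """Standardized-dosage cross-product kinship (plink ``--make-rel``-style).

    The kinship is the averaged cross-product of standardized dosages over
    polymorphic variants, so self-kinship ~ 1. ``exclude_chrom`` drops one
    chromosome's variants (leave-one-chromosome-out, for scans where the
    tested variants must not contribute to the random-effect covariance).
    """
    mask = np.ones(panel.n_variants, dtype=bool)
    if exclude_chrom is not None:
        mask = (panel.variants["chrom"].astype(str) != str(exclude_chrom)).to_numpy()
    x, keep = standardized_dosages(panel.dosages[:, mask])
    if keep.sum() < 2:
        raise DegenerateInputError("kinship needs >= 2 polymorphic variants")
    x = x[:, keep]
    k = x @ x.T / keep.sum()
    k = (k + k.T) / 2.0
    return KinshipMatrix(k, list(panel.sample_ids))


def plant_sharing_structure(
    config: SimulationConfig, panel: GenotypePanel
) -> pd.DataFrame:
    """Plant causal variants realising each requested sharing category.

    Returns the truth table: one row per (gene, tissue) with columns gene,
    tissue, causal_variant (None where the tissue has no effect), effect,
    category, planted_overlap. Genes in a multi-tissue category share one
    identical causal variant across their active tissues.
    """
    for cat in config.category_counts:
        if cat not in PLANTABLE_CATEGORIES:
            raise ConfigurationError(f"unknown category {cat!r}")
    if config.n_blocks < 1 and any(
        n > 0 and c != "null" for c, n in config.category_counts.items()
    ):
        raise CapacityError("planting causal variants requires >= 1 block")
    rng = np.random.default_rng([config.seed, _SALT_TRUTH])
    genes = list(panel.genes["gene"])
    needed = sum(config.category_counts.values())
    if needed > len(genes):
        raise CapacityError(f"{needed} genes requested but panel has {len(genes)}")

    rows = []
    gene_iter = iter(genes)
    for category, count in config.category_counts.items():
        for _ in range(count):
            gene = next(gene_iter)
            if category == "null":
                active: frozenset[str] = frozenset()
            elif category == "singleton-unique":
                active = frozenset({TISSUES[rng.integers(len(TISSUES))]})
            else:
                active = CATEGORY_TISSUES[category]
            causal = None
            effect = 0.0
            if active:
                block = int(rng.integers(config.n_blocks))
                k = config.variants_per_block // 2
                causal = f"{gene}_b{block:02d}_v{k:02d}"
                if not panel.has_variant(causal):
                    raise CapacityError(f"panel lacks variant {causal}")
                effect = float(config.effect_size * rng.choice([-1.0, 1.0]))
            overlap = "same" if len(active) > 1 and "iPSC-PPC" in active else ""
            for tissue in TISSUES:
                on = tissue in active
                rows.append(
                    {
                        "gene": gene,
                        "tissue": tissue,
                        "causal_variant": causal if on else None,
                        "effect": effect if on else 0.0,
                        "category": category,
                        "planted_overlap": overlap if on else "",
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["gene", "tissue", "causal_variant", "effect", "category", "planted_overlap"],
    )


def _standardized_dosage(panel: GenotypePanel, variant_id: str) -> np.ndarray:
    d = panel.dosage_of(variant_id)
    sd = d.std()
    if sd == 0:
        raise DegenerateInputError(f"causal variant {variant_id} is monomorphic")
    return (d - d.mean()) / sd


def simulate_phenotypes(
    panel: GenotypePanel,
    truth: pd.DataFrame,
    kinship: KinshipMatrix,
    config: SimulationConfig,
    tissue: str,
) -> pd.DataFrame:
    """Simulate one tissue's phenotype matrix (samples x genes).

    y = sum(effect x standardized causal dosage) + polygenic background with
    covariance ``polygenic_sd^2 * K`` + iid N(0, noise_sd^2) noise. Multiple
    truth rows for one (gene, tissue) contribute additively, which is how
    multi-causal genes are planted.
    """
    if tissue not in TISSUES:
        raise ConfigurationError(f"unknown tissue {tissue!r}")
    rng = np.random.default_rng([config.seed, _SALT_PHENO, TISSUES.index(tissue)])
    n = panel.n_samples
    genes = list(panel.genes["gene"])
    y = rng.normal(0.0, config.noise_sd, size=(n, len(genes)))
    if config.polygenic_sd > 0:
        k = kinship.values + 1e-8 * np.eye(n)
        chol = np.linalg.cholesky(k)
        y += config.polygenic_sd * (chol @ rng.standard_normal((n, len(genes))))
    sub = truth[(truth["tissue"] == tissue) & truth["causal_variant"].notna()]
    col = {g: j for j, g in enumerate(genes)}
    for _, row in sub.iterrows():
        if row["gene"] not in col:
            raise ReferentialIntegrityError(f"gene {row['gene']} not in panel")
        if not panel.has_variant(row["causal_variant"]):
            raise ReferentialIntegrityError(
                f"causal variant {row['causal_variant']} not in panel"
            )
        y[:, col[row["gene"]]] += row["effect"] * _standardized_dosage(
            panel, row["causal_variant"]
        )
    return pd.DataFrame(y, index=panel.sample_ids, columns=genes)


def _ld_correlations(panel: GenotypePanel, idx: np.ndarray, causal_col: int) -> np.ndarray:
    d = panel.dosages[:, idx]
    c = panel.dosages[:, causal_col]
    dc = d - d.mean(axis=0)
    cc = c - c.mean()
    denom = np.sqrt((dc**2).sum(axis=0) * (cc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (dc.T @ cc) / denom
    return np.nan_to_num(r)


def simulate_summary_stats(
    panel: GenotypePanel,
    truth: pd.DataFrame,
    n: int,
    seed: int,
    tissue: str | None = None,
) -> dict[str, pd.DataFrame]:
    """Generate per-gene marginal association tables directly (RSS/LD model).

    The marginal standardized effect of each variant is its panel LD
    correlation with the causal variant times the true effect, plus noise with
    per-variant standard error 1/sqrt(n) correlated across variants by the
    panel LD matrix (the standard RSS approximation for marginal summary
    statistics); p-values are two-sided normal. Null genes produce uniform
    p-values. Suitable for colocalization-only tests and for GWAS traits
    (pass a truth table with a single active row).
    """
    if n < 2:
        raise ConfigurationError(f"sample size n must be >= 2, got {n}")
    rng = np.random.default_rng([seed, _SALT_SUMSTAT])
    from scipy import stats

    se = 1.0 / np.sqrt(n)
    sub = truth if tissue is None else truth[truth["tissue"] == tissue]
    out: dict[str, pd.DataFrame] = {}
    var_ids = pd.Index(panel.variants["id"])
    for gene, gene_rows in sub.groupby("gene", sort=False):
        idx = panel.gene_variant_indices(gene)
        if idx.size == 0:
            continue
        mean_beta = np.zeros(idx.size)
        for _, row in gene_rows.iterrows():
            if row["causal_variant"] is None or pd.isna(row["causal_variant"]):
                continue
            if not panel.has_variant(row["causal_variant"]):
                raise ReferentialIntegrityError(
                    f"causal variant {row['causal_variant']} not in panel"
                )
            causal_col = var_ids.get_loc(row["causal_variant"])
            mean_beta += row["effect"] * _ld_correlations(panel, idx, causal_col)
        d = panel.dosages[:, idx]
        sd = d.std(axis=0)
        poly = sd > 0
        corr = np.eye(idx.size)
        if poly.sum() > 1:
            sub_corr = np.corrcoef(d[:, poly], rowvar=False)
            corr[np.ix_(poly, poly)] = sub_corr
        chol = np.linalg.cholesky(corr + 1e-6 * np.eye(idx.size))
        beta = mean_beta + se * (chol @ rng.standard_normal(idx.size))
        z = beta / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        f = panel.dosages[:, idx].mean(axis=0)
        maf = np.minimum(f, 1 - f)
        vt = panel.variants.iloc[idx]
        out[gene] = pd.DataFrame(
            {
                "variant": vt["id"].to_numpy(),
                "chrom": vt["chrom"].to_numpy(),
                "pos": vt["pos"].to_numpy(),
                "ref": vt["ref"].to_numpy(),
                "alt": vt["alt"].to_numpy(),
                "beta": beta,
                "se": se,
                "p": p,
                "maf": maf,
                "n": n,
            }
        )
    return out


def simulate_gwas_stats(
    panel: GenotypePanel,
    gene: str,
    causal_variant: str | None,
    effect: float,
    n: int,
    seed: int,
) -> pd.DataFrame:
    """Summary statistics for a GWAS trait over one gene window (single causal
    variant shared with the eQTL, or a null trait when ``causal_variant`` is
    None)."""
    truth = pd.DataFrame(
        [
            {
                "gene": gene,
                "tissue": TISSUES[0],
                "causal_variant": causal_variant,
                "effect": effect if causal_variant else 0.0,
                "category": "null" if causal_variant is None else "gwas",
                "planted_overlap": "",
            }
        ]
    )
    return simulate_summary_stats(panel, truth, n=n, seed=seed)[gene]
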
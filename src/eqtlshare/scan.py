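"""Kinship-aware cis-eQTL scan with hierarchical multiple-testing correction.

The association model for feature *i* and variant *j* is the linear mixed model

    y_i = beta_ji * g_j + C b + u + eps,   cov(u) = sg^2 * K,  eps ~ iid N(0, se^2)

fitted EMMAX-style: the kinship K is eigendecomposed once per cohort, the
variance ratio delta = se^2/sg^2 is estimated on the covariate-only null model
per feature by maximum likelihood, and each variant is then scored by
generalized least squares in the rotated space. With K = I this reduces exactly
to OLS.

Multiple testing follows the two-step scheme: per feature, p-values are
corrected by the effective number of independent tests (M_eff from the
eigenvalues of the windowed variant correlation matrix); the per-feature lead
(minimum corrected p, ties by largest |beta| then smallest position) is then
corrected genome-wide by Benjamini-Hochberg, with significance at q <= 0.01.
Conditional signals are discovered stepwise by adding lead genotypes to the
covariates, up to five rounds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .config import GENE_EXPRESSION, PipelineConfig
from .synth import DegenerateInputError, GenotypePanel, KinshipMatrix


class RankError(ValueError):
    """Covariate matrix is rank-deficient after adding the intercept."""


@dataclass(frozen=True)
class EqtlSignal:
    """One significant association: tissue, feature, conditional rank, lead."""

    tissue: str
    feature: str
    feature_class: str
    rank: int
    lead_variant: str
    lead_beta: float
    p_gene_corrected: float
    q: float

    @property
    def signal_id(self) -> str:
        return f"{self.tissue}|{self.feature}|{self.rank}"


# ---------------------------------------------------------------------------
# variant-level filters


def hwe_exact_pvalue(n_het: int, n_hom_a: int, n_hom_b: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value (Wigginton-style).

    Sums the probabilities of all heterozygote counts (given the observed
    allele counts) that are no more probable than the observed configuration.
    """
    if min(n_het, n_hom_a, n_hom_b) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_het + n_hom_a + n_hom_b
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom_a, n_hom_b) + n_het
    # log-probability of each feasible heterozygote count
    from scipy.special import gammaln

    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_r = (n_rare - hets) // 2
    hom_c = n - hets - hom_r
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(hom_r + 1)
        - gammaln(hom_c + 1)
        + hets * math.log(2.0)
        - gammaln(2 * n + 1)
        + gammaln(n_rare + 1)
        + gammaln(2 * n - n_rare + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[hets == n_het]
    if obs.size == 0:
        raise ValueError("observed heterozygote count infeasible for allele counts")
    return float(min(1.0, probs[probs <= obs[0] * (1 + 1e-12)].sum()))


def variant_qc(dosages: np.ndarray) -> pd.DataFrame:
    """Per-variant MAF, HWE exact p and call rate from a dosage matrix."""
    n_total = dosages.shape[0]
    called = ~np.isnan(dosages)
    call_rate = called.mean(axis=0)
    rows = []
    for j in range(dosages.shape[1]):
        d = dosages[called[:, j], j]
        n_het = int((d == 0.5).sum())
        n_alt = int((d == 1.0).sum())
        n_ref = int((d == 0.0).sum())
        f = d.mean() if d.size else np.nan
        maf = min(f, 1 - f) if d.size else np.nan
        rows.append(
            {
                "maf": maf,
                "hwe_p": hwe_exact_pvalue(n_het, n_alt, n_ref),
                "call_rate": call_rate[j] if n_total else 0.0,
            }
        )
    return pd.DataFrame(rows)


def filter_variants(
    panel: GenotypePanel,
    gene_window: tuple[str, int, int],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Variants passing MAF, HWE, call-rate and cis-window filters.

    ``gene_window`` is (chrom, body_start, body_end), 1-based closed; the scan
    window extends ``cis_window_bp`` beyond the gene body on both sides.
    Returns the surviving rows of ``panel.variants`` (original index retained).
    An empty result is returned, not raised.
    """
    config = config or PipelineConfig()
    chrom, start, end = gene_window
    v = panel.variants
    in_window = (
        (v["chrom"].astype(str) == str(chrom))
        & (v["pos"] >= start - config.cis_window_bp)
        & (v["pos"] <= end + config.cis_window_bp)
    ).to_numpy()
    idx = np.flatnonzero(in_window)
    if idx.size == 0:
        return v.iloc[idx]
    qc = variant_qc(panel.dosages[:, idx])
    keep = (
        (qc["maf"] > config.maf_min)
        & (qc["hwe_p"] > config.hwe_p_min)
        & (qc["call_rate"] > config.call_rate_min)
    ).to_numpy()
    return v.iloc[idx[keep]]


# ---------------------------------------------------------------------------
# expressed-feature selection and normalization


def select_expressed_features(
    tpm: pd.DataFrame,
    isoform_tpm: pd.DataFrame | None = None,
    isoform_usage: pd.DataFrame | None = None,
    isoform_gene: pd.Series | None = None,
    config: PipelineConfig | None = None,
) -> tuple[list[str], list[str]]:
    """Expressed genes and isoforms.

    Genes (rows of ``tpm``, columns = samples) pass with TPM >= 1 in at least
    10% of samples. Isoforms additionally need usage >= 10% in at least 10% of
    samples and must belong to an expressed gene with >= 2 expressed isoforms.
    """
    config = config or PipelineConfig()
    frac = config.expressed_fraction
    genes = tpm.index[(tpm >= config.tpm_min).mean(axis=1) >= frac].tolist()
    if isoform_tpm is None:
        return genes, []
    if isoform_usage is None or isoform_gene is None:
        raise ValueError("isoform selection needs usage matrix and isoform->gene map")
    if not isoform_tpm.columns.equals(isoform_usage.columns):
        raise ValueError("isoform TPM and usage matrices have mismatched samples")
    ok = ((isoform_tpm >= config.tpm_min) & (isoform_usage >= config.usage_min)).mean(
        axis=1
    ) >= frac
    cand = isoform_tpm.index[ok]
    gene_of = isoform_gene.loc[cand]
    counts = gene_of.value_counts()
    expressed_genes = set(genes)
    isoforms = [
        iso
        for iso in cand
        if gene_of[iso] in expressed_genes and counts[gene_of[iso]] >= 2
    ]
    return genes, isoforms


def quantile_normalize(values: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Rank-based inverse-normal transform per feature (columns), ties averaged,
    re-standardized to mean 0 / sd 1 exactly. Constant features map to zeros
    with a warning."""
    arr = np.asarray(values, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[:, None]
    out = np.empty_like(arr)
    n = arr.shape[0]
    for j in range(arr.shape[1]):
        col = arr[:, j]
        if np.nanstd(col) == 0:
            warnings.warn(f"constant feature at column {j}: normalized to zeros")
            out[:, j] = 0.0
            continue
        ranks = stats.rankdata(col, method="average")
        q = stats.norm.ppf(ranks / (n + 1))
        q = (q - q.mean()) / q.std()
        out[:, j] = q
    return out[:, 0] if squeeze else out


# ---------------------------------------------------------------------------
# the mixed-model scan


@dataclass
class KinshipSpectral:
    """Eigendecomposition of a kinship matrix, computed once per cohort."""

    eigenvalues: np.ndarray
    rotation: np.ndarray  # U^T, applied to y, G and C

    @classmethod
    def from_kinship(cls, kinship: KinshipMatrix, jitter: float = 1e-8) -> "KinshipSpectral":
        k = kinship.values
        s, u = np.linalg.eigh(k)
        if s.min() < -1e-6:
            s, u = np.linalg.eigh(k + jitter * np.eye(k.shape[0]))
            if s.min() < -1e-6:
                raise DegenerateInputError("kinship matrix is not PSD even after jitter")
        return cls(np.maximum(s, 0.0), u.T)


def _null_delta_ml(yr: np.ndarray, cr: np.ndarray, s: np.ndarray) -> float:
    """ML estimate of delta = sigma_e^2 / sigma_g^2 on the covariate-only model,
    in the rotated space (variances sigma_g^2 (s_i + delta))."""
    n = yr.shape[0]

    def neg_ll(log_delta: float) -> float:
        delta = math.exp(log_delta)
        w = 1.0 / (s + delta)
        cw = cr * w[:, None]
        xtx = cr.T @ cw
        beta = np.linalg.solve(xtx, cw.T @ yr)
        resid = yr - cr @ beta
        rss = float((resid * resid * w).sum())
        sg2 = rss / n
        return 0.5 * (n * math.log(sg2) + np.log(s + delta).sum())

    res = optimize.minimize_scalar(neg_ll, bounds=(-10.0, 10.0), method="bounded")
    return math.exp(res.x)


def lmm_scan(
    y: np.ndarray,
    genotypes: np.ndarray,
    variant_ids: pd.DataFrame,
    covariates: np.ndarray | None,
    spectral: KinshipSpectral | None,
) -> pd.DataFrame:
    """Score every variant against one phenotype under the mixed model.

    ``genotypes`` is samples x variants (dosage units); ``variant_ids`` the
    matching rows of the panel's variant table. ``spectral`` = None means
    identity kinship (plain OLS). Returns an association table with columns
    variant, chrom, pos, ref, alt, beta, se, p, maf, n.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    c = np.column_stack([np.ones(n)] + ([covariates] if covariates is not None else []))
    if np.linalg.matrix_rank(c) < c.shape[1]:
        raise RankError("covariate matrix singular after adding intercept")
    g = np.asarray(genotypes, dtype=float)

    if spectral is not None:
        yr = spectral.rotation @ y
        cr = spectral.rotation @ c
        gr = spectral.rotation @ g
        delta = _null_delta_ml(yr, cr, spectral.eigenvalues)
        w = 1.0 / (spectral.eigenvalues + delta)
    else:
        yr, cr, gr = y, c, g
        w = np.ones(n)

    # weighted residualization of y and every genotype column on the covariates
    cw = cr * w[:, None]
    xtx_inv = np.linalg.inv(cr.T @ cw)
    y_res = yr - cr @ (xtx_inv @ (cw.T @ yr))
    g_res = gr - cr @ (xtx_inv @ (cw.T @ gr))

    gty = g_res.T @ (w * y_res)
    gtg = (g_res * g_res * w[:, None]).sum(axis=0)
    yty = float((y_res * y_res * w).sum())
    dof = n - c.shape[1] - 1
    if dof <= 0:
        raise DegenerateInputError("not enough samples for the covariate set")
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = gty / gtg
        rss = np.maximum(yty - beta * gty, 0.0)
        sigma2 = rss / dof
        se = np.sqrt(sigma2 / gtg)
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    # monomorphic columns give gtg = 0 -> undefined; report p = 1
    bad = ~np.isfinite(beta)
    beta[bad], se[bad], p[bad] = 0.0, np.inf, 1.0

    f = np.nanmean(g, axis=0)
    out = variant_ids[["id", "chrom", "pos", "ref", "alt"]].copy().reset_index(drop=True)
    out = out.rename(columns={"id": "variant"})
    out["beta"] = beta
    out["se"] = se
    out["p"] = p
    out["maf"] = np.minimum(f, 1 - f)
    out["n"] = n
    return out


# ---------------------------------------------------------------------------
# two-step multiple-testing correction


def effective_tests(
    genotypes: np.ndarray, window: int = 200, var_explained: float = 0.99
) -> float:
    """eigenMT-style effective number of independent tests.

    Variants are split (in map order) into fixed-size windows; per window the
    eigenvalues of the variant correlation matrix give the smallest k whose top
    eigenvalues explain >= ``var_explained`` of the trace; M_eff sums over
    windows.
    """
    m = genotypes.shape[1]
    if m < 1:
        raise DegenerateInputError("M_eff needs at least one variant")
    total = 0.0
    for lo in range(0, m, window):
        block = genotypes[:, lo : lo + window]
        sd = block.std(axis=0)
        poly = sd > 0
        k_mono = int((~poly).sum())  # monomorphic variants count as one test each
        block = block[:, poly]
        if block.shape[1] == 0:
            total += k_mono
            continue
        corr = np.corrcoef(block, rowvar=False)
        corr = np.atleast_2d(corr)
        eig = np.sort(np.linalg.eigvalsh(corr))[::-1]
        cum = np.cumsum(eig) / eig.sum()
        k = int(np.searchsorted(cum, var_explained - 1e-12) + 1)
        total += min(k, block.shape[1]) + k_mono
    return min(total, m)


def gene_level_correction(
    records: pd.DataFrame,
    genotypes: np.ndarray,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Bonferroni-style gene-level correction by M_eff: p_corr = min(1, p * M_eff)."""
    config = config or PipelineConfig()
    m_eff = effective_tests(
        genotypes, window=config.eigenmt_window, var_explained=config.eigenmt_var_explained
    )
    out = records.copy()
    out["p_gene_corrected"] = np.minimum(1.0, out["p"] * m_eff)
    out.attrs["m_eff"] = m_eff
    return out


def select_lead(records: pd.DataFrame) -> pd.Series:
    """Lead variant: minimum corrected p; ties by largest |beta|, then smallest
    position (the residual positional rule makes the choice deterministic)."""
    if records.empty:
        raise DegenerateInputError("no records to select a lead from")
    df = records
    best_p = df["p_gene_corrected"].min()
    tied = df[df["p_gene_corrected"] == best_p]
    best_b = tied["beta"].abs().max()
    tied = tied[tied["beta"].abs() == best_b]
    return tied.loc[tied["pos"].idxmin()]


def genomewide_fdr(lead_p: pd.Series, q_cut: float = 0.01) -> pd.DataFrame:
    """Benjamini-Hochberg across feature leads; flags q <= ``q_cut``."""
    if len(lead_p) == 0:
        return pd.DataFrame(columns=["p", "q", "significant"])
    rej, q, _, _ = multipletests(lead_p.to_numpy(), alpha=q_cut, method="fdr_bh")
    sig = q <= q_cut
    return pd.DataFrame({"p": lead_p, "q": q, "significant": sig}, index=lead_p.index)


# ---------------------------------------------------------------------------
# stepwise conditional discovery for one feature


@dataclass
class FeatureScanResult:
    """Signals for one feature plus the per-rank full association tables."""

    signals: list[EqtlSignal]
    tables: dict[int, pd.DataFrame]  # rank -> association table (marginal for 0)


def conditional_scan(
    y: np.ndarray,
    genotypes: np.ndarray,
    variant_ids: pd.DataFrame,
    covariates: np.ndarray | None,
    spectral: KinshipSpectral | None,
    tissue: str,
    feature: str,
    feature_class: str = GENE_EXPRESSION,
    config: PipelineConfig | None = None,
) -> FeatureScanResult:
    """Primary + stepwise conditional scan for a single feature.

    Round r adds the genotypes of all previous leads as covariates and re-runs
    the scan and gene-level correction; it stops when the new lead's corrected
    p exceeds the significance cut (per-feature gating, equivalent to BH with
    m = 1) or after ``max_conditional`` extra rounds. Leads collinear with
    prior leads are dropped with a warning.
    """
    config = config or PipelineConfig()
    var_index = pd.Index(variant_ids["id"].to_numpy())
    signals: list[EqtlSignal] = []
    tables: dict[int, pd.DataFrame] = {}
    lead_cols: list[np.ndarray] = []
    for rank in range(config.max_conditional + 1):
        cov = covariates
        if lead_cols:
            extra = np.column_stack(lead_cols)
            cov = extra if cov is None else np.column_stack([cov, extra])
        try:
            table = lmm_scan(y, genotypes, variant_ids, cov, spectral)
        except RankError:
            warnings.warn(f"{feature}: lead collinear with covariates at rank {rank}; stopping")
            break
        table = gene_level_correction(table, genotypes, config)
        tables[rank] = table
        lead = select_lead(table)
        signals.append(
            EqtlSignal(
                tissue=tissue,
                feature=feature,
                feature_class=feature_class,
                rank=rank,
                lead_variant=str(lead["variant"]),
                lead_beta=float(lead["beta"]),
                p_gene_corrected=float(lead["p_gene_corrected"]),
                q=float(lead["p_gene_corrected"]),
            )
        )
        if lead["p_gene_corrected"] > config.q_cut:
            # this round's lead is not significant: drop it and stop
            signals.pop()
            tables.pop(rank)
            break
        lead_dosage = genotypes[:, var_index.get_loc(str(lead["variant"]))]
        lead_cols.append(lead_dosage)
    return FeatureScanResult(signals=signals, tables=tables)
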
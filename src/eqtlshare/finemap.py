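"""Single-causal-variant Bayesian fine-mapping from summary statistics.

Each variant's association (p, MAF, N) is converted to a Wakefield approximate
Bayes factor against the null; under the assumption of (at most) one causal
variant per signal, normalizing the Bayes factors gives each variant's
posterior probability of being causal, from which 99% credible sets and
candidate-variant lists are derived. Candidate causal variants can be tested
for enrichment in genomic annotations against a background set with Fisher's
exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .config import AbfPriors, ConfigurationError


@dataclass
class FineMapResult:
    """Per-variant log-ABFs and causal posteriors, with the credible set."""

    table: pd.DataFrame  # variant, pos, labf, pp (pp sums to 1)
    credible_set: list[str]
    credible_level: float

    def pp_of(self, variant: str) -> float:
        row = self.table[self.table["variant"] == variant]
        return float(row["pp"].iloc[0]) if len(row) else 0.0


def z_from_p(p: np.ndarray, beta: np.ndarray | None = None) -> np.ndarray:
    """Two-sided |z| from p, signed by beta when available."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        n_bad = int(((p <= 0) | (p > 1)).sum())
        warnings.warn(f"{n_bad} p-values outside (0, 1]: clamping")
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    z = stats.norm.isf(p / 2.0)
    if beta is not None:
        z = z * np.where(np.asarray(beta) < 0, -1.0, 1.0)
    return z


def wakefield_labf(
    p: np.ndarray,
    maf: np.ndarray,
    n: np.ndarray | int,
    priors: AbfPriors | None = None,
    beta: np.ndarray | None = None,
) -> np.ndarray:
    """Log approximate Bayes factor for association at each variant.

    For a unit-variance quantitative trait the sampling variance of the
    standardized effect is V = 1 / (2 N f (1-f)); with prior effect variance
    W = w_sd^2,

        log ABF = 0.5 * [ log(V / (V + W)) + z^2 * W / (V + W) ].

    Computed entirely in log space; safe for |z| up to several tens.
    """
    priors = priors or AbfPriors()
    maf = np.asarray(maf, dtype=float)
    n = np.broadcast_to(np.asarray(n, dtype=float), maf.shape)
    if np.any((maf <= 0) | (maf > 0.5)):
        raise ConfigurationError("maf must lie in (0, 0.5]")
    if np.any(n < 2):
        raise ConfigurationError("sample size must be >= 2")
    z = z_from_p(p, beta)
    v = 1.0 / (2.0 * n * maf * (1.0 - maf))
    w = priors.w_sd**2
    r = w / (v + w)
    return 0.5 * (np.log1p(-r) + z * z * r)


def finemap_posteriors(
    table: pd.DataFrame,
    priors: AbfPriors | None = None,
    credible_level: float = 0.99,
) -> FineMapResult:
    """Fine-map one signal from its association table.

    ``table`` needs columns variant, pos, p, maf, n (beta optional, used only
    for the sign of z). Posterior: pp_i = exp(labf_i - logsumexp(labf)).
    """
    labf = wakefield_labf(
        table["p"].to_numpy(),
        table["maf"].to_numpy(),
        table["n"].to_numpy(),
        priors,
        table["beta"].to_numpy() if "beta" in table else None,
    )
    pp = np.exp(labf - logsumexp(labf))
    out = table[["variant", "pos"]].copy().reset_index(drop=True)
    out["labf"] = labf
    out["pp"] = pp
    cs = credible_set(out, credible_level)
    return FineMapResult(table=out, credible_set=cs, credible_level=credible_level)


def credible_set(table: pd.DataFrame, level: float = 0.99) -> list[str]:
    """Smallest pp-descending prefix with cumulative pp >= ``level``.

    Ties in pp are ordered by ascending position so the set is deterministic.
    """
    df = table.sort_values(["pp", "pos"], ascending=[False, True], kind="mergesort")
    cum = df["pp"].cumsum()
    k = int(np.searchsorted(cum.to_numpy(), level - 1e-12) + 1)
    k = min(k, len(df))
    return df["variant"].iloc[:k].tolist()


def candidate_causal_variants(result: FineMapResult, pp_threshold: float = 0.01) -> list[str]:
    """Variants with causal posterior >= ``pp_threshold`` (pp-descending)."""
    df = result.table[result.table["pp"] >= pp_threshold]
    df = df.sort_values(["pp", "pos"], ascending=[False, True], kind="mergesort")
    return df["variant"].tolist()


# ---------------------------------------------------------------------------
# annotation enrichment


def _interval_tree(annotations: pd.DataFrame):
    from intervaltree import IntervalTree

    trees: dict[str, "IntervalTree"] = {}
    for chrom, sub in annotations.groupby("chrom"):
        tree = IntervalTree()
        for _, row in sub.iterrows():
            if row["end"] > row["start"]:
                tree.addi(int(row["start"]), int(row["end"]))
        trees[str(chrom)] = tree
    return trees


def _in_annotation(variants: pd.DataFrame, trees) -> np.ndarray:
    hits = np.zeros(len(variants), dtype=bool)
    for i, (_, row) in enumerate(variants.iterrows()):
        tree = trees.get(str(row["chrom"]))
        if tree is not None:
            # variant position is 1-based; internal intervals 0-based half-open
            hits[i] = bool(tree.overlaps(int(row["pos"]) - 1))
    return hits


def annotation_enrichment(
    candidates: pd.DataFrame,
    annotations: dict[str, pd.DataFrame],
    background: pd.DataFrame,
    exclude_candidates_from_background: bool = True,
) -> pd.DataFrame:
    """Fisher-exact enrichment of candidate variants in each annotation.

    ``candidates`` / ``background`` carry columns (variant, chrom, pos)
    [1-based]; each annotation is a (chrom, start, end) interval table, 0-based
    half-open. Returns per-annotation odds ratio, p and BH-adjusted p;
    annotations with an empty contingency cell report OR = NaN, flagged.
    """
    if background.empty:
        raise ConfigurationError("enrichment background must be non-empty")
    bg = background
    if exclude_candidates_from_background:
        bg = bg[~bg["variant"].isin(set(candidates["variant"]))]
        if bg.empty:
            raise ConfigurationError("background empty after excluding candidates")
    rows = []
    for name, ann in annotations.items():
        trees = _interval_tree(ann)
        cand_in = int(_in_annotation(candidates, trees).sum())
        cand_out = len(candidates) - cand_in
        bg_in = int(_in_annotation(bg, trees).sum())
        bg_out = len(bg) - bg_in
        table = [[cand_in, cand_out], [bg_in, bg_out]]
        odds, p = stats.fisher_exact(table)
        zero_cell = min(cand_in, cand_out, bg_in, bg_out) == 0
        rows.append(
            {
                "annotation": name,
                "candidates_in": cand_in,
                "candidates_out": cand_out,
                "background_in": bg_in,
                "background_out": bg_out,
                "odds_ratio": np.nan if not np.isfinite(odds) else odds,
                "p": p,
                "zero_cell": zero_cell,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
        out["significant"] = out["p_adjusted"] < 0.05
    return out
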
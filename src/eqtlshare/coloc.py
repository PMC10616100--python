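"""Five-hypothesis Bayesian colocalization between two summary-statistic signals.

For two association signals over a shared variant set, each variant gets a
per-trait Wakefield log-ABF; assuming at most one causal variant per trait, the
posterior mass of the five hypotheses is

    H0: neither trait associated            L0 = 0
    H1: trait 1 only                        L1 = log(p1)  + S1
    H2: trait 2 only                        L2 = log(p2)  + S2
    H3: both, distinct causal variants      L3 = log(p1) + log(p2) + log(e^{S1+S2} - e^{S4})
    H4: both, the same causal variant       L4 = log(p12) + S4

with S1 = logsumexp(labf1), S2 = logsumexp(labf2), S4 = logsumexp(labf1+labf2),
all arithmetic in log space. Pairs sharing fewer than 500 variants are flagged
``insufficient_overlap`` and skipped; otherwise a pair is classified shared
(PP.H4 >= 0.8), distinct (PP.H3 >= 0.8), or underpowered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .config import AbfPriors, ColocPriors, PipelineConfig
from .finemap import wakefield_labf

SHARED = "shared"
DISTINCT = "distinct"
UNDERPOWERED = "underpowered"
INSUFFICIENT_OVERLAP = "insufficient_overlap"


class InputIntegrityError(ValueError):
    """Malformed input table (e.g. duplicated variant keys)."""


@dataclass
class ColocResult:
    """Posterior probabilities of the five hypotheses for one signal pair."""

    pp_h0: float
    pp_h1: float
    pp_h2: float
    pp_h3: float
    pp_h4: float
    nsnps: int
    classification: str
    #: per-variant log joint ABF (labf1 + labf2), indexed like ``variants``;
    #: normalized it is the posterior over the shared causal variant under H4.
    joint_labf: np.ndarray | None = None
    variants: pd.DataFrame | None = None  # variant, chrom, pos of the overlap

    @property
    def pps(self) -> np.ndarray:
        return np.array([self.pp_h0, self.pp_h1, self.pp_h2, self.pp_h3, self.pp_h4])

    def shared_variant_posteriors(self) -> pd.DataFrame:
        """Posterior over which variant is the shared causal one (given H4)."""
        if self.joint_labf is None or self.variants is None:
            raise ValueError("no per-variant data retained for this result")
        pp = np.exp(self.joint_labf - logsumexp(self.joint_labf))
        out = self.variants.copy()
        out["pp"] = pp
        return out


def harmonize_signals(a: pd.DataFrame, b: pd.DataFrame, nsnps_min: int = 500) -> tuple[pd.DataFrame, int, bool]:
    """Inner-join two association tables on strict variant identity.

    Variant identity is (chrom, pos, ref, alt); no strand flipping or allele
    swapping is attempted. Returns (paired table, overlap count, eligible).
    """
    key = ["chrom", "pos", "ref", "alt"]
    for name, t in (("first", a), ("second", b)):
        if t.duplicated(subset=key).any():
            raise InputIntegrityError(f"duplicate variant keys in {name} table")
    merged = a.merge(b, on=key, suffixes=("_1", "_2"))
    nsnps = len(merged)
    return merged, nsnps, nsnps >= nsnps_min


def _logdiffexp(big: float, small: float) -> float:
    """log(exp(big) - exp(small)), stable; -inf when the difference vanishes."""
    if small >= big:
        return -np.inf
    return big + np.log1p(-np.exp(small - big))


def coloc_labfs(
    labf1: np.ndarray, labf2: np.ndarray, priors: ColocPriors | None = None
) -> np.ndarray:
    """Log posterior weights (unnormalized) of the five hypotheses."""
    priors = priors or ColocPriors()
    s1 = logsumexp(labf1)
    s2 = logsumexp(labf2)
    s4 = logsumexp(labf1 + labf2)
    l0 = 0.0
    l1 = np.log(priors.p1) + s1
    l2 = np.log(priors.p2) + s2
    l3_body = _logdiffexp(s1 + s2, s4)
    if not np.isfinite(l3_body):
        warnings.warn("H3 sum vanished (single shared variant); PP.H3 set to 0")
    l3 = np.log(priors.p1) + np.log(priors.p2) + l3_body
    l4 = np.log(priors.p12) + s4
    return np.array([l0, l1, l2, l3, l4])


def coloc_abf(
    paired: pd.DataFrame,
    priors: ColocPriors | None = None,
    abf_priors_1: AbfPriors | None = None,
    abf_priors_2: AbfPriors | None = None,
    nsnps_min: int = 500,
    eligible: bool | None = None,
) -> ColocResult:
    """Five-hypothesis colocalization on a harmonized pair table.

    ``paired`` is the output of :func:`harmonize_signals`: per-variant columns
    ``p_1, maf_1, n_1`` and ``p_2, maf_2, n_2`` (betas optional).
    """
    nsnps = len(paired)
    if eligible is None:
        eligible = nsnps >= nsnps_min
    if not eligible:
        return ColocResult(np.nan, np.nan, np.nan, np.nan, np.nan, nsnps, INSUFFICIENT_OVERLAP)
    labf1 = wakefield_labf(
        paired["p_1"].to_numpy(), paired["maf_1"].to_numpy(), paired["n_1"].to_numpy(),
        abf_priors_1, paired["beta_1"].to_numpy() if "beta_1" in paired else None,
    )
    labf2 = wakefield_labf(
        paired["p_2"].to_numpy(), paired["maf_2"].to_numpy(), paired["n_2"].to_numpy(),
        abf_priors_2, paired["beta_2"].to_numpy() if "beta_2" in paired else None,
    )
    logw = coloc_labfs(labf1, labf2, priors)
    pp = np.exp(logw - logsumexp(logw))
    keep_cols = [c for c in ("variant", "chrom", "pos") if c in paired.columns]
    if "variant" not in paired.columns and "variant_1" in paired.columns:
        variants = paired[["variant_1", "chrom", "pos"]].rename(columns={"variant_1": "variant"})
    else:
        variants = paired[keep_cols] if keep_cols else None
    result = ColocResult(
        pp_h0=float(pp[0]), pp_h1=float(pp[1]), pp_h2=float(pp[2]),
        pp_h3=float(pp[3]), pp_h4=float(pp[4]),
        nsnps=nsnps, classification="",
        joint_labf=labf1 + labf2,
        variants=variants.reset_index(drop=True) if variants is not None else None,
    )
    result.classification = classify_coloc(result)
    return result


def classify_coloc(
    result: ColocResult, pp_h4_cut: float = 0.8, pp_h3_cut: float = 0.8
) -> str:
    """Shared if PP.H4 >= 0.8; distinct if PP.H3 >= 0.8; else underpowered."""
    if result.classification == INSUFFICIENT_OVERLAP:
        return INSUFFICIENT_OVERLAP
    if result.pp_h4 >= pp_h4_cut:
        return SHARED
    if result.pp_h3 >= pp_h3_cut:
        return DISTINCT
    return UNDERPOWERED


def coloc_pair(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    config: PipelineConfig | None = None,
    abf_priors_a: AbfPriors | None = None,
    abf_priors_b: AbfPriors | None = None,
) -> ColocResult:
    """Harmonize two association tables and colocalize them in one call."""
    config = config or PipelineConfig()
    paired, nsnps, eligible = harmonize_signals(table_a, table_b, config.nsnps_min)
    if not eligible:
        return ColocResult(np.nan, np.nan, np.nan, np.nan, np.nan, nsnps, INSUFFICIENT_OVERLAP)
    result = coloc_abf(
        paired, config.coloc_priors, abf_priors_a or config.abf_priors,
        abf_priors_b or config.abf_priors, config.nsnps_min, eligible=True,
    )
    result.classification = classify_coloc(result, config.pp_h4_cut, config.pp_h3_cut)
    return result
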
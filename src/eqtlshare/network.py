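"""Colocalization-network modules.

All pairwise shared (PP.H4 >= 0.8, nsnps >= 500) colocalizations within one
chromosome and one phenotype class form an undirected graph; Leiden community
detection with a modularity objective (resolution 0.3, 500 iterations) yields
candidate modules, which are then validated against the full pairwise side
table: at least 30% of all C(k, 2) member pairs must be shared (H4), and the
number of H4 pairs must be at least twice the number of distinct (H3) pairs.
Validated modules get ids "<GE|AS>_<chrom>_<int>" (GE = gene expression,
AS = alternative splicing), numbered by ascending minimum member position.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import igraph as ig
import leidenalg as la
import pandas as pd

from .config import GENE_EXPRESSION, PipelineConfig
from .coloc import DISTINCT, SHARED

VALIDATED = "validated"
MODULE_FAILED = "module_failed"


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class ColocGraph:
    """H4-edge graph for one (chromosome, phenotype class) stratum, plus the
    side table of every tested pair's classification."""

    chrom: str
    feature_class: str
    nodes: list[str]
    edges: list[tuple[str, str]]
    side_table: dict[tuple[str, str], str]  # pair -> shared|distinct|underpowered

    def classification_of(self, a: str, b: str) -> str | None:
        return self.side_table.get(_pair_key(a, b))


@dataclass
class Module:
    """A community of colocalized signals with its validation bookkeeping."""

    members: list[str]
    chrom: str
    feature_class: str
    n_h4: int = 0
    n_h3: int = 0
    n_pairs: int = 0
    status: str = ""
    module_id: str = ""


def build_coloc_graph(
    pairs: pd.DataFrame,
    chrom: str,
    feature_class: str = GENE_EXPRESSION,
    config: PipelineConfig | None = None,
) -> ColocGraph:
    """Graph for one stratum from a table of tested pairs.

    ``pairs`` columns: signal_a, signal_b, chrom, feature_class, pp_h4, nsnps,
    classification. Nodes are all signals appearing in any eligible
    (nsnps >= 500) pair; edges are the shared pairs passing both thresholds.
    """
    config = config or PipelineConfig()
    sub = pairs[
        (pairs["chrom"].astype(str) == str(chrom))
        & (pairs["feature_class"] == feature_class)
        & (pairs["nsnps"] >= config.nsnps_min)
    ]
    nodes: set[str] = set()
    edges: list[tuple[str, str]] = []
    side: dict[tuple[str, str], str] = {}
    for _, row in sub.iterrows():
        a, b = str(row["signal_a"]), str(row["signal_b"])
        nodes.update((a, b))
        side[_pair_key(a, b)] = str(row["classification"])
        if row["classification"] == SHARED and row["pp_h4"] >= config.pp_h4_cut:
            edges.append(_pair_key(a, b))
    return ColocGraph(str(chrom), feature_class, sorted(nodes), sorted(set(edges)), side)


def detect_communities(
    graph: ColocGraph,
    resolution: float = 0.3,
    iterations: int = 500,
    seed: int = 1,
) -> list[Module]:
    """Leiden modularity communities; singletons are not modules.

    Deterministic given ``seed``. Returns candidate (unvalidated) modules.
    """
    if not graph.nodes:
        return []
    g = ig.Graph()
    g.add_vertices(graph.nodes)
    if graph.edges:
        g.add_edges(graph.edges)
    partition = la.find_partition(
        g,
        la.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        n_iterations=iterations,
        seed=seed,
    )
    modules = []
    for community in partition:
        members = sorted(g.vs[i]["name"] for i in community)
        if len(members) >= 2:
            modules.append(Module(members, graph.chrom, graph.feature_class))
    return modules


def validate_module(
    module: Module, graph: ColocGraph, config: PipelineConfig | None = None
) -> Module:
    """Apply the 30% H4-fraction and H4 >= 2 x H3 rules over all C(k,2) pairs.

    With ``count_all_pairs`` (default) the denominator counts every unordered
    member pair, tested or not; underpowered/untested pairs count toward
    neither H4 nor H3. The config switch restricts the denominator to tested
    pairs.
    """
    config = config or PipelineConfig()
    k = len(module.members)
    n_h4 = n_h3 = n_tested = 0
    for a, b in combinations(module.members, 2):
        cls = graph.classification_of(a, b)
        if cls is not None:
            n_tested += 1
        if cls == SHARED:
            n_h4 += 1
        elif cls == DISTINCT:
            n_h3 += 1
    n_pairs = k * (k - 1) // 2 if config.count_all_pairs else n_tested
    ok = (
        n_pairs > 0
        and (n_h4 / n_pairs) >= config.module_h4_fraction
        and n_h4 >= config.h4_h3_ratio * n_h3
    )
    module.n_h4, module.n_h3, module.n_pairs = n_h4, n_h3, n_pairs
    module.status = VALIDATED if ok else MODULE_FAILED
    return module


def assign_module_ids(
    modules: list[Module], signal_positions: dict[str, int]
) -> list[Module]:
    """Assign "<GE|AS>_<chrom>_<int>" ids to validated modules, numbering by
    ascending minimum member position (per chromosome and class)."""
    validated = [m for m in modules if m.status == VALIDATED]
    by_stratum: dict[tuple[str, str], list[Module]] = {}
    for m in validated:
        by_stratum.setdefault((m.feature_class, m.chrom), []).append(m)
    for (fclass, chrom), group in by_stratum.items():
        prefix = "GE" if fclass == GENE_EXPRESSION else "AS"
        group.sort(key=lambda m: min(signal_positions.get(s, 0) for s in m.members))
        for i, m in enumerate(group, start=1):
            m.module_id = f"{prefix}_{chrom}_{i}"
    return modules


def modules_table(modules: list[Module]) -> pd.DataFrame:
    rows = []
    for m in modules:
        for member in m.members:
            rows.append(
                {
                    "module_id": m.module_id,
                    "member_signal": member,
                    "chrom": m.chrom,
                    "feature_class": m.feature_class,
                    "n_h4": m.n_h4,
                    "n_h3": m.n_h3,
                    "n_pairs": m.n_pairs,
                    "status": m.status,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "module_id", "member_signal", "chrom", "feature_class",
            "n_h4", "n_h3", "n_pairs", "status",
        ],
    )
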
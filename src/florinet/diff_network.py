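"""Differential comparison of two condition-pair networks.

A node "distinguishes" the two networks when it is present in only one of
them, or present in both with a different signed neighbour set (rewired).
Over-representation of a TF family among the distinguishing nodes is tested
with a one-sided (upper-tail) hypergeometric test on the 2x2 table

    distinguishing x in-family

over a node universe (default: the union of both networks' node sets), and
summarized by the table's odds ratio, with a Haldane 0.5 correction applied
to every cell when any cell is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .expression_de import benjamini_hochberg
from .trn_build import TRN

__all__ = ["NetworkComparison", "EnrichmentResult", "compare_networks", "node_family_enrichment", "enrich_families"]


@dataclass
class NetworkComparison:
    nodes_only_a: set[str]
    nodes_only_b: set[str]
    rewired_nodes: set[str]
    shared_identical_nodes: set[str]
    edges_only_a: set[tuple[str, str, str]]
    edges_only_b: set[tuple[str, str, str]]

    @property
    def distinguishing_nodes(self) -> set[str]:
        return self.nodes_only_a | self.nodes_only_b | self.rewired_nodes

    @property
    def node_universe(self) -> set[str]:
        return self.distinguishing_nodes | self.shared_identical_nodes


@dataclass
class EnrichmentResult:
    family: str
    table: np.ndarray  # 2x2: rows distinguishing yes/no, cols in-family yes/no
    odds_ratio: float
    p_value: float
    haldane_corrected: bool


def compare_networks(trn_a: TRN, trn_b: TRN) -> NetworkComparison:
    """Partition the joint node set by topological difference between networks."""
    nodes_a, nodes_b = trn_a.nodes, trn_b.nodes
    only_a = nodes_a - nodes_b
    only_b = nodes_b - nodes_a
    shared = nodes_a & nodes_b
    rewired = {
        v for v in shared if trn_a.neighbor_signature(v) != trn_b.neighbor_signature(v)
    }
    identical = shared - rewired
    ea, eb = trn_a.edge_set, trn_b.edge_set
    return NetworkComparison(
        nodes_only_a=only_a,
        nodes_only_b=only_b,
        rewired_nodes=rewired,
        shared_identical_nodes=identical,
        edges_only_a=ea - eb,
        edges_only_b=eb - ea,
    )


def node_family_enrichment(
    comparison: NetworkComparison,
    family: Iterable[str],
    universe: Iterable[str] | None = None,
    family_name: str = "",
) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of a gene family among distinguishing nodes.

    With universe size N, family size K, distinguishing size n and overlap k,
    p = P(X >= k) for X ~ Hypergeometric(N, K, n). The odds ratio is the 2x2
    cross-product k(N-K-n+k) / ((K-k)(n-k)).
    """
    uni = set(universe) if universe is not None else comparison.node_universe
    fam = set(family)
    if not fam <= uni:
        raise ValueError(f"family {family_name!r} is not a subset of the universe")
    dist = comparison.distinguishing_nodes & uni
    N, K, n = len(uni), len(fam), len(dist)
    k = len(dist & fam)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    table = np.array(
        [[k, n - k], [K - k, N - K - n + k]], dtype=float
    )
    haldane = bool((table == 0).any())
    t = table + 0.5 if haldane else table
    odds = float((t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0]))
    return EnrichmentResult(family_name, table, odds, min(p, 1.0), haldane)


def enrich_families(
    comparison: NetworkComparison,
    families: Mapping[str, Iterable[str]],
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Enrichment of several families with BH correction across them."""
    uni = set(universe) if universe is not None else comparison.node_universe
    results = []
    for name in sorted(families):
        fam = set(families[name]) & uni
        res = node_family_enrichment(comparison, fam, uni, family_name=name)
        results.append(res)
    df = pd.DataFrame(
        {
            "family": [r.family for r in results],
            "overlap": [int(r.table[0, 0]) for r in results],
            "family_size": [int(r.table[0, 0] + r.table[1, 0]) for r in results],
            "distinguishing": [int(r.table[0, 0] + r.table[0, 1]) for r in results],
            "universe": len(uni),
            "odds_ratio": [r.odds_ratio for r in results],
            "p_value": [r.p_value for r in results],
            "haldane_corrected": [r.haldane_corrected for r in results],
        }
    )
    df["fdr"] = benjamini_hochberg(df["p_value"].to_numpy())
    return df
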
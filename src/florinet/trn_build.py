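"""Transcription-regulatory-network assembly from motif + expression evidence.

A candidate edge TF -> target exists when the TF's binding motif has at least
one occurrence in the target's promoter. A candidate is retained only if all
three refinement criteria hold:

(i)   the pair is coexpressed — Spearman correlation above the threshold
      (default 0.9; by default on the absolute value, because negative edges
      are part of the network even though the published phrasing is ">0.9");
(ii)  at least one gene of the pair is differentially expressed in the
      induced-vs-control or flowered-vs-control comparison;
(iii) at least one gene of the pair is on the curated floral organ
      initiation/differentiation list.

Edge sign is the sign of the Spearman correlation (+ activation-like,
- repression-like). One network is built per condition comparison (C-I, C-F),
with correlations computed over the samples of that comparison's two
conditions by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CountMatrix
from .expression_de import normalize_counts

__all__ = ["TRNConfig", "TRN", "compute_coexpression", "assemble_trn", "deg_union"]

logger = logging.getLogger(__name__)

EDGE_FIELDS = [
    "tf",
    "target",
    "rho",
    "sign",
    "n_hits",
    "motif_hit",
    "coexpressed",
    "deg_criterion",
    "floral_criterion",
]


@dataclass(frozen=True)
class TRNConfig:
    rho_threshold: float = 0.9
    rho_mode: str = "absolute"  # or "signed"
    sample_scope: str = "pair_conditions"  # or "all_samples"

    def __post_init__(self) -> None:
        if not (0 < self.rho_threshold <= 1):
            raise ValueError("rho_threshold must lie in (0, 1]")
        if self.rho_mode not in ("absolute", "signed"):
            raise ValueError("rho_mode must be 'absolute' or 'signed'")
        if self.sample_scope not in ("pair_conditions", "all_samples"):
            raise ValueError("sample_scope must be 'pair_conditions' or 'all_samples'")


@dataclass
class TRN:
    """A directed TF -> target network for one condition comparison."""

    comparison: str
    edges: pd.DataFrame  # columns EDGE_FIELDS

    @property
    def nodes(self) -> set[str]:
        return set(self.edges["tf"]) | set(self.edges["target"])

    @property
    def edge_set(self) -> set[tuple[str, str, str]]:
        return {(r.tf, r.target, r.sign) for r in self.edges.itertuples(index=False)}

    def neighbor_signature(self, node: str) -> frozenset[tuple[str, str, str, str]]:
        """Signed directed incident edges of ``node`` (for rewiring detection)."""
        inc = self.edges[(self.edges["tf"] == node) | (self.edges["target"] == node)]
        return frozenset(
            (r.tf, r.target, r.sign, "out" if r.tf == node else "in")
            for r in inc.itertuples(index=False)
        )


def compute_coexpression(
    cm: CountMatrix,
    tf_ids: Sequence[str],
    sample_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Spearman rho between every TF and every gene on normalized counts.

    Average ranks are used for ties. Pairs involving a constant expression
    vector get NaN (undefined), never 0. The TF-vs-itself cell is NaN.
    """
    samples = list(sample_ids) if sample_ids is not None else cm.sample_ids
    if len(samples) < 3:
        raise ValueError("Spearman correlation needs >= 3 samples in scope")
    sub = cm.subset_samples(samples)
    _, norm = normalize_counts(sub)
    tf_ids = [t for t in tf_ids if t in norm.index]
    vals = norm.to_numpy(dtype=float)
    ranks = stats.rankdata(vals, axis=1)  # average ranks on ties
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    constant = norms == 0
    safe = np.where(constant, 1.0, norms)
    unit = centered / safe[:, None]
    tf_pos = [norm.index.get_loc(t) for t in tf_ids]
    rho = unit[tf_pos] @ unit.T
    rho = np.clip(rho, -1.0, 1.0)
    rho[:, constant] = np.nan
    rho[np.asarray(constant)[tf_pos], :] = np.nan
    table = pd.DataFrame(rho, index=tf_ids, columns=norm.index)
    for t in tf_ids:
        table.loc[t, t] = np.nan
    return table


def deg_union(de_tables: Mapping[str, pd.DataFrame], comparisons: Iterable[str] | None = None) -> set[str]:
    """Union of DEG calls over the given comparisons (default: all provided).

    The default rule follows the network definition: a pair passes the DE
    criterion if either gene is a DEG in flowered-vs-control or in
    induced-vs-control.
    """
    keys = list(comparisons) if comparisons is not None else list(de_tables)
    out: set[str] = set()
    for k in keys:
        t = de_tables[k]
        out |= set(t.index[t["is_deg"]])
    return out


def assemble_trn(
    hits: pd.DataFrame,
    rho_table: pd.DataFrame,
    deg_genes: set[str],
    tf_map: Mapping[str, str],
    floral_set: set[str],
    config: TRNConfig = TRNConfig(),
    comparison: str = "",
) -> TRN:
    """Apply the three refinement criteria to motif-supported candidate pairs.

    ``hits`` is a scan table (gene = promoter owner = candidate target);
    ``tf_map`` maps TF gene ids to their motif ids. Candidate pairs whose
    correlation is undefined are dropped with a logged reason. Output edges
    are sorted by (tf, target) so assembly is order-independent.
    """
    motif_to_tfs: dict[str, list[str]] = {}
    for tf, motif in tf_map.items():
        if tf not in rho_table.index:
            logger.warning("TF %s has a motif but no expression; excluded", tf)
            continue
        motif_to_tfs.setdefault(motif, []).append(tf)

    rows: list[dict] = []
    if len(hits):
        per_pair = hits.groupby(["motif", "gene"], sort=False).size()
        for (motif, target), n_hits in per_pair.items():
            for tf in motif_to_tfs.get(motif, ()):
                if tf == target:
                    continue  # self-regulation excluded
                if target not in rho_table.columns:
                    logger.info("edge %s->%s dropped: target not in expression", tf, target)
                    continue
                rho = rho_table.at[tf, target]
                if np.isnan(rho):
                    logger.info("edge %s->%s dropped: correlation undefined", tf, target)
                    continue
                stat = abs(rho) if config.rho_mode == "absolute" else rho
                coexpressed = bool(stat > config.rho_threshold)
                deg_ok = tf in deg_genes or target in deg_genes
                floral_ok = tf in floral_set or target in floral_set
                if coexpressed and deg_ok and floral_ok:
                    rows.append(
                        {
                            "tf": tf,
                            "target": target,
                            "rho": float(rho),
                            "sign": "+" if rho >= 0 else "-",
                            "n_hits": int(n_hits),
                            "motif_hit": True,
                            "coexpressed": True,
                            "deg_criterion": True,
                            "floral_criterion": True,
                        }
                    )
    edges = pd.DataFrame(rows, columns=EDGE_FIELDS)
    edges = edges.sort_values(["tf", "target"], kind="mergesort").reset_index(drop=True)
    return TRN(comparison=comparison, edges=edges)
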
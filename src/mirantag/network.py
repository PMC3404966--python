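"""Bipartite miRNA-gene network assembly, hub detection and rank evaluation.

Edges are the pairs passing a Benjamini-Hochberg FDR threshold.  Hubs are
nodes whose connectivity exceeds a cutoff calibrated on a network rebuilt by
the same pipeline from sample-shuffled data, separately for the miRNA side
and the gene side.
"""
from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "bh_adjust",
    "build_network",
    "connectivity",
    "detect_hubs",
    "rank_pairs",
    "merge_rankings",
    "rank_evaluation",
]

EDGE_COLUMNS = ["mirna_id", "gene_id", "score", "pvalue", "qvalue"]


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_network(scores: Iterable, q_threshold: float) -> pd.DataFrame:
    """Edge table of all pairs with qvalue <= threshold.

    ``scores`` are PairScore or CorrelationScore objects carrying q-values.
    The returned frame has columns mirna_id, gene_id, score, pvalue, qvalue
    and records the threshold in ``attrs["q_threshold"]``.
    """
    rows = []
    for s in scores:
        if s.qvalue is None:
            raise ValueError("scores must carry BH q-values; run the scan with FDR adjustment")
        if s.qvalue <= q_threshold:
            value = getattr(s, "coefficient", None)
            if value is None:
                value = s.r
            rows.append((s.mirna_id, s.gene_id, float(value), float(s.pvalue), float(s.qvalue)))
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    if edges.duplicated(["mirna_id", "gene_id"]).any():
        raise ValueError("duplicate (mirna_id, gene_id) rows in the score list")
    edges.attrs["q_threshold"] = float(q_threshold)
    return edges


def connectivity(edges: pd.DataFrame) -> pd.DataFrame:
    """Per-node edge count, one row per node, classed as miRNA or gene."""
    parts = []
    for col, klass in (("mirna_id", "miRNA"), ("gene_id", "gene")):
        k = edges[col].value_counts().sort_index()
        parts.append(
            pd.DataFrame(
                {"node_id": k.index, "node_class": klass, "connectivity": k.to_numpy()}
            )
        )
    return pd.concat(parts, ignore_index=True)


def _cutoff(random_k: np.ndarray, rule: str) -> float:
    if random_k.size == 0:
        return 0.0
    if rule == "scaled_max":
        return 0.75 * float(random_k.max())
    if rule == "percentile75":
        return float(np.percentile(random_k, 75))
    raise ValueError(f"unknown hub rule {rule!r}")


def detect_hubs(
    edges: pd.DataFrame,
    randomized_edges: pd.DataFrame,
    rule: str = "scaled_max",
) -> pd.DataFrame:
    """Flag hub nodes against a randomized-data network, per node class.

    The default rule marks a node as a hub when its connectivity exceeds
    0.75 x the maximal connectivity observed in the randomized network for
    the same class; ``rule="percentile75"`` uses the 75th percentile of the
    randomized connectivity distribution instead.  An empty randomized
    network yields cutoff 0 (every connected node is a hub) with a warning.
    """
    if edges.empty:
        return pd.DataFrame(
            columns=["node_id", "node_class", "connectivity", "is_hub", "cutoff_used"]
        )
    real = connectivity(edges)
    rand = connectivity(randomized_edges) if not randomized_edges.empty else pd.DataFrame(
        columns=["node_id", "node_class", "connectivity"]
    )
    if randomized_edges.empty:
        logger.warning("randomized network is empty; hub cutoff falls back to 0")
    out = []
    for klass in ("miRNA", "gene"):
        sub = real[real["node_class"] == klass].copy()
        rk = rand.loc[rand["node_class"] == klass, "connectivity"].to_numpy()
        cut = _cutoff(rk, rule)
        sub["is_hub"] = sub["connectivity"] > cut
        sub["cutoff_used"] = cut
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def rank_pairs(scores: Iterable) -> list[tuple[tuple[str, str], int]]:
    """Deterministic 1-based ranking of scored pairs.

    Sorted by p-value, then |score| descending, then lexicographic pair id.
    """
    keyed = []
    for s in scores:
        value = getattr(s, "coefficient", None)
        if value is None:
            value = s.r
        keyed.append(((s.pvalue, -abs(value), s.mirna_id, s.gene_id), (s.mirna_id, s.gene_id)))
    keyed.sort()
    return [(pair, i + 1) for i, (_, pair) in enumerate(keyed)]


def merge_rankings(
    rankings: Sequence[Sequence[tuple[tuple[str, str], int]]]
) -> list[tuple[tuple[str, str], int]]:
    """Combine rankings by minimum rank per pair, then re-rank.

    Ties on the minimum rank are broken lexicographically by pair id so the
    merged ranking is deterministic and 1-based unique.
    """
    best: dict[tuple[str, str], int] = {}
    for ranking in rankings:
        for pair, rank in ranking:
            if pair not in best or rank < best[pair]:
                best[pair] = rank
    merged = sorted(best.items(), key=lambda kv: (kv[1], kv[0]))
    return [(pair, i + 1) for i, (pair, _) in enumerate(merged)]


def rank_evaluation(
    method_scores: Sequence[tuple[tuple[str, str], int]],
    truth_pairs: set,
) -> pd.DataFrame:
    """Cumulative-hit curve: truth pairs among the top-r predictions, for each r.

    Truth pairs absent from the prediction universe can never be hit; their
    count is logged and recorded in ``attrs["unreachable_truths"]``.
    """
    ranked = sorted(method_scores, key=lambda pr: pr[1])
    ranks = [r for _, r in ranked]
    if len(set(ranks)) != len(ranks) or (ranks and ranks[0] < 1):
        raise ValueError("ranks must be unique and 1-based")
    universe = {pair for pair, _ in ranked}
    unreachable = {p for p in truth_pairs if p not in universe}
    if unreachable:
        logger.warning("%d truth pairs are outside the prediction universe", len(unreachable))
    hits = np.cumsum([pair in truth_pairs for pair, _ in ranked])
    curve = pd.DataFrame({"rank": ranks, "hits": hits})
    curve.attrs["unreachable_truths"] = len(unreachable)
    return curve


def to_sif(edges: pd.DataFrame, path, relation: str = "antagonism") -> None:
    """Write edges in the simple interaction format used by graph viewers."""
    with open(path, "w") as fh:
        for row in edges.itertuples(index=False):
            fh.write(f"{row.mirna_id}\t{relation}\t{row.gene_id}\n")
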
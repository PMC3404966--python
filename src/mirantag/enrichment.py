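"""Gene-set (GO-style) enrichment of predicted target sets.

Each miRNA's predicted target set is tested against every annotation
category with the upper-tail hypergeometric test, using the set of genes
that survived expression filtering as the universe.  No multiple-testing
correction is applied inside the GO scoring by default; instead a negative
control re-runs the analysis on networks whose target labels are permuted
while each miRNA keeps its connectivity.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .network import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentRow",
    "hypergeom_enrich",
    "combined_target_sets",
    "randomized_go_control",
]


@dataclasses.dataclass
class EnrichmentRow:
    mirna_id: str
    category_id: str
    overlap: int
    set_size: int
    category_size: int
    universe_size: int
    pvalue: float
    significant: bool


def hypergeom_enrich(
    target_set: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    p_threshold: float = 0.001,
    mirna_id: str = "miRNA",
) -> list[EnrichmentRow]:
    """Upper-tail hypergeometric p-value of the target set in every category.

    Categories are intersected with the universe first; the target set must
    be a subset of the universe.  An empty target set yields an empty result
    with a warning.
    """
    universe = set(universe)
    targets = set(target_set)
    if not targets:
        logger.warning("%s: empty target set, nothing to test", mirna_id)
        return []
    if not targets <= universe:
        raise ValueError("target set must be a subset of the universe")
    n_univ = len(universe)
    rows = []
    for cat, genes in annotation.items():
        cat_genes = set(genes) & universe
        if not cat_genes:
            continue
        overlap = len(targets & cat_genes)
        # P(X >= overlap), X ~ Hypergeom(N=n_univ, K=|category|, n=|targets|)
        p = float(stats.hypergeom.sf(overlap - 1, n_univ, len(cat_genes), len(targets)))
        rows.append(
            EnrichmentRow(
                mirna_id=mirna_id,
                category_id=str(cat),
                overlap=overlap,
                set_size=len(targets),
                category_size=len(cat_genes),
                universe_size=n_univ,
                pvalue=p,
                significant=p <= p_threshold,
            )
        )
    return rows


def target_sets(edges: pd.DataFrame) -> dict[str, set[str]]:
    """Predicted target set of each miRNA from an edge table."""
    return {
        str(m): set(sub["gene_id"]) for m, sub in edges.groupby("mirna_id", sort=True)
    }


def combined_target_sets(
    edges: pd.DataFrame, seed_hits: Iterable[tuple[str, str]]
) -> dict[str, set[str]]:
    """Intersection of expression evidence and sequence evidence.

    ``seed_hits`` enumerates the (mirna_id, gene_id) pairs carrying at least
    one seed match of any length; only predicted targets also present there
    are kept.
    """
    hits = set(seed_hits)
    out: dict[str, set[str]] = {}
    for m, genes in target_sets(edges).items():
        kept = {g for g in genes if (m, g) in hits}
        if kept:
            out[m] = kept
    return out


def enrich_all(
    sets_by_mirna: Mapping[str, Iterable[str]],
    annotation: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    p_threshold: float = 0.001,
    bh: bool = False,
) -> pd.DataFrame:
    """Enrichment rows for every miRNA target set, as one table.

    ``bh=True`` additionally attaches BH-adjusted q-values across all rows
    (off by default: the negative control below calibrates the raw-p
    threshold instead).
    """
    rows: list[EnrichmentRow] = []
    for m, ts in sets_by_mirna.items():
        rows.extend(hypergeom_enrich(ts, annotation, universe, p_threshold, mirna_id=m))
    table = pd.DataFrame([dataclasses.asdict(r) for r in rows])
    if bh and not table.empty:
        table["qvalue"] = bh_adjust(table["pvalue"].to_numpy())
    return table


def randomized_go_control(
    edges: pd.DataFrame,
    annotation: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    rng: np.random.Generator | int | None = None,
    n_rounds: int = 100,
    p_threshold: float = 0.001,
) -> pd.DataFrame:
    """Label-shuffle negative control for the GO enrichment.

    Each round permutes the gene column of the edge table (every miRNA keeps
    its connectivity, the multiset of target labels is preserved), re-runs
    the enrichment, and records the fraction of tests passing the real-data
    threshold.  Returns one row per round with columns ``fraction_significant``
    and ``n_tests``; all null p-values are stacked in ``attrs["pvalues"]``.
    """
    if n_rounds < 1:
        raise ValueError(f"n_rounds must be >= 1, got {n_rounds}")
    rng = np.random.default_rng(rng)
    genes = edges["gene_id"].to_numpy()
    rows = []
    all_p: list[np.ndarray] = []
    for _ in range(n_rounds):
        shuffled = edges.copy()
        shuffled["gene_id"] = genes[rng.permutation(len(genes))]
        table = enrich_all(target_sets(shuffled), annotation, universe, p_threshold)
        if table.empty:
            rows.append((0.0, 0))
            continue
        rows.append((float(table["significant"].mean()), len(table)))
        all_p.append(table["pvalue"].to_numpy())
    out = pd.DataFrame(rows, columns=["fraction_significant", "n_tests"])
    out.attrs["pvalues"] = np.concatenate(all_p) if all_p else np.empty(0)
    return out
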
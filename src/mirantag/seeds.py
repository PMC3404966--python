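"""Seed-match extraction and enrichment of predicted targets' 3'UTRs.

A miRNA recognizes its targets mainly through base pairing of its 5' seed
region.  For each mature miRNA the module derives every 6-, 7- and 8-mer
window within the first eight nucleotides, takes the reverse complement in
the DNA alphabet (the "match" string searched in 3'UTRs), counts overlapping
occurrences over all predicted miRNA-target pairs, and tests the total
against a null built by permuting the miRNA-to-target assignment.  The
permutation keeps the multiset of UTRs and each miRNA's edge count intact,
so UTR length and nucleotide composition are preserved exactly.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from Bio.Seq import Seq

from .errors import SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "SeedCatalog",
    "SeedEnrichmentResult",
    "extract_seed_matches",
    "count_matches",
    "seed_enrichment",
]

SEED_LENGTHS = (6, 7, 8)
_RNA_ALPHABET = set("ACGU")


@dataclasses.dataclass(frozen=True)
class SeedCatalog:
    """DNA-alphabet seed-match strings of one mature miRNA."""

    mirna_id: str
    mature_sequence: str  # RNA alphabet, 5'->3'
    matches_by_length: Mapping[int, frozenset[str]]


@dataclasses.dataclass
class SeedEnrichmentResult:
    k: int
    observed_count: int
    null_mean: float
    null_sd: float
    zscore: float
    pvalue: float
    n_shuffles: int
    degenerate: bool = False  # permutation-invariant statistic (null sd = 0)


def extract_seed_matches(
    mature_sequence: str, mirna_id: str = "miRNA", offset: int = 0
) -> SeedCatalog:
    """Derive all 6/7/8-mer match strings from a mature miRNA's 5' end.

    The eight seed-region nucleotides start at ``offset`` (0 = the very first
    nucleotide; 1 shifts the window to positions 2-9, closer to canonical
    seed theory).  Every contiguous k-mer window inside that region is
    reverse-complemented into the DNA alphabet.  T in the input is tolerated
    and read as U.
    """
    seq = str(mature_sequence).upper().replace("T", "U")
    if len(seq) < 8 + offset:
        raise ValueError(
            f"mature sequence must have at least {8 + offset} nt, got {len(seq)}"
        )
    region = seq[offset : offset + 8]
    if set(region) - _RNA_ALPHABET:
        raise ValueError(f"illegal characters in seed region {region!r}")
    matches: dict[int, frozenset[str]] = {}
    for k in SEED_LENGTHS:
        kmers = {region[i : i + k] for i in range(8 - k + 1)}
        matches[k] = frozenset(
            str(Seq(km).back_transcribe().reverse_complement()) for km in kmers
        )
    return SeedCatalog(mirna_id=mirna_id, mature_sequence=seq, matches_by_length=matches)


def count_matches(utr_sequence: str, catalog: SeedCatalog, k: int) -> int:
    """Total overlapping occurrences of every length-k match string in a UTR.

    Sliding window with step 1; an empty UTR counts 0.  Distinct match
    strings cannot share a window, so summing per-window membership equals
    summing per-string occurrence counts.
    """
    if k not in SEED_LENGTHS:
        raise ValueError(f"k must be one of {SEED_LENGTHS}, got {k}")
    utr = str(utr_sequence).upper().replace("U", "T")
    matches = catalog.matches_by_length[k]
    return sum(1 for i in range(len(utr) - k + 1) if utr[i : i + k] in matches)


def seed_enrichment(
    edges: pd.DataFrame,
    mature_db: Mapping[str, str],
    utr_db: Mapping[str, str],
    n_shuffles: int = 1000,
    rng: np.random.Generator | int | None = None,
    offset: int = 0,
    ks: Sequence[int] = SEED_LENGTHS,
) -> list[SeedEnrichmentResult]:
    """Seed-count enrichment of predicted pairs against assignment shuffles.

    For each seed length k the observed count is the raw sum over all edges
    of the pair's UTR match count.  The null permutes the miRNA column of
    the edge list (an unbiased Fisher-Yates shuffle via numpy), recomputes
    the sum, and a one-sided normal p-value is taken from the null mean and
    standard deviation.  Edges whose gene lacks a UTR are dropped with a
    logged count; a missing mature sequence is a schema error.
    """
    if n_shuffles < 1:
        raise ValueError(f"n_shuffles must be >= 1, got {n_shuffles}")
    missing_mirna = sorted(set(edges["mirna_id"]) - set(mature_db))
    if missing_mirna:
        raise SchemaError(f"no mature sequence for miRNAs: {missing_mirna[:5]}")
    has_utr = edges["gene_id"].isin(utr_db)
    if (~has_utr).any():
        logger.warning("dropping %d edges whose gene has no 3'UTR", int((~has_utr).sum()))
    kept = edges.loc[has_utr]
    mirnas = kept["mirna_id"].to_list()
    genes = kept["gene_id"].to_list()
    if len(set(mirnas)) < 2:
        raise ValueError("need at least 2 distinct miRNAs to permute assignments")

    catalogs = {
        m: extract_seed_matches(mature_db[m], mirna_id=m, offset=offset)
        for m in set(mirnas)
    }
    cache: dict[tuple[str, str, int], int] = {}

    def pair_count(m: str, g: str, k: int) -> int:
        key = (m, g, k)
        if key not in cache:
            cache[key] = count_matches(utr_db[g], catalogs[m], k)
        return cache[key]

    rng = np.random.default_rng(rng)
    results = []
    null_counts = {k: np.empty(n_shuffles) for k in ks}
    for s in range(n_shuffles):
        perm = rng.permutation(len(mirnas))
        shuffled = [mirnas[i] for i in perm]
        for k in ks:
            null_counts[k][s] = sum(
                pair_count(m, g, k) for m, g in zip(shuffled, genes)
            )
    for k in ks:
        observed = int(sum(pair_count(m, g, k) for m, g in zip(mirnas, genes)))
        mean = float(null_counts[k].mean())
        sd = float(null_counts[k].std(ddof=1)) if n_shuffles > 1 else 0.0
        if sd == 0.0:
            logger.warning("k=%d: permutation-invariant seed count; flagged degenerate", k)
            results.append(
                SeedEnrichmentResult(k, observed, mean, 0.0, 0.0, 1.0, n_shuffles, True)
            )
            continue
        z = (observed - mean) / sd
        results.append(
            SeedEnrichmentResult(
                k, observed, mean, sd, z, float(stats.norm.sf(z)), n_shuffles
            )
        )
    return results


def enrichment_table(results: Sequence[SeedEnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results])
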
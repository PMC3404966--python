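"""Pearson-correlation baseline with leave-one-out outlier correction.

With a few dozen patient samples, a single aberrant measurement can dominate
a Pearson coefficient.  The correction computes the n leave-one-out
coefficients r_(-k), flags sample k as an outlier when dropping it moves the
coefficient by at least two standard deviations of the leave-one-out
distribution, and recomputes r once on the retained samples.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, SchemaError

logger = logging.getLogger(__name__)

__all__ = ["CorrelationScore", "loo_corrected_pearson", "correlation_scan"]


@dataclasses.dataclass
class CorrelationScore:
    mirna_id: str
    gene_id: str
    r: float
    r_raw: float
    pvalue: float
    outlier_samples: list[str]
    n_effective: int
    all_flagged: bool = False
    qvalue: float | None = None
    significant: bool | None = None


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def loo_corrected_pearson(
    x: Sequence[float],
    y: Sequence[float],
    sample_ids: Sequence[str] | None = None,
    mirna_id: str = "miRNA",
    gene_id: str = "gene",
) -> CorrelationScore:
    """Pearson correlation with the 2-SD leave-one-out outlier rule.

    The p-value of the corrected coefficient comes from the exact t transform
    at the effective (post-removal) sample count.  If every sample is flagged
    (or too few remain), the raw coefficient is returned with
    ``all_flagged=True``.  Perfectly stable pairs (sd of the leave-one-out
    coefficients equal to zero, e.g. exactly linear data) flag no outliers.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise SchemaError("x and y must be 1-D of equal length")
    n = x.size
    if n < 5:
        raise DegenerateInputError(f"need at least 5 samples, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant vector has no defined correlation")
    ids = [str(s) for s in sample_ids] if sample_ids is not None else [str(i) for i in range(n)]
    if len(ids) != n:
        raise SchemaError("sample_ids length does not match the vectors")

    r_raw, p_raw = _pearson(x, y)
    mask = np.ones(n, dtype=bool)
    loo = np.empty(n)
    for k in range(n):
        mask[k] = False
        loo[k] = _pearson(x[mask], y[mask])[0]
        mask[k] = True
    sd = loo.std(ddof=1)
    if sd > 0:
        outliers = np.abs(loo - loo.mean()) >= 2.0 * sd
    else:
        outliers = np.zeros(n, dtype=bool)

    keep = ~outliers
    if keep.sum() < 3 or not keep.any() or outliers.all():
        logger.warning(
            "%s-%s: all samples flagged by the LOO rule; returning raw coefficient",
            mirna_id, gene_id,
        )
        return CorrelationScore(
            mirna_id, gene_id, r=r_raw, r_raw=r_raw, pvalue=p_raw,
            outlier_samples=[i for i, o in zip(ids, outliers) if o],
            n_effective=n, all_flagged=True,
        )
    if outliers.any():
        r, p = _pearson(x[keep], y[keep])
    else:
        r, p = r_raw, p_raw
    return CorrelationScore(
        mirna_id, gene_id, r=r, r_raw=r_raw, pvalue=p,
        outlier_samples=[i for i, o in zip(ids, outliers) if o],
        n_effective=int(keep.sum()),
    )


def correlation_scan(expr, fdr_q: float = 0.1) -> list[CorrelationScore]:
    """LOO-corrected Pearson correlation for every (miRNA, gene) pair.

    BH-adjusted q-values are attached across all pairs; the sign of r is
    retained so callers can select the negatively correlated component.
    """
    from .network import bh_adjust

    mirna, mrna = expr.mirna_matrix, expr.mrna_matrix
    if mirna.shape[0] == 0 or mrna.shape[0] == 0:
        raise SchemaError("empty expression matrix: nothing to scan")
    ids = list(mirna.columns)
    scores: list[CorrelationScore] = []
    for mirna_id, x_row in mirna.iterrows():
        for gene_id, y_row in mrna.iterrows():
            scores.append(
                loo_corrected_pearson(
                    x_row.to_numpy(), y_row.to_numpy(), sample_ids=ids,
                    mirna_id=str(mirna_id), gene_id=str(gene_id),
                )
            )
    qvalues = bh_adjust([s.pvalue for s in scores])
    for s, q in zip(scores, qvalues):
        s.qvalue = float(q)
        s.significant = bool(q <= fdr_q)
    return scores
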
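"""Readers, writers and expression filtering.

Expression matrices are tab-separated, one feature per row, first column the
feature id, header row of sample ids, numeric body — the shape exported by
the usual normalization pipelines.  FASTA files carry mature miRNA and 3'UTR
sequences whose headers match the expression matrix ids; annotations come as
GMT or two-column TSV (category, gene).
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ParseError, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "iqr_filter",
    "PairedExpressionSet",
    "read_fasta",
    "read_annotation",
]


def read_expression(path) -> pd.DataFrame:
    """Read a feature x sample TSV into a float matrix.

    Duplicate feature ids are collapsed by their mean with a warning.  Cells
    that are neither numeric nor a recognized missing-value token raise a
    ParseError naming the cell; rows containing missing values are kept here
    and dropped (with a log line) when the PairedExpressionSet is assembled.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        if df[col].dtype == object:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError):
                for fid, val in df[col].items():
                    if isinstance(val, str):
                        try:
                            float(val)
                        except ValueError:
                            raise ParseError(
                                f"{path}: non-numeric value {val!r} at feature "
                                f"{fid!r}, sample {col!r}"
                            ) from None
                raise
    if df.index.has_duplicates:
        n_dup = int(df.index.duplicated().sum())
        logger.warning("%s: %d duplicate feature ids collapsed by mean", path, n_dup)
        df = df.groupby(level=0, sort=False).mean()
    return df.astype(float)


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="feature_id")


def iqr_filter(
    matrix: pd.DataFrame, abundance_quantile: float | None = None
) -> pd.DataFrame:
    """Keep features whose across-sample IQR strictly exceeds the median IQR.

    Low-variance features mostly contribute noise associations, so only the
    upper half of the IQR distribution is retained (strict inequality: ties
    with the median are excluded).  ``abundance_quantile`` optionally drops
    features whose median expression falls below that quantile of all
    feature medians before the variation filter.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 features to apply the IQR filter")
    if matrix.shape[1] < 2:
        raise ValueError("IQR is undefined with fewer than 2 samples")
    if abundance_quantile is not None:
        medians = matrix.median(axis=1)
        floor = medians.quantile(abundance_quantile)
        matrix = matrix.loc[medians >= floor]
        logger.info("abundance floor kept %d features", matrix.shape[0])
    q75 = matrix.quantile(0.75, axis=1)
    q25 = matrix.quantile(0.25, axis=1)
    iqr = q75 - q25
    cutoff = iqr.median()
    kept = matrix.loc[iqr > cutoff]
    if kept.shape[0] == 0:
        logger.warning("IQR filter removed every feature (all IQRs tie the median)")
    logger.info("IQR filter: %d of %d features kept (median IQR %.4g)",
                kept.shape[0], matrix.shape[0], cutoff)
    return kept


@dataclasses.dataclass
class PairedExpressionSet:
    """Two feature x sample matrices sharing one ordered sample list."""

    mirna_matrix: pd.DataFrame
    mrna_matrix: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.mirna_matrix.columns) != list(self.mrna_matrix.columns):
            raise SchemaError(
                "miRNA and mRNA matrices must carry identical sample ids in the same order"
            )
        for name in ("mirna_matrix", "mrna_matrix"):
            m = getattr(self, name)
            n_bad = int(m.isna().any(axis=1).sum())
            if n_bad:
                logger.warning("%s: dropping %d rows with missing values", name, n_bad)
                setattr(self, name, m.dropna(axis=0))

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.mirna_matrix.columns]

    @classmethod
    def from_files(cls, mirna_path, mrna_path) -> "PairedExpressionSet":
        return cls(read_expression(mirna_path), read_expression(mrna_path))

    def filtered(self, abundance_quantile: float | None = None) -> "PairedExpressionSet":
        """Apply the IQR variation filter to both matrices."""
        return PairedExpressionSet(
            iqr_filter(self.mirna_matrix, abundance_quantile),
            iqr_filter(self.mrna_matrix, abundance_quantile),
        )


def read_fasta(path) -> dict[str, str]:
    """FASTA as an id -> sequence dict; duplicate ids keep the longest record."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        if rec.id in seqs and len(seqs[rec.id]) >= len(s):
            logger.info("%s: duplicate record %s, keeping the longer sequence", path, rec.id)
            continue
        if rec.id in seqs:
            logger.info("%s: duplicate record %s, keeping the longer sequence", path, rec.id)
        seqs[rec.id] = s
    return seqs


def read_annotation(path) -> dict[str, set[str]]:
    """Gene-set annotation as a category -> gene-set dict.

    ``.gmt`` files follow the usual layout (name, description, genes...);
    anything else is read as a two-column TSV of (category_id, gene_id).
    """
    path = Path(path)
    ann: dict[str, set[str]] = {}
    if path.suffix.lower() == ".gmt":
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                ann.setdefault(parts[0], set()).update(g for g in parts[2:] if g)
    else:
        table = pd.read_csv(path, sep="\t", header=None, names=["category_id", "gene_id"])
        for cat, sub in table.groupby("category_id"):
            ann[str(cat)] = set(sub["gene_id"].astype(str))
    return ann
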
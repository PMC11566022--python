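"""RNA polymerase II density from global run-on sequencing.

Density for a gene is read coverage over the gene body normalized by
sequencing depth and length, in parts per million per kilobase.  To
minimize the contribution of promoter-proximal paused polymerase, the
first 500 bp of each gene are excluded; genes of 500 bp or less are
dropped (logged).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from pislice.stats import TestResult, mann_whitney

logger = logging.getLogger(__name__)

EXCLUDE_BP = 500


def density(gene_length: int, body_reads: float, depth: float,
            exclude_bp: int = EXCLUDE_BP) -> float:
    """ppm/kb over the gene body [start + exclude_bp, end).

    ``body_reads`` are the reads overlapping the counted interval.
    Raises for genes too short to have a counted body.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    counted = gene_length - exclude_bp
    if counted <= 0:
        raise ValueError(f"gene of {gene_length} bp excluded "
                         f"(<= {exclude_bp} bp body)")
    return (body_reads / depth * 1e6) / (counted / 1000.0)


def density_table(
    reads: pd.DataFrame,
    lengths: pd.Series,
    depths: pd.Series | None = None,
    exclude_bp: int = EXCLUDE_BP,
) -> pd.Series:
    """Mean ppm/kb per gene across replicate columns of ``reads``
    (reads already restricted to gene bodies)."""
    lengths = lengths.reindex(reads.index)
    counted_kb = (lengths - exclude_bp) / 1000.0
    short = counted_kb <= 0
    if short.any():
        logger.info("density_table: excluded %d genes <= %d bp", int(short.sum()),
                    exclude_bp)
    if depths is None:
        depths = reads.sum(axis=0)
    ppm = reads.div(depths, axis=1) * 1e6
    per_rep = ppm.div(counted_kb, axis=0)
    return per_rep[~short].mean(axis=1)


def compare_classes(densities: pd.Series, class_a, class_b) -> dict:
    """Medians, IQRs and a two-tailed Mann-Whitney test between two gene
    classes (e.g. targets derepressed <= 1.25-fold vs >= 1.25-fold)."""
    a = densities.reindex(densities.index.intersection(set(class_a))).dropna()
    b = densities.reindex(densities.index.intersection(set(class_b))).dropna()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both classes must be non-empty")

    def _summary(x: pd.Series) -> dict:
        q1, q3 = np.percentile(x, [25, 75])
        return {"n": len(x), "median": float(x.median()),
                "iqr": (float(q1), float(q3))}

    test: TestResult = mann_whitney(a.to_numpy(), b.to_numpy())
    return {"class_a": _summary(a), "class_b": _summary(b), "test": test}


def split_by_fold_change(log2fc: pd.Series, genes, boundary: float = 1.25) -> dict[str, set]:
    """Split ``genes`` into derepression classes at ``boundary`` fold.
    The exact boundary belongs to the "le" (<= boundary) class."""
    fc = 2.0 ** log2fc.reindex(log2fc.index.intersection(set(genes)))
    return {
        "le": set(fc.index[fc <= boundary]),
        "ge": set(fc.index[fc >= boundary]) - set(fc.index[fc <= boundary]),
    }
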
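"""Translational efficiency (TE) and the translation-activation test.

TE for a gene is its ribosome-footprint occupancy (TPM) divided by its
mRNA abundance (TPM).  Genes with < 10 TPM ribosome occupancy in the
control condition are excluded from downstream summaries, and TE is
undefined where mRNA TPM is 0.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from pislice.stats import TestResult, ks_2samp

logger = logging.getLogger(__name__)

MIN_OCCUPANCY_TPM = 10.0
TE_UP_FOLD = 2.0
TE_DOWN_FOLD = 1.5


def compute_te(
    mrna_tpm: pd.Series,
    occupancy_tpm: pd.Series,
    *,
    min_occupancy: float = MIN_OCCUPANCY_TPM,
    occupancy_filter_values: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene TE table with the occupancy filter flag.

    ``occupancy_filter_values`` is the occupancy used for the >= 10 TPM
    filter (defaults to ``occupancy_tpm`` itself; pass the control-genotype
    occupancy when computing mutant TE).  Genes with zero mRNA are dropped
    and logged.
    """
    genes = mrna_tpm.index.intersection(occupancy_tpm.index)
    mrna = mrna_tpm.reindex(genes)
    occupancy = occupancy_tpm.reindex(genes)
    zero = mrna == 0
    if zero.any():
        logger.info("compute_te: excluded %d genes with zero mRNA TPM", int(zero.sum()))
    mrna, occupancy = mrna[~zero], occupancy[~zero]
    filter_ref = (occupancy if occupancy_filter_values is None
                  else occupancy_filter_values.reindex(mrna.index))
    return pd.DataFrame(
        {
            "mrna_tpm": mrna,
            "occupancy_tpm": occupancy,
            "te": occupancy / mrna,
            "passes_occupancy_filter": filter_ref >= min_occupancy,
        }
    )


def delta_te(te_numerator: pd.DataFrame, te_denominator: pd.DataFrame) -> pd.Series:
    """TE ratio between two conditions (e.g. mutant / control), restricted
    to genes passing the occupancy filter in both tables."""
    genes = te_numerator.index.intersection(te_denominator.index)
    keep = (te_numerator.loc[genes, "passes_occupancy_filter"]
            & te_denominator.loc[genes, "passes_occupancy_filter"])
    genes = genes[keep]
    return te_numerator.loc[genes, "te"] / te_denominator.loc[genes, "te"]


def stage_te_change(
    te_stage_b: pd.DataFrame,
    te_stage_a: pd.DataFrame,
    up_fold: float = TE_UP_FOLD,
    down_fold: float = TE_DOWN_FOLD,
) -> dict[str, set]:
    """Classes of TE change between developmental stages (B vs A):
    up if ratio >= 2, down if ratio <= 1/1.5 (both boundaries inclusive)."""
    ratio = delta_te(te_stage_b, te_stage_a)
    return {
        "up": set(ratio.index[ratio >= up_fold]),
        "down": set(ratio.index[ratio <= 1.0 / down_fold]),
    }


def test_activation_model(dte: pd.Series, target_set, control_set) -> TestResult:
    """KS comparison of the TE-change distribution for translation-model
    targets (3'UTR ELAVL1 motif + seed_plus12 site) vs control genes."""
    targets = dte.reindex(dte.index.intersection(set(target_set))).dropna()
    controls = dte.reindex(dte.index.intersection(set(control_set))).dropna()
    if len(targets) == 0 or len(controls) == 0:
        raise ValueError("target and control sets must be non-empty")
    return ks_2samp(np.log2(targets.to_numpy()), np.log2(controls.to_numpy()))
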
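"""Cleavage-product species from 5'-monophosphorylated long-RNA data.

Reads sharing the same transcript 5'-end coordinate are merged into a
single 5'-monophosphorylated RNA species; only unambiguously mapping
species enter target calling.  A species is considered detected at
>= 0.1 ppm of the library (inclusive).  Genotype dependence of a product
is decided either by absence in the slicer-deficient genotype ("absent")
or by a >= 8-fold reduction of the mean abundance ("fold8").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PRODUCT_PPM_THRESHOLD = 0.1
FOLD_REDUCTION_THRESHOLD = 8.0
DEFAULT_PSEUDOCOUNT_PPM = 0.01


@dataclass
class CleavageProduct:
    """One 5'-monophosphorylated RNA species.

    ``position`` is the 0-based transcript coordinate of the
    5'-monophosphate nucleotide (the 5' end of the 3' cleavage product).
    """

    transcript_id: str
    position: int
    ppm: dict[str, np.ndarray] = field(default_factory=dict)  # genotype -> per-replicate ppm
    unambiguous: bool = True


def collapse_species(
    reads: pd.DataFrame,
    transcript_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Merge per-read transcript 5' ends into species.

    Parameters
    ----------
    reads
        One row per read (or pre-counted with a ``count`` column):
        columns ``transcript_id``, ``position`` and optionally
        ``ambiguous`` (multi-mapping flag) and ``count``.
    transcript_lengths
        If given, reads at positions outside the transcript are rejected
        and logged.

    Returns
    -------
    One row per (transcript_id, position) with ``count``, ``ppm``
    (of all retained reads, ambiguous included) and ``unambiguous``
    (False if any contributing read was flagged ambiguous).
    """
    df = reads.copy()
    if "count" not in df.columns:
        df["count"] = 1
    if "ambiguous" not in df.columns:
        df["ambiguous"] = False
    if transcript_lengths is not None:
        ok = pd.Series(
            [0 <= p < transcript_lengths.get(t, -1)
             for t, p in zip(df["transcript_id"], df["position"])],
            index=df.index,
        )
        n_bad = int((~ok).sum())
        if n_bad:
            logger.info("collapse_species: rejected %d reads outside transcript bounds",
                        n_bad)
        df = df[ok]
    if df.empty:
        return pd.DataFrame(columns=["transcript_id", "position", "count", "ppm",
                                     "unambiguous"])
    grouped = (
        df.groupby(["transcript_id", "position"], as_index=False)
        .agg(count=("count", "sum"), any_ambiguous=("ambiguous", "any"))
    )
    total = grouped["count"].sum()
    grouped["ppm"] = grouped["count"] / total * 1e6
    grouped["unambiguous"] = ~grouped["any_ambiguous"]
    return grouped.drop(columns="any_ambiguous")


def passes_product_threshold(ppm: float, threshold: float = PRODUCT_PPM_THRESHOLD) -> bool:
    """Detection of a putative cleavage product in one replicate
    (>= 0.1 ppm, inclusive)."""
    return ppm >= threshold


def genotype_dependence(
    control_ppm,
    mutant_ppm,
    mode: str = "absent",
    *,
    detection_ppm: float = PRODUCT_PPM_THRESHOLD,
    fold: float = FOLD_REDUCTION_THRESHOLD,
    pseudocount_ppm: float = DEFAULT_PSEUDOCOUNT_PPM,
    strict_zero: bool = False,
) -> str:
    """Classify a cleavage product as genotype-dependent or not.

    Detection (presence) uses any-replicate >= detection_ppm; the fold
    criterion uses means across replicates, with the mutant mean floored
    at ``pseudocount_ppm`` to avoid division by zero.

    Returns
    -------
    "dependent"    detected in control and (mode "absent") undetected in
                   mutant, or (mode "fold8") mean control / mean mutant
                   >= fold.
    "independent"  detected in both genotypes (the control-target
                   criterion).
    "undetermined" undetected in control, or detected in control only but
                   short of the fold criterion.
    """
    control = np.asarray(list(control_ppm), dtype=float)
    mutant = np.asarray(list(mutant_ppm), dtype=float)
    if control.size == 0 or mutant.size == 0:
        raise ValueError("need at least one replicate per genotype")

    detected_control = bool((control >= detection_ppm).any())
    if not detected_control:
        return "undetermined"
    if strict_zero:
        detected_mutant = bool((mutant > 0).any())
    else:
        detected_mutant = bool((mutant >= detection_ppm).any())

    if mode == "absent":
        if not detected_mutant:
            return "dependent"
        return "independent"
    if mode == "fold8":
        ratio = control.mean() / max(mutant.mean(), pseudocount_ppm)
        if ratio >= fold:
            return "dependent"
        return "independent" if detected_mutant else "undetermined"
    raise ValueError(f"unknown mode {mode!r}")


def export_sites_bed(species: pd.DataFrame, path) -> None:
    """Write cleavage sites as 0-based single-nucleotide BED intervals."""
    with open(path, "w") as fh:
        for _, row in species.iterrows():
            fh.write(f"{row['transcript_id']}\t{int(row['position'])}"
                     f"\t{int(row['position']) + 1}\tcleavage\t{row['ppm']:.4f}\t+\n")
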
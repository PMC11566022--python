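"""Spike-anchored transcript quantification and two-genotype differential
abundance.

The differential test is a deliberately simple, fully specified
negative-binomial Wald contrast (NOT a DESeq2 reimplementation):

* size factors by median-of-ratios over non-spike rows;
* per-transcript method-of-moments dispersion (variance model
  mu + alpha * mu^2) with a floor of 0.01;
* log2 fold-change from size-factor-normalized group means with a
  pseudocount of 0.5;
* Wald z from the delta-method standard error, two-tailed normal p,
  Benjamini-Hochberg adjustment.

Absolute scaling (molecules/cell) comes from a regression through the
origin of known spike-in molecules on spike-in counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _ss

from pislice.stats import TestResult, bh_adjust, ks_2samp

DEFAULT_FDR = 0.01
DEFAULT_FOLD = 1.5
MIN_DISPERSION = 0.01
PSEUDOCOUNT = 0.5


@dataclass
class ExpressionMatrix:
    """Raw counts (transcripts x replicates) with spike-in annotation.

    ``spike_molecules`` maps spike row index -> known molecules added per
    library; ``genotype`` maps column -> genotype label; ``lengths`` (nt)
    enables TPM.
    """

    counts: pd.DataFrame
    spike_molecules: dict[str, float] = field(default_factory=dict)
    genotype: dict[str, str] = field(default_factory=dict)
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be >= 0")
        missing = set(self.spike_molecules) - set(self.counts.index)
        if missing:
            raise ValueError(f"spike rows absent from counts: {sorted(missing)}")

    @property
    def spike_mask(self) -> pd.Series:
        return pd.Series(self.counts.index.isin(self.spike_molecules),
                         index=self.counts.index)

    def columns_for(self, genotype: str) -> list[str]:
        return [c for c, g in self.genotype.items() if g == genotype]


def size_factors(counts: pd.DataFrame, exclude=None) -> pd.Series:
    """Median-of-ratios size factors (rows in ``exclude`` are ignored).

    Defined up to a common constant; identical libraries give all-ones.
    """
    work = counts.drop(index=list(exclude)) if exclude is not None else counts
    logs = np.log(work.where(work > 0))
    log_gm = logs.mean(axis=1)  # NaN for rows with any zero
    usable = log_gm.notna()
    if not usable.any():
        raise ValueError("no rows usable for size-factor estimation")
    ratios = logs[usable].sub(log_gm[usable], axis=0)
    return np.exp(ratios.median(axis=0))


def normalize(matrix: ExpressionMatrix) -> dict[str, pd.DataFrame]:
    """TPM over non-spike rows (sums to 1e6 per replicate) and, where
    spike-ins are present, molecules per cell from the spike regression."""
    counts = matrix.counts
    spike = matrix.spike_mask
    body = counts[~spike]
    lengths = (matrix.lengths.reindex(body.index)
               if matrix.lengths is not None
               else pd.Series(1.0, index=body.index))
    rate = body.div(lengths, axis=0)
    tpm = rate.div(rate.sum(axis=0), axis=1) * 1e6
    out = {"tpm": tpm}
    if matrix.spike_molecules:
        spikes = counts[spike]
        molecules = pd.Series(matrix.spike_molecules).reindex(spikes.index)
        slopes = {}
        for col in counts.columns:
            x = spikes[col].to_numpy(dtype=float)
            denominator = float((x ** 2).sum())
            if denominator == 0:
                raise ValueError(f"no spike reads in library {col}")
            slopes[col] = float((molecules.to_numpy() * x).sum()) / denominator
        out["molecules_per_cell"] = body.mul(pd.Series(slopes), axis=1)
    return out


def contrast(
    counts: pd.DataFrame,
    group_a,
    group_b,
    *,
    exclude=None,
    size_factor_rows=None,
    min_dispersion: float = MIN_DISPERSION,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """NB Wald contrast of group B vs group A (log2FC > 0 means higher in B).

    Requires >= 2 replicates per group.  Returns a per-transcript table
    with base means, dispersion, log2fc, p and BH-adjusted q.

    ``size_factor_rows`` restricts the median-of-ratios size-factor
    estimate to the given rows (e.g. spike-ins, which are immune to the
    composition bias a global expression shift induces in the
    all-transcript median); by default all non-excluded rows are used.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least two replicates per group")
    if size_factor_rows is not None:
        sf = size_factors(counts.loc[list(size_factor_rows), group_a + group_b])
    else:
        sf = size_factors(counts[group_a + group_b], exclude=exclude)
    norm = counts[group_a + group_b].div(sf, axis=1)
    if exclude is not None:
        norm = norm.drop(index=list(exclude))
    a, b = norm[group_a], norm[group_b]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    var_a, var_b = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)

    # method-of-moments dispersion pooled across the two groups, floored
    with np.errstate(divide="ignore", invalid="ignore"):
        mom = ((var_a + var_b) / 2 - (mean_a + mean_b) / 2) / ((mean_a + mean_b) / 2) ** 2
    dispersion = mom.clip(lower=min_dispersion).fillna(min_dispersion)

    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    var_log_a = (1.0 / (mean_a + pseudocount) + dispersion) / len(group_a)
    var_log_b = (1.0 / (mean_b + pseudocount) + dispersion) / len(group_b)
    se = np.sqrt(var_log_a + var_log_b) / np.log(2)
    z = log2fc / se
    p = 2 * _ss.norm.sf(np.abs(z))
    result = pd.DataFrame(
        {
            "base_mean_a": mean_a,
            "base_mean_b": mean_b,
            "dispersion": dispersion,
            "log2fc": log2fc,
            "se": se,
            "stat": z,
            "pvalue": p,
        },
        index=norm.index,
    )
    result["qvalue"] = bh_adjust(result["pvalue"].to_numpy())
    return result


def classify_derepression(
    result: pd.DataFrame,
    fdr: float = DEFAULT_FDR,
    fold: float = DEFAULT_FOLD,
) -> dict[str, set]:
    """Nested derepression classes: any increase > significant increase
    (q < FDR) > strong increase (additionally >= fold)."""
    increased = result.index[result["log2fc"] > 0]
    significant = result.index[(result["log2fc"] > 0) & (result["qvalue"] < fdr)]
    strong = result.index[
        (result["log2fc"] >= np.log2(fold)) & (result["qvalue"] < fdr)
    ]
    return {
        "increase": set(increased),
        "significant": set(significant),
        "strong": set(strong) & set(significant),
    }


def replicated_significant(result_allele1: pd.DataFrame, result_allele2: pd.DataFrame,
                           fdr: float = DEFAULT_FDR) -> set:
    """Changes considered only when significant in both independently
    generated mutant alleles, with consistent direction."""
    sig1 = (result_allele1["qvalue"] < fdr)
    sig2 = (result_allele2["qvalue"] < fdr)
    same_sign = np.sign(result_allele1["log2fc"]) == np.sign(
        result_allele2["log2fc"].reindex(result_allele1.index)
    )
    return set(result_allele1.index[sig1 & sig2.reindex(result_allele1.index,
                                                        fill_value=False) & same_sign])


def compare_target_vs_control_foldchange(
    result: pd.DataFrame,
    target_set,
    control_set,
) -> TestResult:
    """Two-sample KS on the log2 fold-change distributions of targets vs
    control targets."""
    targets = result.loc[result.index.intersection(set(target_set)), "log2fc"]
    controls = result.loc[result.index.intersection(set(control_set)), "log2fc"]
    if len(targets) == 0 or len(controls) == 0:
        raise ValueError("target and control sets must be non-empty")
    return ks_2samp(targets.to_numpy(), controls.to_numpy())
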
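"""Target calling: which piRNA explains which cleavage product.

For every (prefix group, cleavage product) pair the guide is aligned at
the product's 5' end under the g10 register and scored against the
abundance-tiered pairing rules.  Candidate calls are then filtered:

* exclusivity — no guide from outside the focal loci is itself callable
  at the same site;
* genotype dependence — the 3' cleavage product is present in control
  but lost in the slicer-deficient genotype.

A call passing both filters is high confidence.  Control targets are the
complementary set used for distribution-level comparisons: sites called
for non-focal, biogenesis-independent guides whose product is detected
in both genotypes.  Because replicate pairing is arbitrary, target counts
are summarized over all control x mutant replicate pairings
(4 x 4 = 16 permutations by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from pislice.pairing import (
    DEFAULT_TIERS,
    TierRule,
    align_guide_at_site,
    duplex_delta_g,
    satisfies_tier,
)


def scan_transcriptome(
    guides: pd.DataFrame,
    products: pd.DataFrame,
    transcripts: dict[str, str],
    *,
    tiers: tuple[TierRule, ...] = DEFAULT_TIERS,
    allow_wobble: bool = False,
    annotate_delta_g: bool = False,
) -> pd.DataFrame:
    """Align every guide at every cleavage product and keep callable pairs.

    Parameters
    ----------
    guides
        One row per prefix group: columns ``guide_id``, ``sequence``
        (representative full-length member), ``locus``, ``ppm``
        (abundance used for the tier preconditions, e.g. mean control ppm).
    products
        One row per cleavage product passing the detection threshold:
        columns ``transcript_id``, ``position``.
    transcripts
        transcript_id -> sequence.

    Returns
    -------
    Candidate calls: one row per callable (guide, site) pair with the
    satisfied rule names and, optionally, the duplex free energy.
    """
    rows = []
    for t_id, pos in zip(products["transcript_id"], products["position"]):
        if t_id not in transcripts:
            raise KeyError(f"product transcript {t_id!r} not in transcript set")
        seq = transcripts[t_id]
        for g_id, g_seq, locus, ppm in zip(
            guides["guide_id"], guides["sequence"], guides["locus"], guides["ppm"]
        ):
            pairing = align_guide_at_site(g_seq, seq, int(pos),
                                          allow_wobble=allow_wobble)
            verdict = satisfies_tier(pairing, float(ppm), tiers)
            if verdict.callable:
                row = {
                    "guide_id": g_id,
                    "locus": locus,
                    "transcript_id": t_id,
                    "position": int(pos),
                    "rules": ",".join(sorted(verdict.satisfied_rules)),
                }
                if annotate_delta_g:
                    row["delta_g"] = duplex_delta_g(g_seq, pairing)
                rows.append(row)
    columns = ["guide_id", "locus", "transcript_id", "position", "rules"]
    if annotate_delta_g:
        columns.append("delta_g")
    return pd.DataFrame(rows, columns=columns)


def exclusivity_filter(candidates: pd.DataFrame, focal_loci) -> pd.DataFrame:
    """Flag focal-locus candidates whose site no non-focal guide can explain.

    ``candidates`` must contain all callable pairs (focal and non-focal);
    the abundance precondition has already been applied during scanning,
    so a non-focal guide with sufficient geometry but insufficient
    abundance does not break exclusivity.
    """
    focal_loci = set(focal_loci)
    if candidates.empty:
        out = candidates.copy()
        out["exclusive"] = pd.Series(dtype=bool)
        return out
    nonfocal_sites = {
        (t, p)
        for t, p, locus in zip(candidates["transcript_id"], candidates["position"],
                               candidates["locus"])
        if locus not in focal_loci
    }
    out = candidates[candidates["locus"].isin(focal_loci)].copy()
    out["exclusive"] = [
        (t, p) not in nonfocal_sites
        for t, p in zip(out["transcript_id"], out["position"])
    ]
    return out


def call_high_confidence(
    candidates: pd.DataFrame,
    dependence: dict[tuple[str, int], str],
    focal_loci,
) -> pd.DataFrame:
    """Combine exclusivity and genotype dependence into confidence classes.

    ``dependence`` maps (transcript_id, position) to the
    :func:`pislice.degradome.genotype_dependence` verdict.  Confidence is
    "high" iff the call is exclusive and its product is genotype-dependent;
    all other callable focal pairs are "candidate".
    """
    calls = exclusivity_filter(candidates, focal_loci)
    calls["genotype_dependent"] = [
        dependence.get((t, p)) == "dependent"
        for t, p in zip(calls["transcript_id"], calls["position"])
    ]
    calls["confidence"] = np.where(
        calls["exclusive"] & calls["genotype_dependent"], "high", "candidate"
    )
    return calls


def call_control_targets(
    candidates: pd.DataFrame,
    dependence: dict[tuple[str, int], str],
    focal_loci,
    biogenesis_dependent_guides=(),
) -> pd.DataFrame:
    """Control-target set: non-focal, biogenesis-independent guides whose
    callable site has a product detected in both genotypes."""
    focal_loci = set(focal_loci)
    dependent_guides = set(biogenesis_dependent_guides)
    if candidates.empty:
        return candidates.copy()
    detected_both = np.array([
        dependence.get((t, p)) == "independent"
        for t, p in zip(candidates["transcript_id"], candidates["position"])
    ])
    keep = (
        ~candidates["locus"].isin(focal_loci)
        & ~candidates["guide_id"].isin(dependent_guides)
        & detected_both
    )
    return candidates[keep].copy()


@dataclass
class PermutationSummary:
    counts: list[int]
    median: float
    iqr: tuple[float, float]

    @property
    def iqr_width(self) -> float:
        return self.iqr[1] - self.iqr[0]


def permutation_summary(control_replicates, mutant_replicates, caller) -> PermutationSummary:
    """Run ``caller(control_rep, mutant_rep) -> count`` on every pairing of
    one control with one mutant replicate and summarize the counts."""
    counts = [
        int(caller(c, m)) for c in control_replicates for m in mutant_replicates
    ]
    if not counts:
        raise ValueError("need at least one replicate per genotype")
    q1, q3 = np.percentile(counts, [25, 75])
    return PermutationSummary(counts, float(np.median(counts)), (float(q1), float(q3)))
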
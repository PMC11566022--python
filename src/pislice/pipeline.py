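"""End-to-end orchestration: simulate -> quantify -> call -> contrast.

``run_all`` executes the whole analysis on a synthetic world and returns a
report with the headline quantities: high-confidence target count (median
and IQR over all control x mutant replicate pairings), the fraction of
focal guides with at least one target, the transcriptome-wide
extrapolation, and the distribution-level contrasts (derepression KS,
translation KS, GRO-seq Mann-Whitney).  All thresholds default to the
pipeline's standard values (1 ppm guide detection, 0.1 ppm products,
8-fold reduction, FDR 0.01, 1.5-fold, 1.25-fold, 10 TPM, 500 bp).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from pislice import contrast as xc
from pislice import degradome as dg
from pislice import groseq as gs
from pislice import smallrna as sr
from pislice import targets as tg
from pislice import translation as tl
from pislice.simulate import SimConfig, SyntheticWorld, generate_world

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    guide_min_ppm: float = 1.0
    product_min_ppm: float = 0.1
    fold_reduction: float = 8.0
    fdr: float = 0.01
    fold_class: float = 1.5
    groseq_fold: float = 1.25
    min_occupancy_tpm: float = 10.0
    dependence_mode: str = "absent"

    def __post_init__(self) -> None:
        for name in ("guide_min_ppm", "product_min_ppm", "fold_reduction",
                     "fdr", "fold_class", "groseq_fold", "min_occupancy_tpm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not self.sim.focal_loci:
            raise ValueError("focal loci must be non-empty for target calling")


def extrapolate_targets(count: float, focal_fraction: float, round_to: int = 10) -> float:
    """Transcriptome-wide target estimate: observed count / fraction of all
    piRNAs produced by the focal loci, rounded to the nearest ``round_to``
    (112 targets at a 0.135 focal fraction extrapolate to ~830)."""
    if not 0 < focal_fraction <= 1:
        raise ValueError("focal fraction must be in (0, 1]")
    if count == 0:
        return 0.0
    value = count / focal_fraction
    return float(round(value / round_to) * round_to) if round_to else float(value)


def fraction_of_guides_with_targets(n_guides_with_targets: int, n_focal_guides: int) -> float:
    if n_focal_guides <= 0:
        raise ValueError("need a positive focal guide count")
    return n_guides_with_targets / n_focal_guides


def run_all(config: RunConfig, world: SyntheticWorld | None = None) -> dict:
    """Run the full pipeline; identical config (and seed) gives an
    identical report."""
    if world is None:
        world = generate_world(config.sim)
    focal = set(config.sim.focal_loci)
    report: dict = {"config": {"sim": asdict(config.sim),
                               **{k: v for k, v in asdict(config).items() if k != "sim"}},
                    "stages": {}}

    # --- small RNA quantification ----------------------------------------
    guides_all = world.guides_table("control")
    control_ppm = world.smallrna_ppm["control"]
    detected = (control_ppm >= config.guide_min_ppm).all(axis=1)
    guides = guides_all[detected.reindex(guides_all["guide_id"]).to_numpy()]
    report["stages"]["smallrna"] = {
        "n_guides_total": int(len(guides_all)),
        "n_guides_detected": int(len(guides)),
    }

    # --- degradome species and genotype dependence ------------------------
    deg_c = world.degradome_ppm["control"]
    deg_m = world.degradome_ppm["knockout"]
    mean_detected = deg_c.mean(axis=1) >= config.product_min_ppm
    products = deg_c[mean_detected]
    dependence = {
        site: dg.genotype_dependence(
            deg_c.loc[[site]].to_numpy().ravel(),
            deg_m.loc[[site]].to_numpy().ravel(),
            mode=config.dependence_mode,
            detection_ppm=config.product_min_ppm,
            fold=config.fold_reduction,
        )
        for site in products.index
    }
    report["stages"]["degradome"] = {
        "n_species": int(len(deg_c)),
        "n_products_detected": int(len(products)),
    }

    # --- candidate scan (replicate-independent) ---------------------------
    products_df = products.index.to_frame(index=False)
    candidates = tg.scan_transcriptome(guides, products_df,
                                       world.transcript_sequences)
    high = tg.call_high_confidence(candidates, dependence, focal)
    high_set = high[high["confidence"] == "high"]
    controls = tg.call_control_targets(
        candidates, dependence, focal,
        biogenesis_dependent_guides=world.pirnas.loc[
            world.pirnas["biogenesis_dependent"], "guide_id"
        ],
    )

    # --- permutation summary over replicate pairings ----------------------
    exclusive = high[high["exclusive"]]
    candidate_sites = sorted(set(zip(exclusive["transcript_id"],
                                     exclusive["position"])))
    site_index = pd.MultiIndex.from_tuples(candidate_sites,
                                           names=["transcript_id", "position"]) \
        if candidate_sites else deg_c.index[:0]
    cand_c = deg_c.reindex(site_index)
    cand_m = deg_m.reindex(site_index)

    def _count_for_pair(c_rep: str, m_rep: str) -> int:
        return int(((cand_c[c_rep] >= config.product_min_ppm)
                    & (cand_m[m_rep] < config.product_min_ppm)).sum())

    reps = list(deg_c.columns)
    perm = tg.permutation_summary(reps, reps, _count_for_pair)

    focal_guide_ids = set(world.pirnas.loc[world.pirnas["locus"].isin(focal),
                                           "guide_id"])
    n_with_targets = high_set["guide_id"].nunique()
    mean_ppm = world.smallrna_ppm["control"].mean(axis=1)
    locus_of = world.pirnas.set_index("guide_id")["locus"]
    focal_mask = locus_of.reindex(mean_ppm.index).isin(focal)
    focal_ppm_fraction = float(mean_ppm[focal_mask].sum() / mean_ppm.sum())
    report["stages"]["target_calling"] = {
        "n_candidates": int(len(candidates)),
        "n_high_confidence": int(len(high_set)),
        "n_control_targets": int(len(controls)),
        "permutation_counts": perm.counts,
        "permutation_median": perm.median,
        "permutation_iqr": list(perm.iqr),
        "n_focal_guides": len(focal_guide_ids),
        "n_guides_with_target": int(n_with_targets),
        "fraction_guides_with_target": fraction_of_guides_with_targets(
            int(n_with_targets), len(focal_guide_ids)),
        "focal_ppm_fraction": focal_ppm_fraction,
        "extrapolated_total_targets": extrapolate_targets(
            perm.median, focal_ppm_fraction),
    }

    # --- steady-state derepression contrast -------------------------------
    counts = pd.concat(
        [world.rnaseq_counts["control"].add_prefix("control_"),
         world.rnaseq_counts["knockout"].add_prefix("knockout_")],
        axis=1,
    )
    result = xc.contrast(
        counts,
        [c for c in counts.columns if c.startswith("control_")],
        [c for c in counts.columns if c.startswith("knockout_")],
        exclude=list(world.rnaseq_spike_molecules),
        size_factor_rows=list(world.rnaseq_spike_molecules),
    )
    classes = xc.classify_derepression(result, fdr=config.fdr, fold=config.fold_class)
    target_tx = set(high_set["transcript_id"])
    control_tx = set(controls["transcript_id"]) - target_tx
    ks = (xc.compare_target_vs_control_foldchange(result, target_tx, control_tx)
          if target_tx and control_tx else None)
    report["stages"]["expression"] = {
        "n_increase": len(classes["increase"] & target_tx),
        "n_significant": len(classes["significant"] & target_tx),
        "n_strong": len(classes["strong"] & target_tx),
        "ks_statistic": None if ks is None else ks.statistic,
        "ks_pvalue": None if ks is None else ks.pvalue,
    }

    # --- translational efficiency ------------------------------------------
    def _tpm(df: pd.DataFrame) -> pd.Series:
        mean = df.mean(axis=1)
        return mean / mean.sum() * 1e6

    te_control = tl.compute_te(_tpm(world.polya_counts["control"]),
                               _tpm(world.ribo_counts["control"]),
                               min_occupancy=config.min_occupancy_tpm)
    te_mutant = tl.compute_te(
        _tpm(world.polya_counts["knockout"]),
        _tpm(world.ribo_counts["knockout"]),
        min_occupancy=config.min_occupancy_tpm,
        occupancy_filter_values=_tpm(world.ribo_counts["control"]),
    )
    dte = tl.delta_te(te_mutant, te_control)
    te_targets = dte.index.intersection(target_tx)
    te_controls = dte.index.intersection(control_tx)
    te_ks = (tl.test_activation_model(dte, te_targets, te_controls)
             if len(te_targets) and len(te_controls) else None)
    report["stages"]["translation"] = {
        "n_genes": int(len(dte)),
        "ks_statistic": None if te_ks is None else te_ks.statistic,
        "ks_pvalue": None if te_ks is None else te_ks.pvalue,
    }

    # --- GRO-seq transcription-rate comparison -----------------------------
    lengths = pd.Series({t: len(seq) for t, seq in world.transcript_sequences.items()})
    densities = gs.density_table(world.groseq_counts, lengths)
    split = gs.split_by_fold_change(result["log2fc"], target_tx,
                                    boundary=config.groseq_fold)
    groseq_stage: dict = {"n_le": len(split["le"]), "n_ge": len(split["ge"])}
    if split["le"] and split["ge"]:
        cmp = gs.compare_classes(densities, split["le"], split["ge"])
        groseq_stage.update({
            "median_le": cmp["class_a"]["median"],
            "median_ge": cmp["class_b"]["median"],
            "mw_pvalue": cmp["test"].pvalue,
        })
    if target_tx and control_tx:
        cmp_tc = gs.compare_classes(densities, target_tx, control_tx)
        groseq_stage.update({
            "median_targets": cmp_tc["class_a"]["median"],
            "median_controls": cmp_tc["class_b"]["median"],
            "mw_pvalue_targets_vs_controls": cmp_tc["test"].pvalue,
        })
    report["stages"]["groseq"] = groseq_stage

    # --- recovery vs planted truth -----------------------------------------
    truth_focal = world.truth_targets[world.truth_targets["kind"] == "focal"]
    truth_sites = set(zip(truth_focal["transcript_id"], truth_focal["position"]))
    called_sites = set(zip(high_set["transcript_id"], high_set["position"]))
    tp = len(called_sites & truth_sites)
    report["stages"]["recovery"] = {
        "n_planted": len(truth_sites),
        "n_called": len(called_sites),
        "precision": tp / len(called_sites) if called_sites else float("nan"),
        "recall": tp / len(truth_sites) if truth_sites else float("nan"),
    }
    return report
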
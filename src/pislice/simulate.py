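"""Self-contained synthetic study with planted piRNA targets.

Generates two genotypes (control and a double-knockout of the focal piRNA
loci) x replicates of every assay table the pipeline consumes, from a
minimal mechanistic model:

* transcript steady state follows first-order kinetics,
  ``ss = k_tx / (k_dec + k_slice)`` in control and ``k_tx / k_dec`` in the
  knockout (slicing removed), so the planted knockout/control fold-change
  is ``1 + k_slice / k_dec``;
* piRNA abundance across loci is log-normal on the ppm scale (the
  empirical distribution is unknown beyond its 0.01-10 nM range, so the
  parameters are exposed in the config);
* degradome abundance of a planted 3' cleavage product is proportional to
  ``k_slice x steady state``; every transcript also sheds one generic
  5'-monophosphate decay species (proportional to ``k_dec x steady
  state``) and a configurable rate of low-abundance background species, so
  the 0.1-ppm product threshold is non-trivial;
* GRO-seq signal is proportional to ``k_tx`` per kb of gene body with
  Poisson noise (polymerase density as a transcription-rate proxy);
* all count tables draw negative-binomial noise around expected
  proportions; small-RNA reads carry 9+9-nt terminal UMIs and an
  equimolar set of nine spike-in oligonucleotides of known molecule
  counts anchors absolute quantification.

Planted target sites satisfy exactly the requested pairing-tier geometry
by construction, and guides from the knocked-out loci (plus guides whose
biogenesis depends on them) have zero reads in the knockout genotype.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from pislice.pairing import DEFAULT_TIERS, align_guide_at_site, satisfies_tier
from pislice.sequences import Transcript, complement
from pislice.smallrna import SpikeIn, SpikeInSet, UMI_LEN

BASES = np.array(list("ACGT"))

#: paired guide positions planted for each tier rule.  Each pattern
#: satisfies its own tier geometry and is minimal for it: R1 plants exactly
#: 20 paired positions in g2-g25 broken so no contiguous window holds; R2-R4
#: plant only their contiguous window, with the flanking position mismatched
#: so the next-larger window fails.  (R3's window contains R2's, so an R3
#: site necessarily satisfies R2 geometry as well; the rules are nested as
#: printed.)
TIER_PATTERNS = {
    "R1": frozenset(range(2, 12)) | frozenset(range(15, 25)),
    "R2": frozenset(range(3, 16)),
    "R3": frozenset(range(3, 17)),
    "R4": frozenset(range(4, 18)),
}


class ConfigurationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions of the synthetic world.

    Rates are per hour; ``k_slice`` applies only to planted targets.
    ``cell_volume_um3`` (1,800, the median primary spermatocyte volume) and
    ``total_pirnas_per_cell`` (1e7) are the constants used for the
    ppm <-> molecules <-> pM conversions.
    """

    seed: int = 1
    n_transcripts: int = 240
    transcript_length_range: tuple[int, int] = (900, 2100)
    n_loci: int = 8
    n_pirnas_per_locus: int = 25
    pirna_logppm_mean: float = math.log(5.0)
    pirna_logppm_sigma: float = 1.2
    frac_planted_targets: float = 0.25
    frac_control_targets: float = 0.15
    tier_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    k_tx_range: tuple[float, float] = (5.0, 500.0)
    k_dec_range: tuple[float, float] = (0.1, 1.0)
    k_slice_range: tuple[float, float] = (0.1, 1.0)
    nb_dispersion: float = 0.05
    depth: int = 1_000_000
    degradome_depth: int = 20_000_000
    smallrna_depth: int = 2_000_000
    groseq_depth: int = 2_000_000
    n_replicates: int = 4
    n_groseq_replicates: int = 3
    n_spikes: int = 9
    spike_length: int = 30
    spike_molecules: float = 5000.0
    rnaseq_spike_molecules: float = 500.0
    background_products_per_transcript: float = 2.0
    background_ppm_logmean: float = math.log(0.12)
    background_ppm_logsigma: float = 1.0
    frac_biogenesis_dependent: float = 0.1
    repeat_fraction: float = 0.17
    te_logsigma: float = 0.2
    focal_loci: tuple[str, str] = ("pi9", "pi17")
    cell_volume_um3: float = 1800.0
    total_pirnas_per_cell: float = 1e7

    def __post_init__(self) -> None:
        if self.depth <= 0 or self.degradome_depth <= 0 or self.smallrna_depth <= 0:
            raise ConfigurationError("library depths must be > 0")
        for name in ("k_tx_range", "k_dec_range", "k_slice_range"):
            low, high = getattr(self, name)
            if low <= 0 or high < low:
                raise ConfigurationError(f"{name} must be positive and ordered")
        if not math.isclose(sum(self.tier_mix), 1.0, abs_tol=1e-9):
            raise ConfigurationError("tier_mix must sum to 1")
        if not 0 <= self.frac_planted_targets <= 1:
            raise ConfigurationError("frac_planted_targets must be in [0, 1]")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        if self.n_replicates < 1:
            raise ConfigurationError("need at least one replicate per genotype")

    @property
    def locus_names(self) -> list[str]:
        others = [f"locus{i}" for i in range(3, self.n_loci + 1)]
        return list(self.focal_loci) + others


@dataclass
class SyntheticWorld:
    """Planted ground truth plus all simulated assay tables."""

    config: SimConfig
    transcripts: dict[str, Transcript]
    pirnas: pd.DataFrame
    truth_targets: pd.DataFrame
    rates: pd.DataFrame
    smallrna_counts: dict[str, pd.DataFrame]
    smallrna_ppm: dict[str, pd.DataFrame]
    degradome_ppm: dict[str, pd.DataFrame]
    rnaseq_counts: dict[str, pd.DataFrame]
    polya_counts: dict[str, pd.DataFrame]
    ribo_counts: dict[str, pd.DataFrame]
    groseq_counts: pd.DataFrame
    spike_set: SpikeInSet
    rnaseq_spike_molecules: dict[str, float] = field(default_factory=dict)

    @property
    def transcript_sequences(self) -> dict[str, str]:
        return {t_id: t.sequence for t_id, t in self.transcripts.items()}

    def guides_table(self, genotype: str = "control") -> pd.DataFrame:
        """Per-guide table with measured mean ppm in ``genotype`` — the
        abundance input to the tier rules."""
        ppm = self.smallrna_ppm[genotype].mean(axis=1)
        df = self.pirnas.copy()
        df["ppm"] = ppm.reindex(df["guide_id"]).to_numpy()
        return df


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def _nb_counts(rng: np.random.Generator, mean, dispersion: float) -> np.ndarray:
    """Negative-binomial draw with variance mean + dispersion * mean^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + np.maximum(mean, 1e-300))
    return rng.negative_binomial(r, p)


def plant_target_site(
    guide: str,
    transcript_seq: str,
    tier: str,
    rng: np.random.Generator,
    position: int | None = None,
) -> tuple[str, int]:
    """Write a site into the transcript that the guide explains under
    exactly the requested tier's geometry.

    Returns the modified sequence and the 0-based coordinate of the
    3'-product 5' end (the base paired to g10).  Positions g1-g30 outside
    the tier's paired pattern are set to the guide's own base, which can
    never be its Watson-Crick complement (nor a G:U wobble), so stricter
    windows fail where the pattern dictates.
    """
    if tier not in TIER_PATTERNS:
        raise ValueError(f"unknown tier {tier!r}")
    n = len(transcript_seq)
    if n < 30:
        raise ValueError("transcript too short for a 30-nt site")
    if position is None:
        position = int(rng.integers(20, n - 10))
    if position - 20 < 0 or position + 10 > n:
        raise ValueError("site would extend beyond the transcript")
    seq = list(transcript_seq)
    paired = TIER_PATTERNS[tier]
    for k in range(1, 31):
        if k > len(guide):
            break
        t = position + 10 - k
        gb = guide[k - 1]
        seq[t] = complement(gb) if k in paired else gb
    return "".join(seq), position


def _proportional_counts(
    rng: np.random.Generator,
    weights: np.ndarray,
    depth: int,
    dispersion: float,
    n_replicates: int,
) -> np.ndarray:
    """Replicate count columns, NB around depth-scaled proportions."""
    weights = np.asarray(weights, dtype=float)
    props = weights / weights.sum()
    return np.column_stack(
        [_nb_counts(rng, depth * props, dispersion) for _ in range(n_replicates)]
    )


def generate_world(config: SimConfig) -> SyntheticWorld:
    """Build the complete synthetic study for one configuration.

    The same config always yields the same world (single seeded RNG,
    consumed in a fixed order).
    """
    rng = np.random.default_rng(config.seed)
    reps = [f"rep{i + 1}" for i in range(config.n_replicates)]

    # --- transcripts with 5'UTR / CDS / 3'UTR annotation -----------------
    transcripts: dict[str, Transcript] = {}
    for i in range(config.n_transcripts):
        length = int(rng.integers(*config.transcript_length_range))
        seq = _random_seq(rng, length)
        u5 = int(0.1 * length)
        cds_end = int(0.7 * length)
        transcripts[f"tx{i:04d}"] = Transcript(
            f"tx{i:04d}", seq,
            {"5UTR": (0, u5), "CDS": (u5, cds_end), "3UTR": (cds_end, length)},
        )
    tx_ids = list(transcripts)

    # --- piRNA population -------------------------------------------------
    guide_rows = []
    for locus in config.locus_names:
        focal = locus in config.focal_loci
        for j in range(config.n_pirnas_per_locus):
            g_id = f"{locus}_g{j:03d}"
            length = int(rng.integers(26, 31))
            guide_rows.append({
                "guide_id": g_id,
                "locus": locus,
                "sequence": _random_seq(rng, length),
                "ppm_true": float(rng.lognormal(config.pirna_logppm_mean,
                                                config.pirna_logppm_sigma)),
                "repeat_derived": bool(rng.random() < config.repeat_fraction),
                "biogenesis_dependent": bool(
                    (not focal) and rng.random() < config.frac_biogenesis_dependent
                ),
            })
    pirnas = pd.DataFrame(guide_rows)
    focal_guides = pirnas.index[pirnas["locus"].isin(config.focal_loci)]
    control_guides = pirnas.index[
        ~pirnas["locus"].isin(config.focal_loci) & ~pirnas["biogenesis_dependent"]
    ]

    # --- plant target sites ----------------------------------------------
    tier_names = [rule.name for rule in DEFAULT_TIERS]
    tier_thresholds = {rule.name: rule.min_ppm for rule in DEFAULT_TIERS}
    n_focal = round(config.frac_planted_targets * config.n_transcripts)
    n_ctrl = round(config.frac_control_targets * config.n_transcripts)
    chosen = rng.choice(len(tx_ids), size=n_focal + n_ctrl, replace=False)
    truth_rows = []
    for rank, tx_index in enumerate(chosen):
        kind = "focal" if rank < n_focal else "control"
        pool = focal_guides if kind == "focal" else control_guides
        g_idx = int(rng.choice(pool))
        tier = str(rng.choice(tier_names, p=config.tier_mix))
        # the guide must clear its tier's abundance precondition with margin
        if pirnas.at[g_idx, "ppm_true"] < 1.5 * tier_thresholds[tier]:
            pirnas.at[g_idx, "ppm_true"] = tier_thresholds[tier] * float(
                rng.uniform(1.5, 3.0)
            )
        t_id = tx_ids[tx_index]
        transcript = transcripts[t_id]
        u5_end = transcript.regions["5UTR"][1]
        position = int(rng.integers(max(20, u5_end), len(transcript) - 10))
        new_seq, position = plant_target_site(
            pirnas.at[g_idx, "sequence"], transcript.sequence, tier, rng, position
        )
        transcripts[t_id] = Transcript(t_id, new_seq, transcript.regions)
        # generator/verifier closure: the planted site must pass its tier
        pairing = align_guide_at_site(pirnas.at[g_idx, "sequence"], new_seq, position)
        verdict = satisfies_tier(pairing, pirnas.at[g_idx, "ppm_true"])
        assert tier in verdict.satisfied_rules, "planted site failed its own tier"
        truth_rows.append({
            "guide_id": pirnas.at[g_idx, "guide_id"],
            "locus": pirnas.at[g_idx, "locus"],
            "transcript_id": t_id,
            "position": position,
            "tier": tier,
            "kind": kind,
        })
    truth = pd.DataFrame(truth_rows, columns=["guide_id", "locus", "transcript_id",
                                              "position", "tier", "kind"])

    # --- kinetic rates and steady states ---------------------------------
    def _loguniform(low: float, high: float, size: int) -> np.ndarray:
        return np.exp(rng.uniform(math.log(low), math.log(high), size=size))

    k_tx = _loguniform(*config.k_tx_range, config.n_transcripts)
    k_dec = _loguniform(*config.k_dec_range, config.n_transcripts)
    k_slice = np.zeros(config.n_transcripts)
    sliced = truth["transcript_id"].map({t: i for i, t in enumerate(tx_ids)})
    k_slice[sliced.to_numpy()] = _loguniform(*config.k_slice_range, len(truth))
    is_focal_target = np.zeros(config.n_transcripts, dtype=bool)
    is_focal_target[sliced[truth["kind"] == "focal"].to_numpy()] = True

    ss_control = k_tx / (k_dec + k_slice)
    # knockout removes slicing only where the guide came from a focal locus
    k_slice_ko = np.where(is_focal_target, 0.0, k_slice)
    ss_knockout = k_tx / (k_dec + k_slice_ko)
    rates = pd.DataFrame(
        {"k_tx": k_tx, "k_dec": k_dec, "k_slice": k_slice,
         "ss_control": ss_control, "ss_knockout": ss_knockout},
        index=tx_ids,
    )

    # --- RNA-seq / poly(A)+ / ribosome-footprint count tables -------------
    spike_ids = [f"spike{i + 1}" for i in range(config.n_spikes)]
    rnaseq_spike_molecules = {s: config.rnaseq_spike_molecules for s in spike_ids}
    te = np.exp(rng.normal(0.0, config.te_logsigma, size=config.n_transcripts))
    ss = {"control": ss_control, "knockout": ss_knockout}

    rnaseq_counts, polya_counts, ribo_counts = {}, {}, {}
    for genotype in ("control", "knockout"):
        w = np.concatenate([ss[genotype],
                            np.full(config.n_spikes, config.rnaseq_spike_molecules)])
        rnaseq_counts[genotype] = pd.DataFrame(
            _proportional_counts(rng, w, config.depth, config.nb_dispersion,
                                 config.n_replicates),
            index=tx_ids + spike_ids, columns=reps,
        )
        polya_counts[genotype] = pd.DataFrame(
            _proportional_counts(rng, ss[genotype], config.depth,
                                 config.nb_dispersion, config.n_replicates),
            index=tx_ids, columns=reps,
        )
        ribo_counts[genotype] = pd.DataFrame(
            _proportional_counts(rng, te * ss[genotype], config.depth,
                                 config.nb_dispersion, config.n_replicates),
            index=tx_ids, columns=reps,
        )

    # --- degradome (5'-monophosphate species) -----------------------------
    species = []  # (transcript_id, position, weight_control, weight_knockout)
    for row, tx_index in zip(truth.itertuples(), sliced.to_numpy()):
        w_ctrl = k_slice[tx_index] * ss_control[tx_index]
        w_ko = 0.0 if row.kind == "focal" else k_slice[tx_index] * ss_knockout[tx_index]
        species.append((row.transcript_id, row.position, w_ctrl, w_ko))
    used_sites = {(s[0], s[1]) for s in species}

    def _fresh_position(t_id: str) -> int:
        while True:  # distinct (transcript, position) keys per species
            pos = int(rng.integers(0, len(transcripts[t_id])))
            if (t_id, pos) not in used_sites:
                used_sites.add((t_id, pos))
                return pos

    # generic decay species: one per transcript, genotype-proportional
    for i, t_id in enumerate(tx_ids):
        species.append((t_id, _fresh_position(t_id),
                        k_dec[i] * ss_control[i], k_dec[i] * ss_knockout[i]))
    main_total = sum(s[2] for s in species)
    # low-abundance background species around the 0.1-ppm threshold
    n_bg = rng.poisson(config.background_products_per_transcript,
                       size=config.n_transcripts)
    for i, t_id in enumerate(tx_ids):
        for _ in range(int(n_bg[i])):
            ppm_intent = rng.lognormal(config.background_ppm_logmean,
                                       config.background_ppm_logsigma)
            w = ppm_intent / 1e6 * main_total
            species.append((t_id, _fresh_position(t_id), w, w))
    deg_index = pd.MultiIndex.from_tuples(
        [(s[0], s[1]) for s in species], names=["transcript_id", "position"]
    )
    degradome_ppm = {}
    for genotype, col in (("control", 2), ("knockout", 3)):
        w = np.array([s[col] for s in species])
        counts = _proportional_counts(rng, w, config.degradome_depth,
                                      config.nb_dispersion, config.n_replicates)
        ppm = counts / counts.sum(axis=0, keepdims=True) * 1e6
        degradome_ppm[genotype] = pd.DataFrame(ppm, index=deg_index, columns=reps)

    # --- small RNA --------------------------------------------------------
    spike_seqs = [_random_seq(rng, config.spike_length) for _ in range(config.n_spikes)]
    spike_set = SpikeInSet(tuple(
        SpikeIn(s_id, seq, config.spike_molecules)
        for s_id, seq in zip(spike_ids, spike_seqs)
    ))
    # molecules: ppm_true maps to molecules/cell via the per-cell total
    guide_molecules = pirnas["ppm_true"].to_numpy() * config.total_pirnas_per_cell * 1e-6
    other_molecules = max(config.total_pirnas_per_cell - guide_molecules.sum(), 0.0)
    absent_in_ko = (
        pirnas["locus"].isin(config.focal_loci) | pirnas["biogenesis_dependent"]
    ).to_numpy()
    smallrna_counts, smallrna_ppm = {}, {}
    sr_index = list(pirnas["guide_id"]) + spike_ids + ["__other__"]
    for genotype in ("control", "knockout"):
        gm = guide_molecules.copy()
        if genotype == "knockout":
            gm[absent_in_ko] = 0.0
        w = np.concatenate([gm,
                            np.full(config.n_spikes, config.spike_molecules),
                            [other_molecules]])
        counts = _proportional_counts(rng, w, config.smallrna_depth,
                                      config.nb_dispersion, config.n_replicates)
        table = pd.DataFrame(counts, index=sr_index, columns=reps)
        smallrna_counts[genotype] = table
        nonspike = table.drop(index=spike_ids)
        ppm = nonspike / nonspike.sum(axis=0) * 1e6
        smallrna_ppm[genotype] = ppm.drop(index="__other__")

    # --- GRO-seq (control genotype) ---------------------------------------
    lengths = np.array([len(transcripts[t]) for t in tx_ids])
    body_kb = np.maximum(lengths - 500, 0) / 1000.0
    w = k_tx * body_kb
    props = w / w.sum()
    groseq = pd.DataFrame(
        np.column_stack([
            rng.poisson(config.groseq_depth * props)
            for _ in range(config.n_groseq_replicates)
        ]),
        index=tx_ids,
        columns=[f"rep{i + 1}" for i in range(config.n_groseq_replicates)],
    )

    return SyntheticWorld(
        config=config,
        transcripts=transcripts,
        pirnas=pirnas,
        truth_targets=truth,
        rates=rates,
        smallrna_counts=smallrna_counts,
        smallrna_ppm=smallrna_ppm,
        degradome_ppm=degradome_ppm,
        rnaseq_counts=rnaseq_counts,
        polya_counts=polya_counts,
        ribo_counts=ribo_counts,
        groseq_counts=groseq,
        spike_set=spike_set,
        rnaseq_spike_molecules=rnaseq_spike_molecules,
    )


def emit_reads(
    world: SyntheticWorld,
    assay: str,
    out_dir,
    n_reads: int = 10_000,
) -> list:
    """Write assay files for one world.

    ``smallrna`` samples a FASTQ of UMI-flanked inserts (guides plus
    spike-ins, control genotype expectations); the other assays write TSV
    count tables; ``fasta``/``bed``/``truth`` export the reference.  Files
    are deterministic for a fixed config.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(world.config.seed + 987_654)
    written = []

    def _write_table(df: pd.DataFrame, name: str) -> None:
        path = out_dir / name
        df.to_csv(path, sep="\t")
        written.append(path)

    if assay == "smallrna":
        gm = world.pirnas["ppm_true"].to_numpy() * world.config.total_pirnas_per_cell * 1e-6
        inserts = list(world.pirnas["sequence"]) + [
            e.sequence for e in world.spike_set.entries
        ]
        weights = np.concatenate([gm, [e.molecules_added for e in world.spike_set.entries]])
        draws = rng.choice(len(inserts), size=n_reads, p=weights / weights.sum())
        path = out_dir / "smallrna.fastq"
        with open(path, "w") as fh:
            for i, j in enumerate(draws):
                umi5 = _random_seq(rng, UMI_LEN)
                umi3 = _random_seq(rng, UMI_LEN)
                read = umi5 + inserts[j] + umi3
                fh.write(f"@read{i}\n{read}\n+\n{'I' * len(read)}\n")
        written.append(path)
    elif assay == "degradome":
        for genotype, df in world.degradome_ppm.items():
            _write_table(df, f"degradome_ppm_{genotype}.tsv")
    elif assay == "rnaseq":
        for genotype, df in world.rnaseq_counts.items():
            _write_table(df, f"rnaseq_counts_{genotype}.tsv")
    elif assay == "ribo":
        for genotype in world.ribo_counts:
            _write_table(world.ribo_counts[genotype], f"ribo_counts_{genotype}.tsv")
            _write_table(world.polya_counts[genotype], f"polya_counts_{genotype}.tsv")
    elif assay == "groseq":
        _write_table(world.groseq_counts, "groseq_counts_control.tsv")
    elif assay == "fasta":
        path = out_dir / "transcripts.fasta"
        with open(path, "w") as fh:
            for t in world.transcripts.values():
                fh.write(f">{t.transcript_id}\n{t.sequence}\n")
        written.append(path)
    elif assay == "bed":
        path = out_dir / "regions.bed"
        with open(path, "w") as fh:
            for t in world.transcripts.values():
                for name, (start, end) in t.regions.items():
                    fh.write(f"{t.transcript_id}\t{start}\t{end}\t{name}\n")
        written.append(path)
    elif assay == "truth":
        _write_table(world.truth_targets.set_index("guide_id"), "truth_targets.tsv")
    else:
        raise ValueError(f"unknown assay {assay!r}")
    return written


def config_to_yaml(config: SimConfig, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)


def config_from_yaml(path) -> SimConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for key in ("transcript_length_range", "tier_mix", "k_tx_range", "k_dec_range",
                "k_slice_range", "focal_loci"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return SimConfig(**raw)
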
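"""Absolute small-RNA quantification: UMI deduplication, spike-in
calibration, 25-nt prefix grouping, and detection thresholds.

piRNA 3' trimming produces 3'-end heterogeneity, so reads are grouped by
their 5' 25-nt prefix and each prefix group is treated as one piRNA
species family.  Spike-in oligonucleotides of known molar amount anchor
library-relative abundance (ppm) to molecules per cell and picomolar
concentration, given the per-cell piRNA total (default 1e7) and cell
volume (default 1,800 um^3, the median primary spermatocyte).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from pislice.sequences import normalize

logger = logging.getLogger(__name__)

AVOGADRO = 6.02214076e23
UMI_LEN = 9
PREFIX_LEN = 25

DEFAULT_TOTAL_PIRNAS_PER_CELL = 1e7
DEFAULT_CELL_VOLUME_UM3 = 1800.0


class CalibrationError(ValueError):
    """No spike-in reads detected; absolute quantification impossible."""


@dataclass(frozen=True)
class SpikeIn:
    name: str
    sequence: str
    molecules_added: float


@dataclass
class SpikeInSet:
    """Spike-in oligonucleotides of known per-library molecule counts."""

    entries: tuple[SpikeIn, ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("spike-in set must contain at least one entry")
        if any(e.molecules_added <= 0 for e in self.entries):
            raise ValueError("spike-in molecules_added must be > 0")
        self._sequences = {normalize(e.sequence) for e in self.entries}

    @property
    def total_molecules(self) -> float:
        return sum(e.molecules_added for e in self.entries)

    def is_spike(self, sequence: str) -> bool:
        # exact-match assignment, zero mismatches
        return normalize(sequence) in self._sequences


def deduplicate(reads) -> dict[str, int]:
    """Collapse UMI-tagged reads to unique molecules.

    Each read is ``9-nt UMI + insert + 9-nt UMI`` (adapters already
    trimmed).  A unique (insert, UMI-pair) combination counts once.
    Reads shorter than 19 nt (no insert possible) are skipped and logged.
    """
    seen: set[tuple[str, str]] = set()
    counts: Counter[str] = Counter()
    skipped = 0
    for read in reads:
        read = normalize(read)
        if len(read) < 2 * UMI_LEN + 1:
            skipped += 1
            continue
        umi = read[:UMI_LEN] + read[-UMI_LEN:]
        insert = read[UMI_LEN:-UMI_LEN]
        if (insert, umi) not in seen:
            seen.add((insert, umi))
            counts[insert] += 1
    if skipped:
        logger.info("deduplicate: skipped %d reads shorter than %d nt",
                    skipped, 2 * UMI_LEN + 1)
    return dict(counts)


def apply_blocklist(counts: dict[str, int], blocklist) -> dict[str, int]:
    """Drop inserts matching a blocklist (e.g. rRNA fragments).

    ``blocklist`` is an iterable of sequences or a FASTA path; matching is
    exact on the normalized sequence.  Removed reads are logged.
    """
    import os

    if isinstance(blocklist, (str, os.PathLike)):
        from Bio import SeqIO

        blocked = {normalize(str(rec.seq)) for rec in SeqIO.parse(blocklist, "fasta")}
    else:
        blocked = {normalize(s) for s in blocklist}
    kept = {s: c for s, c in counts.items() if normalize(s) not in blocked}
    removed = sum(counts.values()) - sum(kept.values())
    if removed:
        logger.info("apply_blocklist: removed %d reads matching blocklist", removed)
    return kept


@dataclass
class Calibration:
    """Per-library absolute scale and relative abundance."""

    molecules_per_read: float
    ppm: dict[str, float]          # non-spike inserts only
    molecules: dict[str, float]
    spike_reads: int
    total_nonspike_reads: int


def calibrate(counts: dict[str, int], spikes: SpikeInSet) -> Calibration:
    """Convert deduplicated insert counts to ppm and molecules.

    scale = total spike molecules added / total spike reads;
    ppm is computed over non-spike reads only.
    """
    spike_reads = sum(c for seq, c in counts.items() if spikes.is_spike(seq))
    if spike_reads == 0:
        raise CalibrationError("no spike-in reads detected")
    scale = spikes.total_molecules / spike_reads
    nonspike = {normalize(s): c for s, c in counts.items() if not spikes.is_spike(s)}
    total = sum(nonspike.values())
    ppm = {s: c / total * 1e6 for s, c in nonspike.items()} if total else {}
    molecules = {s: c * scale for s, c in nonspike.items()}
    return Calibration(scale, ppm, molecules, spike_reads, total)


def group_by_prefix(
    ppm: pd.DataFrame,
    locus: dict[str, str] | None = None,
    repeat_derived: dict[str, bool] | None = None,
) -> pd.DataFrame:
    """Group full-length species by their 5' 25-nt prefix.

    Parameters
    ----------
    ppm
        Abundance table: rows indexed by full-length insert sequence,
        one column per replicate (ppm).  Inserts shorter than 25 nt are
        routed to a discard bin (logged) and do not form groups.
    locus, repeat_derived
        Optional per-sequence annotation; a group inherits its
        representative's annotation, defaulting to "unassigned" / False.

    Returns
    -------
    DataFrame indexed by 25-nt prefix with the summed per-replicate ppm
    columns plus ``representative`` (highest-abundance member; ties broken
    by lexicographically smallest sequence), ``locus`` and
    ``repeat_derived``.
    """
    ppm = ppm.copy()
    ppm.index = [normalize(s) for s in ppm.index]
    short = [s for s in ppm.index if len(s) < PREFIX_LEN]
    if short:
        logger.info("group_by_prefix: discarded %d inserts shorter than %d nt",
                    len(short), PREFIX_LEN)
        ppm = ppm.drop(index=short)
    if ppm.empty:
        out = pd.DataFrame(columns=list(ppm.columns) + ["representative", "locus",
                                                        "repeat_derived"])
        out.index.name = "prefix"
        return out

    prefixes = ppm.index.str[:PREFIX_LEN]
    grouped = ppm.groupby(prefixes).sum()
    totals = ppm.sum(axis=1)

    reps: dict[str, str] = {}
    for seq in sorted(ppm.index):  # lexicographic order makes ties deterministic
        pre = seq[:PREFIX_LEN]
        if pre not in reps or totals[seq] > totals[reps[pre]]:
            reps[pre] = seq
    grouped["representative"] = [reps[p] for p in grouped.index]
    grouped["locus"] = [
        (locus or {}).get(r, "unassigned") for r in grouped["representative"]
    ]
    grouped["repeat_derived"] = [
        bool((repeat_derived or {}).get(r, False)) for r in grouped["representative"]
    ]
    grouped.index.name = "prefix"
    return grouped


def apply_detection_filter(
    groups: pd.DataFrame,
    control_columns,
    min_ppm: float = 1.0,
) -> pd.DataFrame:
    """Keep prefix groups whose abundance is >= min_ppm in *every* control
    replicate (boundary inclusive)."""
    if len(list(control_columns)) == 0:
        raise ValueError("need at least one control replicate")
    if groups.empty:
        return groups
    mask = (groups[list(control_columns)] >= min_ppm).all(axis=1)
    return groups[mask]


def is_undetectable_in_mutant(ppm_values, max_mean_ppm: float = 0.1) -> bool:
    """A piRNA is undetectable in a mutant if its mean abundance across
    mutant replicates is <= 0.1 ppm (inclusive)."""
    values = list(ppm_values)
    if not values:
        raise ValueError("need at least one mutant replicate")
    return sum(values) / len(values) <= max_mean_ppm


def ppm_to_molecules(ppm: float, total_per_cell: float = DEFAULT_TOTAL_PIRNAS_PER_CELL) -> float:
    """molecules/cell = ppm x total piRNAs per cell x 1e-6
    (1 ppm -> 10 molecules at 1e7 piRNAs/cell)."""
    if total_per_cell <= 0:
        raise ValueError("total_per_cell must be > 0")
    return ppm * total_per_cell * 1e-6


def molecules_to_pm(n: float, cell_volume_um3: float = DEFAULT_CELL_VOLUME_UM3) -> float:
    """Concentration (pM) of n molecules in one cell.

    1 um^3 = 1e-15 L, so one molecule in a 1,800 um^3 primary spermatocyte
    is ~0.92 pM (~1 pM).
    """
    if cell_volume_um3 <= 0:
        raise ValueError("cell volume must be > 0")
    volume_l = cell_volume_um3 * 1e-15
    return n / (volume_l * AVOGADRO) * 1e12


def pm_to_molecules(pm: float, cell_volume_um3: float = DEFAULT_CELL_VOLUME_UM3) -> float:
    if cell_volume_um3 <= 0:
        raise ValueError("cell volume must be > 0")
    volume_l = cell_volume_um3 * 1e-15
    return pm * 1e-12 * volume_l * AVOGADRO


def detectability_probability(
    mean_molecules: float,
    model: str = "poisson",
    dispersion: float | None = None,
) -> float:
    """Fraction of cells containing at least one molecule.

    Poisson: 1 - exp(-mean).  Negative binomial (variance mean + a*mean^2
    with dispersion a): 1 - (r / (r + mean))^r with r = 1/a.
    """
    if mean_molecules < 0:
        raise ValueError("mean must be >= 0")
    if model == "poisson":
        return 1.0 - math.exp(-mean_molecules)
    if model == "nb":
        if dispersion is None or dispersion <= 0:
            raise ValueError("nb model requires dispersion > 0")
        r = 1.0 / dispersion
        return 1.0 - (r / (r + mean_molecules)) ** r
    raise ValueError(f"unknown model {model!r}")
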
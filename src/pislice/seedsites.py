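"""miRNA-style and translation-model site scanning.

Three site definitions, all anchored on the target position t1 (the
nucleotide opposite guide position g1; the seed g2-g8 pairs t2-t8,
immediately 5' of t1 on the target):

* ``sevenmer_A1`` — perfect match to the guide seed (g2-g8) with an A at
  t1, the canonical high-affinity miRNA site;
* ``seed_plus7`` — seed match plus >= 7 further paired positions within
  g9-g30 at the same register (non-contiguous counting);
* ``seed_plus12`` — seed match plus >= 12 paired positions within g9-g30,
  the geometry proposed for piRNA-directed translational activation
  (combined with an ELAVL1-binding motif in the same 3'UTR).
"""

from __future__ import annotations

from dataclasses import dataclass

from pislice.sequences import Transcript, is_watson_crick, normalize, reverse_complement

MODES = ("sevenmer_A1", "seed_plus7", "seed_plus12")
DEFAULT_REGIONS = ("5UTR", "3UTR")
#: U-rich ELAVL1/HuR-type motif; configurable, given in DNA alphabet.
DEFAULT_ELAVL1_MOTIF = "TTTTT"


@dataclass
class SeedSite:
    transcript_id: str
    region: str
    t1_position: int  # 0-based coordinate of t1 on the target
    mode: str
    has_elavl1_motif_nearby: bool | None = None


def _paired_in_3prime(guide: str, seq: str, t1: int) -> int:
    """Paired positions within g9-g30 with t1 at transcript coordinate t1
    (target coordinate of gk is t1 - (k - 1))."""
    count = 0
    for k in range(9, 31):
        if k > len(guide):
            break
        t = t1 - (k - 1)
        if t < 0:
            break
        if is_watson_crick(guide[k - 1], seq[t]):
            count += 1
    return count


def find_sites(
    guide: str,
    transcript: Transcript,
    mode: str,
    regions=DEFAULT_REGIONS,
) -> list[SeedSite]:
    """Scan one transcript for seed-anchored sites of one guide.

    Sites are reported only when t1 lies within one of the requested
    annotated regions; a transcript without region annotation is an error.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if not transcript.regions:
        raise ValueError(f"transcript {transcript.transcript_id} lacks region annotation")
    guide = normalize(guide)
    if len(guide) < 8:
        raise ValueError("guide shorter than the g2-g8 seed")
    seq = transcript.sequence
    seed_match = reverse_complement(guide[1:8])  # pairs t8..t2, 5'->3' on target

    sites = []
    for t1 in range(7, len(seq)):
        if seq[t1 - 7 : t1] != seed_match:
            continue
        if mode == "sevenmer_A1" and seq[t1] != "A":
            continue
        if mode == "seed_plus7" and _paired_in_3prime(guide, seq, t1) < 7:
            continue
        if mode == "seed_plus12" and _paired_in_3prime(guide, seq, t1) < 12:
            continue
        region = transcript.region_of(t1)
        if region in regions:
            sites.append(SeedSite(transcript.transcript_id, region, t1, mode))
    return sites


def count_sites_per_guide(
    guide: str,
    transcripts,
    mode: str,
    regions=DEFAULT_REGIONS,
) -> int:
    """Total site count for one guide across a transcript collection."""
    return sum(len(find_sites(guide, t, mode, regions)) for t in transcripts)


def elavl1_annotate(
    sites: list[SeedSite],
    transcripts: dict[str, Transcript],
    motif: str = DEFAULT_ELAVL1_MOTIF,
    scope: str = "3UTR",
) -> list[SeedSite]:
    """Flag sites whose transcript carries the ELAVL1 motif in ``scope``
    (default: anywhere in the same 3'UTR)."""
    motif = normalize(motif)
    flagged = []
    for site in sites:
        transcript = transcripts[site.transcript_id]
        interval = transcript.regions.get(scope)
        present = False
        if interval is not None:
            start, end = interval
            present = motif in transcript.sequence[start:end]
        flagged.append(SeedSite(site.transcript_id, site.region, site.t1_position,
                                site.mode, present))
    return flagged
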
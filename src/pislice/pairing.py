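"""Guide:target pairing geometry at a cleavage site.

The cleavage register follows standard Argonaute geometry: slicing occurs
between the target nucleotides paired to guide positions g10 and g11, so
the 5'-monophosphate nucleotide of the 3' cleavage product pairs guide
position g10.  With ``p`` the 0-based transcript coordinate of that
nucleotide, guide position k (1-based, counted from the guide 5' end)
pairs transcript coordinate ``p + 10 - k`` for k = 1..30.  Positions that
fall outside the transcript, or beyond the guide's own length, are treated
as unpaired rather than rejecting the site.

Whether a guide can explain a cleavage event is decided by abundance-tiered
pairing rules: less abundant guides must pair more extensively.  The four
default tiers are

====  =========  =======================================
rule  abundance  geometry
====  =========  =======================================
R1    >= 1 ppm   >= 20 nt paired within g2-g25
R2    >= 5 ppm   contiguous pairing g3-g15
R3    >= 10 ppm  contiguous pairing g3-g16
R4    >= 50 ppm  contiguous pairing g4-g17
====  =========  =======================================

Rules are evaluated independently and combined by OR: a guide is callable
at a site if any rule's abundance precondition and geometry both hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pislice.sequences import is_watson_crick, is_wobble, normalize

GUIDE_SPAN = 30  # g1..g30 window considered at every site


@dataclass
class PairingResult:
    """Per-position match vector of a guide against a target site.

    ``match[k-1]`` is True iff guide position k forms a Watson-Crick pair
    (optionally G:U wobble) with the transcript. The vector always has
    length 30; positions beyond the guide length are False.
    """

    match: np.ndarray

    def __post_init__(self) -> None:
        self.match = np.asarray(self.match, dtype=bool)
        if self.match.shape != (GUIDE_SPAN,):
            raise ValueError(f"match vector must have length {GUIDE_SPAN}")

    def paired_in(self, g_start: int, g_end: int) -> int:
        """Number of paired positions in the inclusive window [g_start, g_end]."""
        return int(self.match[g_start - 1 : g_end].sum())

    def contiguous(self, g_start: int, g_end: int) -> bool:
        """True iff every position in the inclusive window is paired."""
        return bool(self.match[g_start - 1 : g_end].all())


def align_guide_at_site(
    guide: str,
    transcript: str,
    cleavage_position: int,
    *,
    allow_wobble: bool = False,
) -> PairingResult:
    """Pair a guide against a transcript window anchored at a cleavage site.

    Parameters
    ----------
    guide
        Guide (piRNA) sequence, 5'->3'.  The guide pairs antiparallel to the
        transcript; only its first 30 nt are considered.
    transcript
        Transcript sequence, 5'->3' (DNA or RNA alphabet).
    cleavage_position
        0-based coordinate of the 5'-monophosphate nucleotide of the 3'
        cleavage product, i.e. the target base paired to g10.
    allow_wobble
        Count G:U wobble as paired (off by default: the calling rules treat
        wobble as mismatch).
    """
    guide = normalize(guide)
    if not guide:
        raise ValueError("empty guide sequence")
    if cleavage_position < 0:
        raise ValueError("cleavage position must be >= 0")
    transcript = normalize(transcript)
    n = len(transcript)
    match = np.zeros(GUIDE_SPAN, dtype=bool)
    for k in range(1, min(len(guide), GUIDE_SPAN) + 1):
        t = cleavage_position + 10 - k
        if t < 0 or t >= n:
            continue
        gb, tb = guide[k - 1], transcript[t]
        if is_watson_crick(gb, tb) or (allow_wobble and is_wobble(gb, tb)):
            match[k - 1] = True
    return PairingResult(match)


@dataclass(frozen=True)
class TierRule:
    """One abundance-tiered pairing rule.

    ``kind`` is "count" (>= min_paired positions paired within the window)
    or "contiguous" (every window position paired).
    """

    name: str
    min_ppm: float
    kind: str
    g_start: int
    g_end: int
    min_paired: int = 0

    def geometry_holds(self, pairing: PairingResult) -> bool:
        if self.kind == "count":
            return pairing.paired_in(self.g_start, self.g_end) >= self.min_paired
        if self.kind == "contiguous":
            return pairing.contiguous(self.g_start, self.g_end)
        raise ValueError(f"unknown rule kind {self.kind!r}")


DEFAULT_TIERS: tuple[TierRule, ...] = (
    TierRule("R1", 1.0, "count", 2, 25, 20),
    TierRule("R2", 5.0, "contiguous", 3, 15),
    TierRule("R3", 10.0, "contiguous", 3, 16),
    TierRule("R4", 50.0, "contiguous", 4, 17),
)


@dataclass
class RuleVerdict:
    """Which tier rules a (pairing, abundance) pair satisfies."""

    satisfied_rules: frozenset[str] = field(default_factory=frozenset)

    @property
    def callable(self) -> bool:
        return bool(self.satisfied_rules)


def satisfies_tier(
    pairing: PairingResult,
    abundance_ppm: float,
    tiers: tuple[TierRule, ...] = DEFAULT_TIERS,
) -> RuleVerdict:
    """Evaluate every tier rule; a rule counts only if both its abundance
    precondition and its pairing geometry hold (thresholds inclusive)."""
    if abundance_ppm < 0:
        raise ValueError("abundance must be >= 0")
    satisfied = frozenset(
        rule.name
        for rule in tiers
        if abundance_ppm >= rule.min_ppm and rule.geometry_holds(pairing)
    )
    return RuleVerdict(satisfied)


# RNA/RNA Watson-Crick nearest-neighbor stacking free energies at 37 C
# (kcal/mol), keyed by the guide-strand dinucleotide 5'->3'.  The 10 unique
# duplex parameters (Xia et al. 1998) expand to 16 keys under rotational
# symmetry.  RNA alphabet with T standing in for U.
NN_STACK_DG37 = {
    "AA": -0.93, "TT": -0.93,
    "AT": -1.10,
    "TA": -1.33,
    "CT": -2.08, "AG": -2.08,
    "CA": -2.11, "TG": -2.11,
    "GT": -2.24, "AC": -2.24,
    "GA": -2.35, "TC": -2.35,
    "CG": -2.36,
    "GG": -3.26, "CC": -3.26,
    "GC": -3.42,
}


def duplex_delta_g(guide: str, pairing: PairingResult) -> float:
    """Nearest-neighbor duplex free energy (kcal/mol) of the paired runs.

    Sums Watson-Crick stacking terms over consecutive paired guide
    positions; no initiation or terminal penalties (annotation only, never
    used for target calling).  A pairing with no paired position is 0 by
    definition.
    """
    guide = normalize(guide)
    dg = 0.0
    for k in range(1, GUIDE_SPAN):  # stack between positions k and k+1
        if pairing.match[k - 1] and pairing.match[k] and k < len(guide):
            dg += NN_STACK_DG37[guide[k - 1 : k + 1]]
    return dg
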
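"""Nucleotide-sequence helpers shared across the package.

All sequences are handled internally in DNA alphabet (ACGT, uppercase);
RNA input (U) is normalized on entry.  Transcript coordinates are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}

REGION_NAMES = ("5UTR", "CDS", "3UTR")


def normalize(seq: str) -> str:
    """Uppercase and convert RNA (U) to DNA (T)."""
    return seq.upper().replace("U", "T")


def complement(base: str) -> str:
    return _COMPLEMENT.get(base, "N")


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(normalize(seq)))


def is_watson_crick(guide_base: str, target_base: str) -> bool:
    """True iff the target base is the Watson-Crick complement of the guide
    base (A:U, G:C; T treated as U)."""
    return _COMPLEMENT.get(guide_base) == target_base


def is_wobble(guide_base: str, target_base: str) -> bool:
    """G:U wobble geometry (guide G opposite target U, or guide U opposite
    target G), in DNA alphabet."""
    return (guide_base, target_base) in (("G", "T"), ("T", "G"))


@dataclass
class Transcript:
    """A transcript sequence with 5'UTR / CDS / 3'UTR annotation.

    ``regions`` maps region name to a 0-based half-open interval.  Regions
    must tile the transcript without overlap; this is not enforced so that
    partial annotations (e.g. lncRNAs with no CDS) remain representable.
    """

    transcript_id: str
    sequence: str
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = normalize(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    def region_of(self, position: int) -> str | None:
        """Region name containing ``position``, or None."""
        for name, (start, end) in self.regions.items():
            if start <= position < end:
                return name
        return None
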
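"""Helicase signature-motif screen for protein sequences.

Consensus motifs characteristic of the DDX (DEAD-box) and DHX (DEAH-box)
helicase families, plus a few from other ATP-dependent helicases, are
compiled into exact-length regular expressions and scanned against protein
sequences.  In a motif pattern ``x`` is a wildcard matching any of the 20
amino acids; every other letter matches that residue case-insensitively
(lowercase letters such as the ``g`` in ``RgxD`` denote the same residue as
their uppercase form).  No gaps are allowed, overlapping occurrences are all
reported, and positions are 1-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import AMINO_ACIDS, SequenceRecord

__all__ = [
    "MotifPattern",
    "MotifMatch",
    "builtin_motif_sets",
    "compile_motif",
    "scan",
    "helicase_report",
]

FAMILIES = ("DDX", "DHX", "other")

_DDX = ["GFxxPxxIQ", "AxxGxGKT", "PTRELA", "TPGR", "DExD", "SAT", "FVxT", "RgxD"]
_DHX = ["GxxGxGKT", "TQPRRV", "TDGML", "DExH", "SAT", "FLTG", "TNIAET", "QrxGRAGR"]
_OTHER = ["AHTSAGKT", "TSPIKALSNQ", "MTTEIL"]


@dataclass(frozen=True)
class MotifPattern:
    """A named consensus motif; ``x`` is the wildcard character."""

    name: str
    family: str
    pattern: str

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if not self.pattern:
            raise ValueError("empty motif pattern")
        for ch in self.pattern:
            if ch == "x":
                continue
            if not ch.isalpha():
                raise ValueError(f"illegal character {ch!r} in motif {self.pattern!r}")
            if ch.upper() not in AMINO_ACIDS:
                raise ValueError(f"non-residue letter {ch!r} in motif {self.pattern!r}")

    def __len__(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class MotifMatch:
    """One motif occurrence; ``position`` is the 1-based start."""

    seq_id: str
    motif: str
    family: str
    position: int
    substring: str


def builtin_motif_sets() -> list[MotifPattern]:
    """The 8 DDX + 8 DHX + 3 other helicase signature motifs, verbatim.

    ``SAT`` appears in both the DDX and DHX sets and yields two distinct
    entries.
    """
    out = [MotifPattern(p, "DDX", p) for p in _DDX]
    out += [MotifPattern(p, "DHX", p) for p in _DHX]
    out += [MotifPattern(p, "other", p) for p in _OTHER]
    return out


def compile_motif(pattern: str | MotifPattern) -> re.Pattern[str]:
    """Compile a motif into an overlapping-occurrence regex.

    The regex uses a lookahead capture so that overlapping matches are all
    found by ``finditer``.
    """
    pat = pattern.pattern if isinstance(pattern, MotifPattern) else pattern
    MotifPattern(pat, "other", pat)  # reuse validation
    body = "".join("[" + AMINO_ACIDS + "]" if ch == "x" else ch.upper() for ch in pat)
    return re.compile(f"(?=({body}))")


def scan(
    sequence: SequenceRecord, motifs: Iterable[MotifPattern] | None = None
) -> list[MotifMatch]:
    """Report every occurrence of every motif in one sequence.

    Overlaps allowed; sorted by position, then motif name, then family.
    """
    motifs = list(motifs) if motifs is not None else builtin_motif_sets()
    matches: list[MotifMatch] = []
    for m in motifs:
        rx = compile_motif(m)
        for hit in rx.finditer(sequence.residues):
            matches.append(
                MotifMatch(
                    seq_id=sequence.seq_id,
                    motif=m.name,
                    family=m.family,
                    position=hit.start() + 1,
                    substring=hit.group(1),
                )
            )
    matches.sort(key=lambda m: (m.position, m.motif, m.family))
    return matches


def scan_all(
    sequences: Sequence[SequenceRecord], motifs: Iterable[MotifPattern] | None = None
) -> list[MotifMatch]:
    motifs = list(motifs) if motifs is not None else builtin_motif_sets()
    out: list[MotifMatch] = []
    for seq in sequences:
        out.extend(scan(seq, motifs))
    return out


def helicase_report(matches: Sequence[MotifMatch]) -> dict:
    """Per-family match counts and a verdict.

    The verdict is "no helicase signature" iff there were zero matches;
    otherwise the families with hits are listed.  No threshold for a positive
    helicase call is asserted.
    """
    counts: dict[str, int] = {}
    for m in matches:
        counts[m.family] = counts.get(m.family, 0) + 1
    if not matches:
        verdict = "no helicase signature"
    else:
        fams = ", ".join(f"{f}: {counts[f]}" for f in FAMILIES if f in counts)
        verdict = f"motif hits found ({fams}); no overall classification asserted"
    return {"family_counts": counts, "n_matches": len(matches), "verdict": verdict}
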
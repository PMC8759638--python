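"""Exact IUPAC consensus motif scanning on promoter sequences, both strands.

The DRE box (TATCGATA, bound by DREF and BEAF-32) is its own reverse
complement, so a palindromic tandem such as TATCGATATCGATA carries the motif
twice on each strand at the same forward coordinates.  The scanner tests
every offset, reports minus-strand matches at forward coordinates, and counts
coincident strand-symmetric matches separately -- the convention under which
the tandem yields four perfect matches whose union span is 14bp.

Consensus matching is exact under IUPAC degeneracy; no position-weight-matrix
scoring is involved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio.Seq import Seq

__all__ = ["MotifMatch", "revcomp", "scan", "match_span", "scan_fasta"]

IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}


@dataclass(frozen=True)
class MotifMatch:
    sequence: str  # sequence name
    start: int  # 0-based, forward coordinates regardless of strand
    end: int  # half-open
    strand: str  # "+" or "-"
    motif: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end - self.start != len(self.motif):
            raise ValueError("match width must equal motif length")


def _validate(seq: str, what: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid {what} character(s): {sorted(bad)}")
    return seq


def revcomp(seq: str) -> str:
    """IUPAC-aware reverse complement."""
    return str(Seq(_validate(seq, "DNA")).reverse_complement())


def _matches_at(seq: str, motif: str, offset: int) -> bool:
    return all(seq[offset + i] in IUPAC[m] for i, m in enumerate(motif))


def scan(
    seq: str,
    motif: str,
    both_strands: bool = True,
    name: str = "seq",
) -> list[MotifMatch]:
    """All exact IUPAC-consensus matches of ``motif`` in ``seq``.

    Minus-strand hits are found by matching the reverse complement of the
    motif on the forward sequence and are reported at forward coordinates
    with strand "-"; for palindromic motifs this yields coincident +/-
    matches, counted separately.  Matches are sorted by (start, strand).
    """
    seq = _validate(seq, "sequence")
    motif = _validate(motif, "motif")
    if len(motif) > len(seq):
        raise ValueError("motif longer than sequence")
    out: list[MotifMatch] = []
    rc = revcomp(motif)
    for off in range(len(seq) - len(motif) + 1):
        if _matches_at(seq, motif, off):
            out.append(MotifMatch(name, off, off + len(motif), "+", motif))
        if both_strands and _matches_at(seq, rc, off):
            out.append(MotifMatch(name, off, off + len(motif), "-", motif))
    out.sort(key=lambda m: (m.start, m.strand))
    return out


def match_span(matches: Sequence[MotifMatch]) -> tuple[int, int]:
    """Smallest single interval covering every match (all on one sequence)."""
    if not matches:
        raise ValueError("match_span of an empty match list")
    names = {m.sequence for m in matches}
    if len(names) > 1:
        raise ValueError(f"matches span multiple sequences: {sorted(names)}")
    return min(m.start for m in matches), max(m.end for m in matches)


def scan_fasta(
    path, motif: str, both_strands: bool = True
) -> dict[str, list[MotifMatch]]:
    """Scan every record of a FASTA file; returns name -> matches."""
    from Bio import SeqIO

    return {
        rec.id: scan(str(rec.seq), motif, both_strands=both_strands, name=rec.id)
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_matches(matches: Sequence[MotifMatch], path) -> None:
    """BED6 with the motif in the name column and strand in column 6."""
    with open(path, "w") as fh:
        for m in matches:
            fh.write(
                f"{m.sequence}\t{m.start}\t{m.end}\t{m.motif}\t0\t{m.strand}\n"
            )
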
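"""Degenerate 12-mer consensus scanning with mismatch tolerance.

The Ter-macrodomain insulators tidR (GCTGACGTCAGC) and tidL (GTTGACGTCAGC)
share the IUPAC consensus GYTGACGTCAGC.  This module counts mismatches of a
site against such a degenerate pattern (a base failing its IUPAC class costs
1; degenerate positions are free for any allowed base), scans sequences on one
or both strands, optionally treats the sequence as circular, and collapses the
double report a perfect palindrome produces on the two strands.

Only fixed-consensus mismatch scanning is provided — no PWM scoring or motif
discovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

__all__ = [
    "TID_CONSENSUS", "TIDR_SEQ", "TIDL_SEQ", "SHUFFLED_CONTROL",
    "MotifPattern", "MotifHit",
    "mismatch_count", "reverse_complement", "is_palindrome",
    "scan", "scan_fasta", "census", "hits_to_bed6",
]

TID_CONSENSUS = "GYTGACGTCAGC"
TIDR_SEQ = "GCTGACGTCAGC"
TIDL_SEQ = "GTTGACGTCAGC"
SHUFFLED_CONTROL = "GACGCTAGCGTC"  # same palindromic organisation, no activity

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


@dataclass(frozen=True)
class MotifPattern:
    """An IUPAC degenerate pattern (default: the tidRL consensus)."""

    iupac: str = TID_CONSENSUS

    def __post_init__(self):
        if not self.iupac:
            raise ValueError("empty pattern")
        bad = set(self.iupac.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC characters in pattern: {sorted(bad)}")
        object.__setattr__(self, "iupac", self.iupac.upper())

    def __len__(self) -> int:
        return len(self.iupac)

    def reverse_complement(self) -> "MotifPattern":
        return MotifPattern("".join(_COMPLEMENT[b] for b in reversed(self.iupac)))


@dataclass(frozen=True)
class MotifHit:
    """A scan hit. ``position`` is the 1-based forward-strand window start."""

    position: int
    strand: str
    mismatches: int
    site: str


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement (IUPAC codes supported)."""
    seq = seq.upper()
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq))
    except KeyError as e:
        raise ValueError(f"invalid nucleotide {e.args[0]!r}") from None


def is_palindrome(seq: str) -> bool:
    """True iff the sequence equals its own reverse complement."""
    return seq.upper() == reverse_complement(seq)


def mismatch_count(site: str, pattern: MotifPattern | str) -> int:
    """Positions of ``site`` failing the IUPAC class of ``pattern``.

    Non-ACGT characters in the site (e.g. N) always count as mismatches.
    """
    if isinstance(pattern, str):
        pattern = MotifPattern(pattern)
    site = site.upper()
    if len(site) != len(pattern):
        raise ValueError(
            f"site length {len(site)} != pattern length {len(pattern)}"
        )
    return sum(
        1 for b, p in zip(site, pattern.iupac) if b not in IUPAC[p] or b not in "ACGT"
    )


def _mismatch_profile(seq_codes: np.ndarray, pattern: MotifPattern) -> np.ndarray:
    """Mismatch count for every window start (vectorised over the sequence)."""
    k = len(pattern)
    n = seq_codes.size - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    mm = np.zeros(n, dtype=np.int64)
    for j, p in enumerate(pattern.iupac):
        allowed = np.zeros(256, dtype=bool)
        for b in IUPAC[p]:
            allowed[ord(b)] = True
        mm += ~allowed[seq_codes[j:j + n]]
    return mm


def scan(sequence: str, pattern: MotifPattern | str = TID_CONSENSUS,
         max_mismatch: int = 0, strands: str = "both", circular: bool = False,
         collapse_palindromic: bool = True) -> list[MotifHit]:
    """All windows within the mismatch budget, sorted by position.

    With ``strands="both"`` a reverse-strand hit is reported at the
    forward-strand start of its window.  When ``collapse_palindromic`` is on,
    a window hit on both strands is reported once (forward strand retained) so
    a palindromic site is counted a single time in per-genome censuses.
    With ``circular`` the last ``len(pattern)-1`` windows wrap the origin.
    """
    if isinstance(pattern, str):
        pattern = MotifPattern(pattern)
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    if strands not in {"both", "forward"}:
        raise ValueError("strands must be 'both' or 'forward'")
    seq = sequence.upper()
    k = len(pattern)
    n_seq = len(seq)
    if not circular and n_seq < k:
        raise ValueError("sequence shorter than pattern (and not circular)")
    work = seq + (seq[: k - 1] if circular else "")
    codes = np.frombuffer(work.encode("ascii"), dtype=np.uint8)
    per_strand: dict[str, np.ndarray] = {"+": _mismatch_profile(codes, pattern)}
    if strands == "both":
        per_strand["-"] = _mismatch_profile(codes, pattern.reverse_complement())
    hits: dict[tuple[int, str], MotifHit] = {}
    for strand, mm in per_strand.items():
        for i in np.nonzero(mm <= max_mismatch)[0]:
            pos = int(i) + 1
            if pos > n_seq:  # wrapped duplicate of a linear window
                continue
            hits[(pos, strand)] = MotifHit(
                position=pos, strand=strand, mismatches=int(mm[i]),
                site=work[i:i + k],
            )
    out = []
    for (pos, strand), h in hits.items():
        if (
            collapse_palindromic and strand == "-" and (pos, "+") in hits
        ):
            continue
        out.append(h)
    out.sort(key=lambda h: (h.position, h.strand))
    return out


def scan_fasta(path: str | Path, pattern: MotifPattern | str = TID_CONSENSUS,
               max_mismatch: int = 0, strands: str = "both",
               circular: bool = False, collapse_palindromic: bool = True
               ) -> dict[str, list[MotifHit]]:
    """Scan every record of a (multi-)FASTA file; returns hits per record id."""
    out: dict[str, list[MotifHit]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = scan(str(rec.seq), pattern, max_mismatch, strands,
                           circular, collapse_palindromic)
    return out


def census(sequence: str, max_mismatch: int = 1, circular: bool = True
           ) -> dict[str, int]:
    """Site census under both mismatch conventions.

    ``consensus_*`` counts mismatches against the degenerate consensus
    GYTGACGTCAGC (a Y position accepts C or T at zero cost); ``tidr_*`` counts
    literal distance from tidR (GCTGACGTCAGC).  Exact and budget-limited counts
    are reported separately, with and without palindromic collapsing, because
    published per-genome counts rarely state either convention.
    """
    out = {}
    for mode, pat in (("consensus", TID_CONSENSUS), ("tidr", TIDR_SEQ)):
        for collapse in (True, False):
            tag = "collapsed" if collapse else "per_strand"
            hits = scan(sequence, pat, max_mismatch, "both", circular, collapse)
            out[f"{mode}_{tag}_le_{max_mismatch}mm"] = len(hits)
            out[f"{mode}_{tag}_exact"] = sum(1 for h in hits if h.mismatches == 0)
    return out


def hits_to_bed6(hits: Iterable[MotifHit], chrom: str, pattern_len: int = 12
                 ) -> str:
    """BED6 export (0-based half-open; score column carries the mismatch count)."""
    lines = [
        f"{chrom}\t{h.position - 1}\t{h.position - 1 + pattern_len}\t"
        f"{h.site}\t{h.mismatches}\t{h.strand}"
        for h in hits
    ]
    return "\n".join(lines) + ("\n" if lines else "")
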
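"""Summit-centered sequence windows and IUPAC-degenerate motif scanning.

Windows of fixed half-width around called summits are exported as FASTA
for external de novo motif discovery (e.g. MEME in ZOOPS mode); a direct
scanner locates occurrences of IUPAC consensus motifs such as RAWTSGAAC
on either strand, which is how motif-bearing peaks are counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from cutmap.genome import GenomeIndex

logger = logging.getLogger(__name__)

#: IUPAC nucleotide code -> set of matching sequence bases.
#: A sequence 'N' is matched only by the motif code 'N'.
IUPAC_SETS = {
    "A": {"A"},
    "C": {"C"},
    "G": {"G"},
    "T": {"T"},
    "R": {"A", "G"},
    "Y": {"C", "T"},
    "S": {"C", "G"},
    "W": {"A", "T"},
    "K": {"G", "T"},
    "M": {"A", "C"},
    "B": {"C", "G", "T"},
    "D": {"A", "G", "T"},
    "H": {"A", "C", "T"},
    "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T", "N"},
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class IupacMotif:
    pattern: str

    def __post_init__(self):
        bad = [c for c in self.pattern.upper() if c not in IUPAC_SETS]
        if bad or not self.pattern:
            raise ValueError(f"invalid IUPAC code(s) {bad!r} in motif {self.pattern!r}")
        object.__setattr__(self, "pattern", self.pattern.upper())

    def __len__(self) -> int:
        return len(self.pattern)


@dataclass
class MotifWindow:
    contig: str
    summit: int
    sequence: str
    flank: int

    def __post_init__(self):
        if len(self.sequence) != 2 * self.flank + 1:
            raise ValueError("window sequence length must be 2*flank + 1")


def extract_windows(
    summits: Iterable[tuple[str, int]] | "PeakSet",
    genome: GenomeIndex,
    flank: int = 20,
) -> list[MotifWindow]:
    """Summit-centered windows of width 2*flank + 1.

    Accepts a PeakSet or an iterable of (contig, summit) pairs. Summits
    whose window would cross a contig boundary are skipped (logged count).
    """
    if not genome.has_sequence:
        raise ValueError("window extraction requires a genome with sequence")
    pairs: list[tuple[str, int]]
    if hasattr(summits, "peaks"):
        pairs = [(p.contig, p.summit) for p in summits.peaks]
    else:
        pairs = list(summits)
    windows = []
    n_skipped = 0
    for contig, summit in pairs:
        start, end = summit - flank, summit + flank + 1
        if start < 0 or end > genome.length(contig):
            n_skipped += 1
            continue
        windows.append(
            MotifWindow(contig=contig, summit=summit,
                        sequence=genome.fetch(contig, start, end), flank=flank)
        )
    if n_skipped:
        logger.info("skipped %d summit(s) whose window crossed a contig boundary", n_skipped)
    return windows


def _matches_at(seq: str, pattern: str, offset: int) -> bool:
    return all(
        seq[offset + k] in IUPAC_SETS[pattern[k]] for k in range(len(pattern))
    )


def scan_iupac(
    sequence: str, motif: IupacMotif, both_strands: bool = True
) -> list[tuple[int, str]]:
    """All (plus-strand offset, strand) matches of the motif in the sequence.

    Minus-strand hits are found by scanning the reverse complement; the
    reported offset is the leftmost base of the hit in plus-strand
    coordinates.
    """
    seq = sequence.upper()
    bad = set(seq) - {"A", "C", "G", "T", "N"}
    if bad:
        raise ValueError(f"sequence contains non-nucleotide characters {sorted(bad)!r}")
    m = len(motif)
    hits = [
        (i, "+") for i in range(len(seq) - m + 1) if _matches_at(seq, motif.pattern, i)
    ]
    if both_strands:
        rc = reverse_complement(seq)
        for i in range(len(rc) - m + 1):
            if _matches_at(rc, motif.pattern, i):
                hits.append((len(seq) - m - i, "-"))
    return sorted(hits)


def count_motif_windows(
    windows: list[MotifWindow], motif: IupacMotif, both_strands: bool = True
) -> tuple[int, list[bool]]:
    """Number of windows with >= 1 motif match on either strand, plus per-window flags."""
    flags = [bool(scan_iupac(w.sequence, motif, both_strands)) for w in windows]
    return sum(flags), flags


def write_windows_fasta(windows: list[MotifWindow], path: str | Path) -> None:
    """FASTA export of summit windows; headers encode contig:summit."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f">{w.contig}:{w.summit}\n{w.sequence}\n")


def meme_command(fasta_path: str | Path, out_dir: str = "meme_out") -> str:
    """Shell snippet for the delegated external motif-discovery run."""
    return (
        f"meme {fasta_path} -dna -revcomp -mod zoops -nmotifs 5 "
        f"-minw 5 -maxw 15 -oc {out_dir}"
    )
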
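"""Reduce alignment files to per-contig arrays of R1 read 5'-end counts.

Each retained read contributes exactly one count: a forward-strand read at
its leftmost aligned reference position, a reverse-strand read at its
rightmost aligned reference base (one less than the exclusive alignment
end). Both strands accumulate into a single per-contig array, mirroring
how a blunt or near-blunt double-strand break produces tagged 5' ends on
both strands at (almost) the same position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from cutmap.genome import GenomeIndex

logger = logging.getLogger(__name__)

#: alignment categories excluded by default ("basic mapping filters")
DEFAULT_EXCLUDE_FLAGS = frozenset(
    {"unmapped", "secondary", "supplementary", "duplicate", "qc_fail"}
)

_FLAG_TESTS = {
    "unmapped": lambda r: r.is_unmapped,
    "secondary": lambda r: r.is_secondary,
    "supplementary": lambda r: r.is_supplementary,
    "duplicate": lambda r: r.is_duplicate,
    "qc_fail": lambda r: r.is_qcfail,
}


@dataclass(frozen=True)
class FilterConfig:
    """Mapping filters applied before 5'-end counting.

    min_aligned_length is measured in reference space by default (rightmost
    minus leftmost aligned base + 1), since 5'-end positions are
    reference-space quantities; set ``aligned_length_mode="query"`` to use
    the number of aligned query bases instead.
    """

    min_aligned_length: int = 40
    exclude_flags: frozenset[str] = DEFAULT_EXCLUDE_FLAGS
    min_mapping_quality: int = 0
    r1_only: bool = True
    aligned_length_mode: str = "reference"

    def __post_init__(self):
        if self.min_aligned_length < 1:
            raise ValueError("min_aligned_length must be >= 1")
        if self.min_mapping_quality < 0:
            raise ValueError("min_mapping_quality must be >= 0")
        unknown = set(self.exclude_flags) - set(_FLAG_TESTS)
        if unknown:
            raise ValueError(f"unknown exclude flags: {sorted(unknown)}")
        if self.aligned_length_mode not in ("reference", "query"):
            raise ValueError("aligned_length_mode must be 'reference' or 'query'")


@dataclass
class EndCountTrack:
    """Per-contig integer arrays of read 5'-end counts for one replicate."""

    replicate_id: str
    condition: str
    counts: dict[str, np.ndarray]
    library_size: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.condition not in ("treated", "mock"):
            raise ValueError("condition must be 'treated' or 'mock'")
        total = int(sum(int(a.sum()) for a in self.counts.values()))
        if self.library_size is None:
            self.library_size = total
        elif self.library_size != total:
            raise ValueError(
                f"library_size {self.library_size} != sum of counts {total}"
            )


def _keep(read: pysam.AlignedSegment, cfg: FilterConfig) -> bool:
    for flag in cfg.exclude_flags:
        if _FLAG_TESTS[flag](read):
            return False
    if cfg.r1_only and read.is_paired and read.is_read2:
        return False
    if read.mapping_quality < cfg.min_mapping_quality:
        return False
    if cfg.aligned_length_mode == "reference":
        aligned = read.reference_length or 0
    else:
        aligned = read.query_alignment_length or 0
    return aligned >= cfg.min_aligned_length


def five_prime_position(read: pysam.AlignedSegment) -> int:
    """0-based reference position of the read's 5' end.

    Forward strand: leftmost aligned base; reverse strand: rightmost
    aligned base (reference_end - 1).
    """
    if read.is_reverse:
        return read.reference_end - 1
    return read.reference_start


def extract_r1_ends(
    alignment_file: str | Path,
    genome: GenomeIndex,
    cfg: FilterConfig | None = None,
    replicate_id: str = "rep1",
    condition: str = "treated",
) -> EndCountTrack:
    """Count filtered R1 5' ends per reference base.

    The alignment file must be coordinate-sorted; BAM files must be
    indexed. Contigs present in the alignments but absent from `genome`
    raise an error naming the contig.
    """
    cfg = cfg or FilterConfig()
    path = str(alignment_file)
    counts = {c: np.zeros(genome.length(c), dtype=np.int64) for c in genome.contigs}
    n_kept = 0
    with pysam.AlignmentFile(path) as af:
        if af.is_bam and not af.has_index():
            raise FileNotFoundError(f"alignment file {path} has no index")
        for contig in af.references:
            if contig not in genome:
                raise ValueError(f"contig {contig!r} in alignments absent from genome")
        for read in af.fetch(until_eof=True):
            if read.is_unmapped and "unmapped" in cfg.exclude_flags:
                continue
            if not _keep(read, cfg):
                continue
            contig = read.reference_name
            if contig not in counts:
                raise ValueError(f"contig {contig!r} in alignments absent from genome")
            counts[contig][five_prime_position(read)] += 1
            n_kept += 1
    if n_kept == 0:
        logger.warning("no reads retained from %s; track is all zeros", path)
    return EndCountTrack(
        replicate_id=replicate_id, condition=condition, counts=counts,
        library_size=n_kept,
    )
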
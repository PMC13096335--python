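"""tRF-seq cleavage mapping from 5'-base coverage of uniquely aligned reads.

Within a tRNA locus, the 5' base of each uniquely aligned read is counted
per position; comparing the (depth-normalized) coverage between the
defense-present and defense-absent conditions localizes the endonucleolytic
cleavage position as the maximum of the coverage ratio (e.g. the variable
loop around position 48 of tRNA-Tyr).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from cutmap.readends import five_prime_position

logger = logging.getLogger(__name__)

DEFAULT_RATIO_PSEUDOCOUNT = 1.0
DEFAULT_MIN_RATIO = 2.0


@dataclass
class TrfCoverage:
    """Per-position counts of read 5' bases within one locus."""

    locus: str
    counts: np.ndarray                    # length = locus length, 0-based locus coords
    condition: str
    replicate_id: str = "rep1"
    library_size: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("coverage counts must be non-negative")
        if self.library_size is None:
            self.library_size = int(self.counts.sum())


@dataclass
class CleavageCall:
    locus: str
    positions: list[int]     # argmax positions of the ratio (all ties), empty if below threshold
    ratio: float             # maximal ratio value
    pseudocount: float


def trf_five_prime_coverage(
    alignment_file: str | Path,
    locus: tuple[str, int, int],
    condition: str,
    replicate_id: str = "rep1",
    uniqueness: str = "primary_no_secondary",
    min_mapq: int = 1,
) -> TrfCoverage:
    """Count 5' bases of uniquely aligned reads inside a genomic locus.

    Uniqueness rules: ``primary_no_secondary`` keeps primary alignments of
    reads that have no secondary records anywhere in the file (two-pass);
    ``mapq`` keeps primary alignments with mapping quality >= min_mapq.
    The library size is the genome-wide number of retained reads, so
    loci can be compared across libraries of different depth.
    """
    contig, start, end = locus
    if uniqueness not in ("primary_no_secondary", "mapq"):
        raise ValueError(f"unknown uniqueness rule {uniqueness!r}")
    path = str(alignment_file)
    multi: set[str] = set()
    if uniqueness == "primary_no_secondary":
        with pysam.AlignmentFile(path) as af:
            for read in af.fetch(until_eof=True):
                if read.is_secondary:
                    multi.add(read.query_name)
    counts = np.zeros(end - start, dtype=np.int64)
    n_retained = 0
    with pysam.AlignmentFile(path) as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if uniqueness == "primary_no_secondary" and read.query_name in multi:
                continue
            if uniqueness == "mapq" and read.mapping_quality < min_mapq:
                continue
            n_retained += 1
            if read.reference_name != contig:
                continue
            pos = five_prime_position(read)
            if start <= pos < end:
                counts[pos - start] += 1
    return TrfCoverage(
        locus=f"{contig}:{start}-{end}",
        counts=counts,
        condition=condition,
        replicate_id=replicate_id,
        library_size=n_retained,
    )


def trf_ratio(
    with_defense: TrfCoverage,
    without_defense: TrfCoverage,
    pseudocount: float = DEFAULT_RATIO_PSEUDOCOUNT,
    scale: str = "cpm",
    min_ratio: float = DEFAULT_MIN_RATIO,
) -> tuple[CleavageCall, np.ndarray]:
    """Per-position coverage ratio (defense present / absent) and cleavage call.

    The pseudocount is in count units and is added before depth scaling,
    so a zero-coverage position behaves like a fractional count rather
    than vanishing against the per-million scale. With ``scale="cpm"``
    each pseudocounted vector is scaled by its library size (counts per
    million retained reads); ``scale="raw"`` compares pseudocounted
    counts directly. The call reports every argmax position of the ratio
    track, or none when the maximum stays below ``min_ratio``.
    """
    if with_defense.locus != without_defense.locus or len(with_defense.counts) != len(
        without_defense.counts
    ):
        raise ValueError("coverage vectors are over different loci")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if scale == "cpm":
        if with_defense.library_size == 0 or without_defense.library_size == 0:
            raise ValueError("cannot CPM-scale an empty library")
        w = (with_defense.counts + pseudocount) * (1e6 / with_defense.library_size)
        wo = (without_defense.counts + pseudocount) * (1e6 / without_defense.library_size)
    elif scale == "raw":
        w = with_defense.counts + pseudocount
        wo = without_defense.counts + pseudocount
    else:
        raise ValueError(f"unknown scale {scale!r}")
    ratio = w / wo
    peak = float(ratio.max())
    if peak >= min_ratio:
        positions = [int(i) for i in np.flatnonzero(ratio == peak)]
    else:
        positions = []
    call = CleavageCall(
        locus=with_defense.locus, positions=positions, ratio=peak,
        pseudocount=pseudocount,
    )
    return call, ratio
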
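"""Summit calling on smoothed treated profiles with replicate consistency.

Candidate summits are local maxima of the smoothed treated CPM profile
passing three summit criteria (minimum signal, minimum log2 fold change,
minimum treated-to-mock ratio). Replicate consistency is then enforced at
the raw-count level: a minimum number of treated replicates must each show
a raw 5'-end count above a floor within a small window around the summit.
Surviving summits within a merge distance of each other are clustered
transitively and the strongest smoothed signal wins. Final peaks are
fixed-width (default 3 bp) intervals centered on the summit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from cutmap.genome import GenomeIndex
from cutmap.readends import EndCountTrack, FilterConfig, extract_r1_ends
from cutmap.profiles import (
    ConditionProfile,
    FoldChangeTrack,
    DEFAULT_PSEUDOCOUNT,
    DEFAULT_SMOOTH_WINDOW,
    aggregate_condition,
    cpm_normalize,
    log2fc,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Thresholds:
    min_signal: float = 1.0        # CPM at the summit, smoothed treated
    min_log2fc: float = 2.0
    min_ratio: float = 1.2         # treated/mock at the summit (pseudocounted)
    min_raw_count: int = 5         # raw 5'-end counts per supporting replicate
    support_radius: int = 1        # bp around the summit for the raw-count check
    min_supporting_replicates: int = 2
    merge_distance: int = 3        # bp; summits this close are merged
    peak_width: int = 3            # bp; emitted interval width

    def __post_init__(self):
        for name in (
            "min_signal", "min_log2fc", "min_ratio", "min_raw_count",
            "support_radius", "min_supporting_replicates", "merge_distance",
            "peak_width",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.peak_width % 2 == 0:
            raise ValueError("peak_width must be odd")


@dataclass
class SummitCandidate:
    contig: str
    position: int
    treated_smoothed: float
    mock_smoothed: float
    log2fc: float
    ratio: float
    support: int = 0


@dataclass
class Peak:
    contig: str
    start: int
    end: int
    summit: int
    treated_smoothed: float
    mock_smoothed: float
    log2fc: float
    ratio: float
    support: int

    @property
    def midpoint(self) -> float:
        """Average of start and end coordinates (for genome-distribution plots)."""
        return (self.start + self.end) / 2


@dataclass
class PeakSet:
    peaks: list[Peak]
    thresholds: Thresholds
    pseudocount: float

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def filtered(self, min_log2fc: float) -> "PeakSet":
        """Strictly filtered view (log2FC > cutoff), as used for plotting exports."""
        kept = [p for p in self.peaks if p.log2fc > min_log2fc]
        return PeakSet(kept, self.thresholds, self.pseudocount)


def local_maxima(
    values: np.ndarray, rtol: float = 1e-9, atol: float = 1e-12
) -> list[int]:
    """Positions of local maxima: >= both neighbors, > at least one.

    A plateau (run of equal values) reports its center position
    (left-of-center for even-length runs): a symmetric moving average of
    an isolated spike produces an exactly flat plateau whose center is the
    spike, so the center is the only tie-break that recovers it. Values
    within a small relative tolerance count as equal, because summing CPM
    tracks and convolving leaves floating-point jitter on plateaus that
    are flat in exact arithmetic. A constant array has no maxima. Edge
    runs qualify when they strictly exceed their single inner neighbor.
    """
    x = np.asarray(values, dtype=np.float64)
    n = len(x)
    out: list[int] = []
    i = 0
    while i < n:
        tol = atol + rtol * abs(x[i])
        j = i
        while j + 1 < n and abs(x[j + 1] - x[i]) <= tol:
            j += 1
        left_less = i > 0 and x[i - 1] < x[i] - tol
        right_less = j < n - 1 and x[j + 1] < x[i] - tol
        left_ok = left_less or i == 0
        right_ok = right_less or j == n - 1
        if left_ok and right_ok and (left_less or right_less):
            out.append((i + j) // 2)
        i = j + 1
    return out


def find_summits(
    treated: ConditionProfile,
    mock: ConditionProfile,
    fc: FoldChangeTrack,
    th: Thresholds,
) -> list[SummitCandidate]:
    """Local maxima of the smoothed treated profile passing the summit criteria."""
    pc = fc.pseudocount
    candidates: list[SummitCandidate] = []
    for contig in sorted(treated.smoothed):
        t = treated.smoothed[contig]
        m = mock.smoothed[contig]
        lfc = fc.values[contig]
        for pos in local_maxima(t):
            ratio = (t[pos] + pc) / (m[pos] + pc)
            if t[pos] >= th.min_signal and lfc[pos] >= th.min_log2fc and ratio >= th.min_ratio:
                candidates.append(
                    SummitCandidate(
                        contig=contig,
                        position=pos,
                        treated_smoothed=float(t[pos]),
                        mock_smoothed=float(m[pos]),
                        log2fc=float(lfc[pos]),
                        ratio=float(ratio),
                    )
                )
    return candidates


def replicate_support(
    candidate: SummitCandidate,
    raw_treated: list[EndCountTrack],
    th: Thresholds,
) -> int:
    """Number of treated replicates with raw count >= min_raw_count near the summit.

    The window is [summit - support_radius, summit + support_radius],
    clipped to the contig.
    """
    if not raw_treated:
        raise ValueError("need at least one raw treated track")
    n = 0
    for track in raw_treated:
        arr = track.counts[candidate.contig]
        lo = max(0, candidate.position - th.support_radius)
        hi = min(len(arr), candidate.position + th.support_radius + 1)
        if arr[lo:hi].max(initial=0) >= th.min_raw_count:
            n += 1
    return n


def merge_summits(
    candidates: list[SummitCandidate], th: Thresholds
) -> list[SummitCandidate]:
    """Transitively cluster same-contig summits within merge_distance.

    One summit per cluster survives: highest smoothed treated signal,
    leftmost on ties.
    """
    ordered = sorted(candidates, key=lambda c: (c.contig, c.position))
    merged: list[SummitCandidate] = []
    cluster: list[SummitCandidate] = []

    def flush():
        if cluster:
            merged.append(max(cluster, key=lambda c: (c.treated_smoothed, -c.position)))

    for cand in ordered:
        if (
            cluster
            and cand.contig == cluster[-1].contig
            and cand.position - cluster[-1].position <= th.merge_distance
        ):
            cluster.append(cand)
        else:
            flush()
            cluster = [cand]
    flush()
    return merged


def emit_peaks(
    summits: list[SummitCandidate], genome: GenomeIndex, th: Thresholds
) -> list[Peak]:
    """Fixed-width intervals centered on final summits, clipped at contig edges."""
    half = (th.peak_width - 1) // 2
    peaks = []
    for s in summits:
        length = genome.length(s.contig)
        start = s.position - half
        end = s.position + half + 1
        if start < 0 or end > length:
            logger.warning(
                "peak at %s:%d clipped at contig edge", s.contig, s.position
            )
            start = max(0, start)
            end = min(length, end)
        peaks.append(
            Peak(
                contig=s.contig,
                start=start,
                end=end,
                summit=s.position,
                treated_smoothed=s.treated_smoothed,
                mock_smoothed=s.mock_smoothed,
                log2fc=s.log2fc,
                ratio=s.ratio,
                support=s.support,
            )
        )
    return peaks


def call_peaks_from_tracks(
    raw_treated: list[EndCountTrack],
    raw_mock: list[EndCountTrack],
    genome: GenomeIndex,
    th: Thresholds | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> PeakSet:
    """Peak calling from already-extracted 5'-end count tracks."""
    th = th or Thresholds()
    treated = aggregate_condition(
        [cpm_normalize(t) for t in raw_treated], "treated", smooth_window
    )
    mock = aggregate_condition(
        [cpm_normalize(t) for t in raw_mock], "mock", smooth_window
    )
    fc = log2fc(treated, mock, pseudocount)
    candidates = find_summits(treated, mock, fc, th)
    supported = []
    for cand in candidates:
        support = replicate_support(cand, raw_treated, th)
        if support >= th.min_supporting_replicates:
            supported.append(replace(cand, support=support))
    final = merge_summits(supported, th)
    return PeakSet(emit_peaks(final, genome, th), th, pseudocount)


def call_peaks(
    treated_files: list[str | Path],
    mock_files: list[str | Path],
    genome: GenomeIndex,
    cfg: FilterConfig | None = None,
    th: Thresholds | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> PeakSet:
    """End-to-end peak calling from treated and mock alignment files."""
    if not treated_files or not mock_files:
        raise ValueError("need at least one treated and one mock alignment file")
    cfg = cfg or FilterConfig()
    raw_treated = [
        extract_r1_ends(f, genome, cfg, replicate_id=f"treated_{i+1}", condition="treated")
        for i, f in enumerate(treated_files)
    ]
    raw_mock = [
        extract_r1_ends(f, genome, cfg, replicate_id=f"mock_{i+1}", condition="mock")
        for i, f in enumerate(mock_files)
    ]
    return call_peaks_from_tracks(
        raw_treated, raw_mock, genome, th, pseudocount, smooth_window
    )
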
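"""CPM normalization, per-condition aggregation, smoothing and log2 fold change.

Counts are scaled to counts-per-million per replicate using the
whole-library size, replicate CPM tracks are summed within each condition,
the aggregate is smoothed with a centered moving average (default 5 bp,
zero-padded edges, constant divisor), and treated vs. mock enrichment is
expressed as log2((treated + pc) / (mock + pc)) with a small pseudocount.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cutmap.readends import EndCountTrack

DEFAULT_PSEUDOCOUNT = 0.1  # CPM; small relative to the 1.0 CPM summit threshold
DEFAULT_SMOOTH_WINDOW = 5  # bp


@dataclass
class CPMTrack:
    replicate_id: str
    values: dict[str, np.ndarray]


@dataclass
class ConditionProfile:
    """Summed CPM across a condition's replicates, plus its smoothed form."""

    condition: str
    aggregate: dict[str, np.ndarray]
    smoothed: dict[str, np.ndarray]
    window: int


@dataclass
class FoldChangeTrack:
    values: dict[str, np.ndarray]
    pseudocount: float


def cpm_normalize(track: EndCountTrack) -> CPMTrack:
    """Scale a replicate's counts to counts-per-million of its library."""
    if track.library_size == 0:
        raise ValueError(f"empty replicate {track.replicate_id!r}: library_size is 0")
    scale = 1e6 / track.library_size
    return CPMTrack(
        replicate_id=track.replicate_id,
        values={c: a.astype(np.float64) * scale for c, a in track.counts.items()},
    )


def _check_same_contigs(value_dicts: list[dict[str, np.ndarray]]) -> None:
    first = value_dicts[0]
    shapes = {c: a.shape for c, a in first.items()}
    for other in value_dicts[1:]:
        if set(other) != set(shapes) or any(other[c].shape != shapes[c] for c in shapes):
            raise ValueError("tracks have mismatched contigs or contig lengths")


def smooth(values: np.ndarray, window: int = DEFAULT_SMOOTH_WINDOW) -> np.ndarray:
    """Centered moving average with zero-padded edges and constant divisor.

    out[i] = (1/w) * sum of in[i-(w-1)/2 .. i+(w-1)/2], out-of-range terms 0.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError(f"smoothing window must be odd and >= 1, got {window}")
    if window > len(values):
        raise ValueError("smoothing window exceeds array length")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(np.asarray(values, dtype=np.float64), kernel, mode="same")


def aggregate_condition(
    tracks: list[CPMTrack], condition: str, window: int = DEFAULT_SMOOTH_WINDOW
) -> ConditionProfile:
    """Element-wise sum of replicate CPM tracks, then smoothing."""
    if not tracks:
        raise ValueError("need at least one track to aggregate")
    _check_same_contigs([t.values for t in tracks])
    aggregate = {
        c: np.sum([t.values[c] for t in tracks], axis=0) for c in tracks[0].values
    }
    smoothed = {c: smooth(a, window) for c, a in aggregate.items()}
    return ConditionProfile(
        condition=condition, aggregate=aggregate, smoothed=smoothed, window=window
    )


def log2fc(
    treated: ConditionProfile,
    mock: ConditionProfile,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> FoldChangeTrack:
    """log2((treated.smoothed + pc) / (mock.smoothed + pc)), elementwise."""
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be > 0, got {pseudocount}")
    _check_same_contigs([treated.smoothed, mock.smoothed])
    values = {
        c: np.log2((treated.smoothed[c] + pseudocount) / (mock.smoothed[c] + pseudocount))
        for c in treated.smoothed
    }
    return FoldChangeTrack(values=values, pseudocount=pseudocount)
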
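"""Writers for the standard text outputs: bedGraph, BED, TSV tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from cutmap.peakcall import PeakSet
from cutmap.readends import EndCountTrack


def write_bedgraph(values: dict[str, np.ndarray], path: str | Path) -> None:
    """bedGraph (0-based half-open) with one line per run of equal nonzero value."""
    with open(path, "w") as fh:
        for contig, arr in values.items():
            arr = np.asarray(arr)
            if len(arr) == 0:
                continue
            boundaries = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [len(arr)]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{contig}\t{s}\t{e}\t{v:g}\n")


def write_peaks_bed(peaks: PeakSet, path: str | Path) -> None:
    """BED5: contig, start, end, name, score = round(100 * log2FC) capped at 1000."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks, start=1):
            score = int(np.clip(round(100 * p.log2fc), 0, 1000))
            fh.write(f"{p.contig}\t{p.start}\t{p.end}\tpeak_{i}\t{score}\n")


def peaks_to_dataframe(peaks: PeakSet) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig": p.contig,
                "start": p.start,
                "end": p.end,
                "summit": p.summit,
                "midpoint": p.midpoint,
                "treated_cpm": p.treated_smoothed,
                "mock_cpm": p.mock_smoothed,
                "log2fc": p.log2fc,
                "ratio": p.ratio,
                "support": p.support,
            }
            for p in peaks
        ]
    )


def write_peaks_tsv(peaks: PeakSet, path: str | Path) -> None:
    peaks_to_dataframe(peaks).to_csv(path, sep="\t", index=False)


def write_track_manifest(tracks: list[EndCountTrack], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "replicate_id": t.replicate_id,
                "condition": t.condition,
                "library_size": t.library_size,
            }
            for t in tracks
        ]
    ).to_csv(path, sep="\t", index=False)
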
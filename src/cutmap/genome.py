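"""Reference genome index: contig names, lengths and optional sequence access."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pyfaidx


class GenomeIndex:
    """Ordered map of contig name -> length, with optional sequence access.

    Coordinates are 0-based, intervals half-open, throughout the package.
    """

    def __init__(self, lengths: Mapping[str, int], fasta: pyfaidx.Fasta | None = None):
        lengths = dict(lengths)
        if not lengths:
            raise ValueError("genome must contain at least one contig")
        for name, length in lengths.items():
            if length <= 0:
                raise ValueError(f"contig {name!r} has non-positive length {length}")
        self._lengths = lengths
        self._fasta = fasta

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeIndex":
        fasta = pyfaidx.Fasta(str(path))
        return cls({name: len(fasta[name]) for name in fasta.keys()}, fasta=fasta)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self._lengths)

    @property
    def contigs(self) -> list[str]:
        return list(self._lengths)

    @property
    def has_sequence(self) -> bool:
        return self._fasta is not None

    def __contains__(self, contig: str) -> bool:
        return contig in self._lengths

    def length(self, contig: str) -> int:
        try:
            return self._lengths[contig]
        except KeyError:
            raise KeyError(f"contig {contig!r} not in genome") from None

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Sequence of [start, end) on `contig`, uppercased."""
        if self._fasta is None:
            raise ValueError("genome index was built without sequence access")
        length = self.length(contig)
        if not (0 <= start <= end <= length):
            raise ValueError(
                f"interval [{start}, {end}) out of bounds for {contig} (length {length})"
            )
        return str(self._fasta[contig][start:end]).upper()
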
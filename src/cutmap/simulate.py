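"""Synthetic-data generators with known ground truth for every pipeline stage.

Four generators emulate the structure of the real inputs:

* random genomes with concrete instances of a degenerate motif planted at
  recorded positions;
* SITE-seq style alignment files, with shared Poisson background 5' ends
  in every replicate and sharp treated-only excesses at planted cut sites
  (sorted, indexed BAM output written through pysam);
* neighborhood annotation sets in which tRNA genes follow a Poisson
  process at a background rate genome-wide and an elevated rate inside
  the focal gene's flanked region;
* tRF 5'-base count vectors with a condition-specific cleavage spike.

Every generator is deterministic given (config, seed); per-replicate
streams are spawned from the master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pysam

from cutmap.genome import GenomeIndex
from cutmap.motifs import IupacMotif, IUPAC_SETS
from cutmap.neighborhood import GenomeAnnotation
from cutmap.trf import TrfCoverage


# ---------------------------------------------------------------------------
# genomes with planted motifs

def simulate_genome(
    length: int,
    gc_fraction: float = 0.35,
    n_planted_motifs: int = 0,
    motif: IupacMotif | None = None,
    seed: int = 0,
) -> tuple[str, list[int]]:
    """Random i.i.d. sequence with concrete motif instances planted.

    Degenerate motif codes are resolved uniformly at random; planted
    instances do not overlap. Returns (sequence, sorted planted positions).
    """
    if n_planted_motifs > 0:
        if motif is None:
            raise ValueError("motif required when planting instances")
        if length < len(motif) * n_planted_motifs * 10:
            raise ValueError("genome too short for the requested motif placements")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    seq = rng.choice(np.array(list("ACGT")), size=length, p=p)
    positions: list[int] = []
    if n_planted_motifs > 0:
        m = len(motif)
        for _ in range(n_planted_motifs):
            for _attempt in range(10000):
                pos = int(rng.integers(0, length - m + 1))
                if all(abs(pos - q) >= m for q in positions):
                    break
            else:
                raise RuntimeError("could not place motif instances without overlap")
            positions.append(pos)
            instance = [rng.choice(sorted(IUPAC_SETS[c] - {"N"})) for c in motif.pattern]
            seq[pos : pos + m] = instance
    return "".join(seq), sorted(positions)


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# SITE-seq alignment files with planted cut sites

@dataclass
class SimTruth:
    """Planted signal structure of a SITE-seq simulation."""

    planted_sites: list[tuple[str, int, float]]  # (contig, position, expected excess/replicate)
    background_rate: float = 0.02                # expected background 5' ends per bp per replicate
    n_treated: int = 3
    n_mock: int = 3
    read_length: int = 100
    #: end-repair jitter: probability that a cut-site read's 5' end lands at
    #: site-1 / site / site+1. End repair and dA-tailing blunt a minority of
    #: tagged ends by one nucleotide; a perfectly single-base signal is not
    #: what the assay produces, and its smoothed profile is an exactly flat
    #: plateau whose argmax is set by stray background reads.
    end_jitter: tuple[float, float, float] = (0.15, 0.7, 0.15)
    seed: int = 0

    def __post_init__(self):
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if any(x[2] < 0 for x in self.planted_sites):
            raise ValueError("expected site counts must be >= 0")
        if abs(sum(self.end_jitter) - 1.0) > 1e-9 or any(p < 0 for p in self.end_jitter):
            raise ValueError("end_jitter must be a probability vector over (-1, 0, +1)")


@dataclass
class SiteSeqSim:
    treated_paths: list[Path]
    mock_paths: list[Path]
    truth: SimTruth
    tallies: dict[str, dict[str, np.ndarray]]    # replicate_id -> contig -> planted 5'-end counts


def _write_bam(
    path: Path,
    header: pysam.AlignmentHeader,
    records: list[tuple[str, int, bool, str]],
    read_length: int,
) -> None:
    """Write, coordinate-sort and index a BAM of simple full-match R1 records.

    Each record is (contig, 5' end position, is_reverse, name); the
    aligned span consumes `read_length` reference bases.
    """
    tmp = path.with_suffix(".unsorted.bam")
    refs = {name: i for i, name in enumerate(header.references)}
    with pysam.AlignmentFile(str(tmp), "wb", header=header) as out:
        for contig, pos, is_reverse, name in records:
            a = pysam.AlignedSegment(header)
            a.query_name = name
            # paired, first-in-pair, mate unmapped; reverse bit as drawn
            a.flag = 0x1 | 0x40 | 0x8 | (0x10 if is_reverse else 0)
            a.reference_id = refs[contig]
            a.reference_start = pos - read_length + 1 if is_reverse else pos
            a.mapping_quality = 60
            a.cigarstring = f"{read_length}M"
            a.query_sequence = "A" * read_length
            a.query_qualities = pysam.qualitystring_to_array("I" * read_length)
            out.write(a)
    pysam.sort("-o", str(path), str(tmp))
    Path(tmp).unlink()
    pysam.index(str(path))


def simulate_site_seq(
    genome: GenomeIndex | dict[str, int],
    truth: SimTruth,
    out_dir: str | Path,
) -> SiteSeqSim:
    """Simulate sorted, indexed treated and mock alignment files.

    Background reads land their 5' ends uniformly (Poisson total per
    replicate) on random strands in every replicate; treated replicates
    additionally receive Poisson-distributed forward reads whose 5' ends
    sit at each planted position up to the +/-1 bp end-repair jitter in
    the truth. Positions whose read would run off the contig are excluded
    from the background draw, and planted sites must leave room for a
    full read.
    """
    lengths = genome.lengths if isinstance(genome, GenomeIndex) else dict(genome)
    rl = truth.read_length
    for contig, pos, _ in truth.planted_sites:
        if contig not in lengths:
            raise ValueError(f"planted site contig {contig!r} not in genome")
        if pos + rl > lengths[contig]:
            raise ValueError(f"planted site {contig}:{pos} leaves no room for a read")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = pysam.AlignmentHeader.from_references(
        list(lengths), [lengths[c] for c in lengths]
    )
    streams = np.random.SeedSequence(truth.seed).spawn(truth.n_treated + truth.n_mock)
    replicates = [(f"treated_{i+1}", True) for i in range(truth.n_treated)] + [
        (f"mock_{i+1}", False) for i in range(truth.n_mock)
    ]
    treated_paths, mock_paths = [], []
    tallies: dict[str, dict[str, np.ndarray]] = {}
    for (rep_id, is_treated), ss in zip(replicates, streams):
        rng = np.random.default_rng(ss)
        records: list[tuple[str, int, bool, str]] = []
        tally = {c: np.zeros(n, dtype=np.int64) for c, n in lengths.items()}
        n_read = 0
        for contig, length in lengths.items():
            n_bg = rng.poisson(truth.background_rate * length)
            for _ in range(n_bg):
                is_reverse = bool(rng.integers(2))
                # valid 5'-end range keeps the whole read on the contig
                if is_reverse:
                    pos = int(rng.integers(rl - 1, length))
                else:
                    pos = int(rng.integers(0, length - rl + 1))
                records.append((contig, pos, is_reverse, f"{rep_id}_bg{n_read}"))
                tally[contig][pos] += 1
                n_read += 1
        if is_treated:
            for contig, pos, expected in truth.planted_sites:
                n_site = rng.poisson(expected)
                offsets = rng.choice([-1, 0, 1], size=n_site, p=truth.end_jitter)
                for off in offsets:
                    p = min(max(pos + int(off), 0), lengths[contig] - rl)
                    records.append((contig, p, False, f"{rep_id}_site{n_read}"))
                    tally[contig][p] += 1
                    n_read += 1
        path = out_dir / f"{rep_id}.bam"
        _write_bam(path, header, records, rl)
        (treated_paths if is_treated else mock_paths).append(path)
        tallies[rep_id] = tally
    truth_json = out_dir / "truth.json"
    truth_json.write_text(json.dumps(asdict(truth), indent=2))
    return SiteSeqSim(
        treated_paths=treated_paths, mock_paths=mock_paths, truth=truth,
        tallies=tallies,
    )


def default_site_truth(
    genome_length: int = 50000,
    n_sites: int = 12,
    expected_excess: float = 20.0,
    background_rate: float = 0.02,
    n_treated: int = 3,
    n_mock: int = 3,
    read_length: int = 100,
    seed: int = 0,
    contig: str = "sim",
    min_separation: int = 500,
) -> SimTruth:
    """Evenly scattered planted cut sites on a single synthetic contig."""
    rng = np.random.default_rng(seed)
    positions: list[int] = []
    lo, hi = read_length, genome_length - 2 * read_length
    for _ in range(n_sites):
        for _attempt in range(10000):
            pos = int(rng.integers(lo, hi))
            if all(abs(pos - q) >= min_separation for q in positions):
                break
        else:
            raise RuntimeError("could not scatter planted sites")
        positions.append(pos)
    return SimTruth(
        planted_sites=[(contig, p, expected_excess) for p in sorted(positions)],
        background_rate=background_rate,
        n_treated=n_treated,
        n_mock=n_mock,
        read_length=read_length,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# neighborhood annotation sets

@dataclass
class NeighborhoodSimConfig:
    """Study-scale defaults: 296 phage-sized genomes, ~1 tRNA per 10 kb
    background, 50-fold enrichment inside the focal gene's +/-1 kb region."""

    n_genomes: int = 296
    genome_length_range: tuple[int, int] = (30000, 180000)
    background_rate: float = 1e-4          # tRNA genes per bp genome-wide
    enrichment: float = 50.0               # rate multiplier inside the proximal region
    focal_gene_length: int = 600
    trna_length: int = 76
    flank: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.enrichment < 0:
            raise ValueError("enrichment factor must be >= 0")


def simulate_neighborhood(cfg: NeighborhoodSimConfig) -> list[GenomeAnnotation]:
    """Genomes whose tRNA genes follow an inhomogeneous Poisson process.

    The start-point intensity is `background_rate` everywhere except the
    focal gene body +/- flank, where it is multiplied by `enrichment`.
    """
    rng = np.random.default_rng(cfg.seed)
    out = []
    tl = cfg.trna_length
    for g in range(cfg.n_genomes):
        length = int(rng.integers(cfg.genome_length_range[0], cfg.genome_length_range[1] + 1))
        fs = int(rng.integers(cfg.flank, length - cfg.flank - cfg.focal_gene_length))
        fe = fs + cfg.focal_gene_length
        lo, hi = max(0, fs - cfg.flank), min(length, fe + cfg.flank)
        starts: list[int] = []
        n_out = rng.poisson(cfg.background_rate * (length - (hi - lo)))
        for _ in range(n_out):
            s = int(rng.integers(0, length - (hi - lo)))
            starts.append(s if s < lo else s + (hi - lo))
        n_in = rng.poisson(cfg.background_rate * cfg.enrichment * (hi - lo))
        starts.extend(int(rng.integers(lo, hi)) for _ in range(n_in))
        trnas = [(s, min(s + tl, length)) for s in sorted(starts)]
        out.append(
            GenomeAnnotation(
                genome_id=f"genome_{g+1}",
                genome_length=length,
                focal_gene=(fs, fe),
                trna_genes=trnas,
            )
        )
    return out


def write_annotation_tsv(annotations: list[GenomeAnnotation], path: str | Path) -> None:
    """TSV export compatible with neighborhood.read_annotation_tsv."""
    with open(path, "w") as fh:
        fh.write("genome_id\tgenome_length\tfocal_start\tfocal_end\ttrna_start\ttrna_end\n")
        for a in annotations:
            fs, fe = a.focal_gene
            if not a.trna_genes:
                fh.write(f"{a.genome_id}\t{a.genome_length}\t{fs}\t{fe}\t\t\n")
            for ts, te in a.trna_genes:
                fh.write(f"{a.genome_id}\t{a.genome_length}\t{fs}\t{fe}\t{ts}\t{te}\n")


# ---------------------------------------------------------------------------
# tRF coverage vectors

def simulate_trf(
    locus_length: int = 85,
    cleavage_position: int = 48,
    spike: float = 200.0,
    background: float = 5.0,
    seed: int = 0,
    locus: str = "tRNA-Tyr",
) -> tuple[TrfCoverage, TrfCoverage]:
    """Pair of 5'-base count vectors (defense present, defense absent).

    Both conditions share a per-position Poisson background; the
    defense-present condition adds a Poisson spike at the cleavage
    position.
    """
    if not 0 <= cleavage_position < locus_length:
        raise ValueError("cleavage_position outside locus")
    rng = np.random.default_rng(seed)
    base_with = rng.poisson(background, size=locus_length)
    base_without = rng.poisson(background, size=locus_length)
    base_with[cleavage_position] += rng.poisson(spike)
    return (
        TrfCoverage(locus=locus, counts=base_with, condition="with_defense"),
        TrfCoverage(locus=locus, counts=base_without, condition="without_defense"),
    )
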
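import numpy as np
import pysam
import pytest
from hypothesis import settings

from cutmap.genome import GenomeIndex

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_bam(path, lengths, reads):
    """Write a small coordinate-sorted, indexed BAM from read dicts.

    Each read dict: contig, start (0-based leftmost), length
    (reference-consumed bases), and optional reverse, mapq, name, paired,
    read2, secondary, supplementary, duplicate, qcfail, unmapped, cigar.
    """
    header = pysam.AlignmentHeader.from_references(
        list(lengths), [lengths[c] for c in lengths]
    )
    refs = {name: i for i, name in enumerate(lengths)}
    tmp = str(path) + ".unsorted.bam"
    with pysam.AlignmentFile(tmp, "wb", header=header) as out:
        for i, r in enumerate(reads):
            a = pysam.AlignedSegment(header)
            a.query_name = r.get("name", f"read{i}")
            flag = 0
            if r.get("paired", True):
                flag |= 0x1 | 0x8
                flag |= 0x80 if r.get("read2") else 0x40
            if r.get("reverse"):
                flag |= 0x10
            if r.get("unmapped"):
                flag |= 0x4
            if r.get("secondary"):
                flag |= 0x100
            if r.get("supplementary"):
                flag |= 0x800
            if r.get("duplicate"):
                flag |= 0x400
            if r.get("qcfail"):
                flag |= 0x200
            a.flag = flag
            if not r.get("unmapped"):
                a.reference_id = refs[r["contig"]]
                a.reference_start = r["start"]
                a.mapping_quality = r.get("mapq", 60)
                a.cigarstring = r.get("cigar", f"{r['length']}M")
            qlen = a.infer_query_length() or r.get("length", 50)
            a.query_sequence = "A" * qlen
            a.query_qualities = pysam.qualitystring_to_array("I" * qlen)
            out.write(a)
    pysam.sort("-o", str(path), tmp)
    import os

    os.remove(tmp)
    pysam.index(str(path))
    return path


@pytest.fixture
def small_genome():
    return GenomeIndex({"chr": 1000})


@pytest.fixture
def bam_factory(tmp_path):
    counter = {"n": 0}

    def factory(lengths, reads):
        counter["n"] += 1
        return make_bam(tmp_path / f"t{counter['n']}.bam", lengths, reads)

    return factory


@pytest.fixture
def fasta_factory(tmp_path):
    counter = {"n": 0}

    def factory(sequences):
        counter["n"] += 1
        path = tmp_path / f"g{counter['n']}.fa"
        with open(path, "w") as fh:
            for name, seq in sequences.items():
                fh.write(f">{name}\n{seq}\n")
        return path

    return factory
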
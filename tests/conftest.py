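import pysam
import pytest

from smncopy.registry import GRCH37_CONTIG_LENGTHS, load_registry
from smncopy.simulate import fixture_registry


@pytest.fixture(scope="session")
def registry():
    return load_registry("GRCh37")


@pytest.fixture(scope="session")
def fix_registry():
    """Desk-scale registry: real sites/variants, shrunken gene windows."""
    return fixture_registry()


def make_header() -> pysam.AlignmentHeader:
    chroms = sorted(GRCH37_CONTIG_LENGTHS, key=int)
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": GRCH37_CONTIG_LENGTHS[c]} for c in chroms],
        }
    )


def make_read(
    header,
    name,
    chrom,
    start0,
    seq,
    qual=40,
    cigar=None,
    flag=0,
    mapq=60,
):
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = seq
    a.flag = flag
    a.reference_id = header.get_tid(chrom)
    a.reference_start = start0
    a.mapping_quality = mapq
    a.cigartuples = cigar if cigar is not None else ((0, len(seq)),)
    a.query_qualities = pysam.qualitystring_to_array(chr(qual + 33) * len(seq))
    return a


def write_bam(path, header, reads):
    """Sort, write and index a hand-built read list; returns the path."""
    reads = sorted(reads, key=lambda r: (r.reference_id, r.reference_start))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for r in reads:
            bam.write(r)
    pysam.index(str(path))
    return str(path)
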
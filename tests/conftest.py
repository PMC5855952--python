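import numpy as np
import pysam
import pytest

from shapesort import mapsim


def make_header(reference_name="transcript", length=100):
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "unsorted"},
         "SQ": [{"SN": reference_name, "LN": length}]}
    )


def make_read(
    header,
    qname="r1",
    start=0,
    seq="ACGT",
    qual=37,
    flag=0,
    cigar=None,
    mate_start=None,
):
    a = pysam.AlignedSegment(header)
    a.query_name = qname
    a.flag = flag
    a.reference_id = 0
    a.reference_start = start
    a.mapping_quality = 60
    a.cigarstring = cigar or f"{len(seq)}M"
    a.query_sequence = seq
    a.query_qualities = pysam.qualitystring_to_array(chr(qual + 33) * len(seq))
    if mate_start is not None:
        a.next_reference_id = 0
        a.next_reference_start = mate_start
    return a


def random_structure(length, rng, stem_prob=0.6):
    """Random valid dot-bracket string built from nested stems."""
    chars = ["."] * length
    i, j = 0, length - 1
    while i < j:
        if rng.random() < stem_prob:
            chars[i], chars[j] = "(", ")"
            i, j = i + 1, j - 1
        else:
            if rng.random() < 0.5:
                i += 1
            else:
                j -= 1
    return "".join(chars)


@pytest.fixture
def rng():
    return np.random.default_rng(20_26)


@pytest.fixture
def hairpin_profile():
    """60-nt transcript with a central hairpin and known reactivities."""
    seq = mapsim.random_sequence(60, seed=17)
    structure = "." * 14 + "((((((((....))))))))" + "." * 26
    return mapsim.make_profile(seq, structure, seed=17)
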
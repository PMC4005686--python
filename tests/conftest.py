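import numpy as np
import pysam
import pytest

from splicesieve.simulate import SimulationConfig, simulate_dataset

HEADER = pysam.AlignmentHeader.from_dict({
    "HD": {"VN": "1.6", "SO": "coordinate"},
    "SQ": [{"SN": "chr1", "LN": 1_000_000}, {"SN": "chr2", "LN": 1_000_000}],
})


def make_aln(
    cigar: str,
    pos: int = 1000,
    name: str = "r1",
    reference: str = "chr1",
    md: str | None = None,
    nm: int | None = None,
    nh: int = 1,
    xs: str | None = "+",
    mapq: int = 50,
    flag: int = 0,
) -> pysam.AlignedSegment:
    """Hand-build a pysam record for parser tests."""
    a = pysam.AlignedSegment(HEADER)
    a.query_name = name
    a.reference_id = HEADER.get_tid(reference)
    a.reference_start = pos
    a.cigarstring = cigar
    a.flag = flag
    a.mapping_quality = mapq
    qlen = a.infer_query_length()
    a.query_sequence = "A" * qlen
    tags = [("NH", nh)]
    if nm is not None:
        tags.append(("NM", nm))
    if md is not None:
        tags.append(("MD", md))
    if xs is not None:
        tags.append(("XS", xs))
    a.set_tags(tags)
    return a


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small simulated dataset shared across tests: 60 expressed and 12
    artefactual junctions, 50 bp reads, 10% multireads."""
    d = tmp_path_factory.mktemp("sim")
    sam = str(d / "small.sam")
    truth_tsv = str(d / "small.truth.tsv")
    config = SimulationConfig(
        n_true_junctions=60, n_fp_junctions=12, read_length=50,
        mean_reads_per_junction=12.0, fraction_multireads=0.1, seed=11)
    truth = simulate_dataset(config, sam, truth_tsv)
    return {"sam": sam, "truth_tsv": truth_tsv, "truth": truth,
            "config": config}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
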
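import pytest

from lctscape import chimera, reference
from lctscape.simulate import SimConfig, simulate_genome, simulate_reads


@pytest.fixture(scope="session")
def small_truth():
    """Error-free toy study shared by read-level tests."""
    cfg = SimConfig(seed=11, error_rate=0.0)
    return simulate_genome(cfg)


@pytest.fixture(scope="session")
def small_pairs(small_truth):
    return simulate_reads(small_truth)


@pytest.fixture(scope="session")
def finder_inputs(small_truth):
    refs = {
        e.id: reference.extract_5p_sequence(small_truth.genome, e)[0]
        for e in small_truth.elements
    }
    elements = {e.id: e for e in small_truth.elements}
    repeats = chimera.RepeatAnnotation.from_rmsk_rows(small_truth.rmsk_rows)
    return refs, elements, repeats


@pytest.fixture(scope="session")
def finder_result(small_pairs, finder_inputs):
    refs, elements, repeats = finder_inputs
    return chimera.find_chimeras(small_pairs, refs, elements, repeats)


def make_element(
    eid="L1_X", chrom="chrT", start=10_000, end=16_000, strand="+",
    subfamily="L1PA1", has_asp=True,
):
    """Element with consensus fields chosen to give the requested ASP state."""
    return reference.L1Element(
        id=eid, chrom=chrom, start=start, end=end, strand=strand,
        subfamily=subfamily,
        consensus_5p_offset=0 if has_asp else 500,
        consensus_end=6000 if has_asp else 550,
    )
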
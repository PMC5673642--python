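import numpy as np
import pytest

from limnobin._codes import decode
from limnobin.io_core import SequenceRecord
from limnobin.synthetic import (CommunityDesign, GenomeSpec, simulate_community,
                                simulate_reference_db)


def random_seq(rng, n: int) -> str:
    return decode(rng.integers(0, 4, n).astype(np.uint8))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def ref_db():
    """64-reference synthetic 16S set over 8 taxa."""
    return simulate_reference_db(seed=3)


@pytest.fixture(scope="session")
def small_genome():
    spec = GenomeSpec("Gsmall", 100_000, 0.5, 21, "Verrucomicrobia")
    from limnobin.synthetic import simulate_genome

    return simulate_genome(spec)[0]


@pytest.fixture(scope="session")
def community():
    """Three target genomes at distinct composition/GC/coverage, one sample."""
    specs = [
        GenomeSpec("G1", 400_000, 0.45, 101, "Verrucomicrobia", n_16s_copies=1),
        GenomeSpec("G2", 400_000, 0.52, 202, "Verrucomicrobia", n_16s_copies=1),
        GenomeSpec("G3", 400_000, 0.60, 303, "Verrucomicrobia", n_16s_copies=1),
    ]
    design = CommunityDesign(
        specs, coverage=[[2.0], [4.0], [8.0]], read_length_bp=100,
        per_base_error=0.005, seed=17,
    )
    return simulate_community(design)


@pytest.fixture(scope="session")
def community_coverage(community):
    """Per-contig depth of the community's single sample, via recruitment."""
    from limnobin.binning import coverage_estimate
    from limnobin.recruitment import recruit

    n, hits = recruit(community.reads["S1"], community.contigs)
    per_contig = {}
    for h in hits:
        per_contig.setdefault(h.subject_id, []).append(h)
    return {
        "S1": {
            c.id: coverage_estimate(len(c), per_contig.get(c.id, []))
            for c in community.contigs
        }
    }
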
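import numpy as np
import pytest

from mirproc.intervals import GenomicInterval
from mirproc.hairpin import HairpinLocus
from mirproc.quantify import AlignedRead
from mirproc.simulate import SimConfig, simulate_condition, simulate_reference


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(n_loci=6, n_replicates=2, library_size=3000,
                     mirtron_loci=1, cluster_loci=1, multimap_dup=1, seed=11)


@pytest.fixture(scope="session")
def small_ref(small_cfg):
    return simulate_reference(small_cfg)


@pytest.fixture(scope="session")
def small_readsets(small_cfg, small_ref):
    return {cond: simulate_condition(small_ref, small_cfg, cond)
            for cond in ("wt", "mutant")}


@pytest.fixture()
def toy_hairpin():
    """60-nt plus-strand hairpin: mature 5p = 1..22, mature 3p = 39..60."""
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGU"), size=60))
    return HairpinLocus(
        id="toy-mir", interval=GenomicInterval("chrT", 1000, 1060, "+"),
        sequence=seq, mature5p=(1, 22), mature3p=(39, 60),
    )


def make_read(chrom, start, end, strand="+", n_hits=1, rid=None, sample="s1"):
    iv = GenomicInterval(chrom, start, end, strand)
    return AlignedRead(rid or f"r{start}_{end}", sample, end - start, [iv], n_hits)
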
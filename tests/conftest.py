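import numpy as np
import pytest

from poolscan.poolio import SiteCounts


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_site(chrom="chrI", pos=100, ref="A", pools=(), dels=None):
    """Build a SiteCounts from per-pool {base: count} dicts."""
    counts = np.zeros((len(pools), 4), dtype=np.int64)
    for p, mapping in enumerate(pools):
        for base, n in mapping.items():
            counts[p, "ACGT".index(base)] = n
    return SiteCounts(chrom=chrom, pos=pos, ref=ref, counts=counts, dels=dels)


@pytest.fixture
def random_sites(rng):
    """300 random two-pool sites covering mono-, bi- and multi-allelic cases."""
    sites = []
    pos = 0
    for _ in range(300):
        pos += int(rng.integers(1, 50))
        kind = rng.integers(0, 4)
        counts = np.zeros((2, 4), dtype=np.int64)
        if kind == 0:  # monomorphic
            b = rng.integers(0, 4)
            counts[:, b] = rng.integers(0, 120, size=2)
        elif kind == 1:  # clean biallelic
            b1, b2 = rng.choice(4, size=2, replace=False)
            counts[:, b1] = rng.integers(0, 120, size=2)
            counts[:, b2] = rng.integers(0, 120, size=2)
        elif kind == 2:  # biallelic + trace third allele
            b1, b2, b3 = rng.choice(4, size=3, replace=False)
            counts[:, b1] = rng.integers(20, 120, size=2)
            counts[:, b2] = rng.integers(5, 120, size=2)
            counts[:, b3] = rng.integers(0, 4, size=2)
        else:  # anything
            counts[:] = rng.integers(0, 60, size=(2, 4))
        sites.append(
            SiteCounts(chrom="chrI", pos=pos, ref="ACGT"[rng.integers(0, 4)], counts=counts)
        )
    return sites


@pytest.fixture
def gff3_text():
    return (
        "##gff-version 3\n"
        "chrI\tsrc\tgene\t100\t500\t.\t+\t.\tID=g1;Name=bglap;description=bone development receptor\n"
        "chrI\tsrc\tmRNA\t100\t500\t.\t+\t.\tID=m1;Parent=g1\n"
        "chrI\tsrc\texon\t100\t200\t.\t+\t.\tID=e1;Parent=m1\n"
        "chrI\tsrc\tgene\t600\t900\t.\t-\t.\tID=g2;Name=wls;Ontology_term=wnt/beta-catenin signaling\n"
        "chrII\tsrc\tgene\t50\t90\t.\t+\t.\tID=g3\n"
    )
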
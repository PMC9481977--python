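import numpy as np
import pytest

from promdir.annotation import GeneRecord
from promdir.coverage import StrandedCoverage


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def small_chrom_sizes():
    return {"chrI": 10_000, "chrII": 5_000}


@pytest.fixture
def empty_coverage(small_chrom_sizes):
    return StrandedCoverage.zeros(small_chrom_sizes)


def make_gene(gid="g1", chrom="chrI", start=1000, end=2000, strand="+",
              tss=None):
    kwargs = dict(chrom=chrom, start=start, gene_id=gid, end=end,
                  strand=strand)
    if tss is not None:
        kwargs["tss"] = tss
    return GeneRecord(**kwargs)


@pytest.fixture
def plus_gene():
    return make_gene("gplus", start=1000, end=2000, strand="+")


@pytest.fixture
def minus_gene():
    return make_gene("gminus", start=3000, end=4000, strand="-")


def random_fragments(rng, chrom_sizes, n=1000, max_len=150):
    """Random strand-annotated fragments within chromosome bounds."""
    chroms = list(chrom_sizes)
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        size = chrom_sizes[chrom]
        length = int(rng.integers(1, max_len))
        start = int(rng.integers(0, size - length))
        strand = "+" if rng.random() < 0.5 else "-"
        out.append((chrom, start, start + length, strand))
    return out


def brute_force_end_tally(fragments, chrom_sizes, end_convention="3prime",
                          library_strandness="forward"):
    """Naive per-fragment oracle for end-coverage accumulation."""
    flip = {"+": "-", "-": "+"}
    tally = {c: {"+": np.zeros(n), "-": np.zeros(n)}
             for c, n in chrom_sizes.items()}
    for chrom, start, end, strand in fragments:
        ts = strand if library_strandness == "forward" else flip[strand]
        if end_convention == "3prime":
            pos = end - 1 if ts == "+" else start
        else:
            pos = start if ts == "+" else end - 1
        tally[chrom][ts][pos] += 1
    return tally
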
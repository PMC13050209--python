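import numpy as np
import pandas as pd
import pytest

from lohkit.calls_io import GenomeMeta, Genotype, SiteCall, telomere_mask
from lohkit.dual_reference import FamilyMatrix, MarkerSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_meta():
    meta = GenomeMeta(
        chrom_lengths={"chr1": 500_000, "chr2": 400_000},
        centromeres={"chr1": 200_000, "chr2": 150_000},
    )
    meta.add_masks(telomere_mask(meta.chrom_lengths, 7500))
    return meta


def make_call(
    chrom="chr1",
    pos=100_000,
    genotype=Genotype.HET,
    gq=99.0,
    qual=5000.0,
    depth=60,
    ad=(30, 30),
    qd=20.0,
    mq=60.0,
    fs=1.0,
    sor=1.0,
):
    return SiteCall(
        chrom=chrom,
        pos=pos,
        alleles=("A", "C"),
        genotype=genotype,
        gq=gq,
        site_qual=qual,
        depth=depth,
        allele_depths=ad,
        annotations={"QD": qd, "MQ": mq, "FS": fs, "SOR": sor},
    )


@pytest.fixture
def call_factory():
    return make_call


def make_marker_set(positions, chrom="chr1"):
    return MarkerSet(
        pd.DataFrame(
            {
                "chrom": chrom,
                "pos": positions,
                "p1_allele": "A",
                "p2_allele": "C",
            }
        )
    )


@pytest.fixture
def marker_set_factory():
    return make_marker_set


def make_family(genotype_matrix, founder="F", positions=None, gq=None):
    g = np.asarray(genotype_matrix, dtype=np.int8)
    n_m, n_c = g.shape
    if positions is None:
        positions = 1000 * (np.arange(n_m) + 1)
    clones = ([founder] if founder else []) + [
        f"c{i}" for i in range(n_c - (1 if founder else 0))
    ]
    if gq is None:
        gq = np.full(g.shape, 99.0)
    return FamilyMatrix(
        markers=make_marker_set(positions),
        clones=clones,
        genotypes=g,
        gq=gq,
        founder=founder,
    )


@pytest.fixture
def family_factory():
    return make_family
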
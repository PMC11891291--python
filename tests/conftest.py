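import numpy as np
import pandas as pd
import pytest

from germtherm.config import SimulationConfig
from germtherm.filtering import VariantTable
from germtherm.relatedness import compute_grm
from germtherm.simulate import simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small structured cohort shared by read-only tests."""
    cfg = SimulationConfig(
        n_accessions=30, n_snps=200, seeds_per_cell=8, rng_seed=11
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_grm(small_cohort):
    return compute_grm(small_cohort.genotypes)


def make_variant_table(
    pos,
    chrom="A01",
    mq=60.0,
    is_indel=False,
    dp=50,
    ad=(25, 25),
    alt=("T",),
    n_accessions=3,
):
    """Build a uniform VariantTable for filter unit tests."""
    m = len(pos)

    def expand(val, dtype=None):
        arr = np.asarray(val if np.ndim(val) else [val] * m)
        return arr.astype(dtype) if dtype else arr

    chroms = expand(chrom, object) if np.ndim(chrom) else np.array([chrom] * m, object)
    mqs = expand(mq, float)
    indels = expand(is_indel, bool)
    alts = alt if isinstance(alt, list) else [tuple(alt)] * m
    dps = np.asarray(dp) if np.ndim(dp) == 2 else np.full((m, n_accessions), dp)
    if np.ndim(ad) == 3:
        ad_ref, ad_alt = np.asarray(ad)[..., 0], np.asarray(ad)[..., 1]
    else:
        ad_ref = np.full((m, n_accessions), ad[0])
        ad_alt = np.full((m, n_accessions), ad[1])
    return VariantTable(
        chrom=chroms,
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.array(["A"] * m, object),
        alt=list(alts),
        mq=mqs,
        is_indel=indels,
        ad_ref=ad_ref.astype(np.int64),
        ad_alt=ad_alt.astype(np.int64),
        dp=dps.astype(np.int64),
        dosage=np.ones((m, n_accessions), dtype=np.int8),
        accession_ids=[f"s{i}" for i in range(n_accessions)],
    )


@pytest.fixture()
def variant_table_factory():
    return make_variant_table
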
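import numpy as np
import pytest

from mrkit.harmonize import HarmonizedVariant
from mrkit.io import SnpAssociation, SummaryTable

ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]


def make_assoc(
    rsid="rs1",
    effect_allele="A",
    other_allele="G",
    eaf=0.3,
    beta=0.1,
    se=0.01,
    pvalue=1e-10,
    n=10000,
    trait_id="trait",
):
    return SnpAssociation(
        rsid=rsid,
        effect_allele=effect_allele,
        other_allele=other_allele,
        eaf=eaf,
        beta=beta,
        se=se,
        pvalue=pvalue,
        n=n,
        trait_id=trait_id,
    )


def make_table(records, trait_id="trait"):
    return SummaryTable(records=list(records), trait_id=trait_id)


def make_variant(rsid="rs1", bx=0.1, se_bx=0.01, by=0.05, se_by=0.01,
                 eaf_x=0.3, eaf_y=0.3, status="aligned"):
    return HarmonizedVariant(
        rsid=rsid, effect_allele="A", other_allele="G",
        bx=bx, se_bx=se_bx, by=by, se_by=se_by,
        eaf_exposure=eaf_x, eaf_outcome=eaf_y, status=status,
    )


def make_variants(bx, by, se_bx=None, se_by=None):
    """HarmonizedVariant list from plain arrays, for estimator tests."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    se_bx = np.full_like(bx, 0.01) if se_bx is None else np.asarray(se_bx, dtype=float)
    se_by = np.full_like(by, 0.01) if se_by is None else np.asarray(se_by, dtype=float)
    return [
        make_variant(rsid=f"rs{i}", bx=bx[i], se_bx=se_bx[i], by=by[i], se_by=se_by[i])
        for i in range(len(bx))
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def five_snp_table():
    """Five SNPs: two fail the p filter, three are genome-wide significant."""
    return make_table(
        [
            make_assoc(rsid="rs1", pvalue=1e-12),
            make_assoc(rsid="rs2", effect_allele="T", other_allele="C", pvalue=1e-9),
            make_assoc(rsid="rs3", effect_allele="A", other_allele="C", pvalue=2e-8),
            make_assoc(rsid="rs4", pvalue=1e-7),
            make_assoc(rsid="rs5", effect_allele="T", other_allele="G", pvalue=0.5),
        ]
    )
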
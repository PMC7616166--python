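import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sexmr.io import CANONICAL_COLUMNS, SummaryStats

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.filter_too_much],
)
settings.load_profile("suite")


def snp_row(
    rsid="rs1",
    chrom="1",
    pos=1000,
    effect_allele="A",
    other_allele="G",
    eaf=0.3,
    beta=0.1,
    se=0.01,
    pvalue=1e-10,
    n=100_000,
):
    return dict(
        rsid=rsid,
        chrom=chrom,
        pos=pos,
        effect_allele=effect_allele,
        other_allele=other_allele,
        eaf=eaf,
        beta=beta,
        se=se,
        pvalue=pvalue,
        n=n,
    )


def build_stats(rows, trait="exposure", unit="SD", sex="female"):
    df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
    return SummaryStats(trait=trait, unit=unit, sex=sex, df=df)


@pytest.fixture
def make_stats():
    return build_stats


@pytest.fixture
def rng():
    return np.random.default_rng(20240730)
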
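import numpy as np
import pytest

from mrkit import HarmonizedInstrument, SnpAssociation, WaldEstimate


def make_instrument(
    rsid="rs1", g=0.1, sg=0.02, G=0.05, sG=0.02, eaf_exp=0.3, eaf_out=0.3
) -> HarmonizedInstrument:
    return HarmonizedInstrument(
        rsid=rsid,
        beta_exposure=g,
        se_exposure=sg,
        beta_outcome=G,
        se_outcome=sG,
        eaf_exposure=eaf_exp,
        eaf_outcome=eaf_out,
    )


def random_instruments(rng, n=8, beta=0.3, pleiotropy_sd=0.0):
    """Instrument sets with exact linear structure plus optional direct effects."""
    g = rng.uniform(0.05, 0.3, n) * rng.choice([-1, 1], n)
    sg = rng.uniform(0.005, 0.02, n)
    sG = rng.uniform(0.01, 0.05, n)
    alpha = rng.normal(0, pleiotropy_sd, n) if pleiotropy_sd else np.zeros(n)
    G = beta * g + alpha + rng.normal(0, sG)
    return [
        make_instrument(f"rs{i}", g[i], sg[i], G[i], sG[i]) for i in range(n)
    ]


def make_snp(rsid="rs1", a1="A", a2="G", eaf=0.3, beta=0.1, se=0.02, p=1e-9, n=7827):
    return SnpAssociation(
        rsid=rsid, effect_allele=a1, other_allele=a2, eaf=eaf,
        beta=beta, se=se, pvalue=p, n=n,
    )


def make_ratio(rsid="rs1", ratio=0.5, se=0.2) -> WaldEstimate:
    return WaldEstimate(rsid=rsid, ratio=ratio, se_ratio=se)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
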
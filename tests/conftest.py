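import numpy as np
import pandas as pd
import pytest

from gsemkit.ldsc import LdScoreTable
from gsemkit.sumstats import MungedTrait, ReferencePanel
from gsemkit.synthgen import (
    SyntheticTruth, TraitSpec, simulate_ld_scores, simulate_sumstats,
)


@pytest.fixture(scope="session")
def ld20k() -> LdScoreTable:
    """Shared desk-scale LD score table (M = 20 000)."""
    return simulate_ld_scores(20_000, seed=1)


@pytest.fixture(scope="session")
def ld5k() -> LdScoreTable:
    return simulate_ld_scores(5_000, seed=2)


@pytest.fixture
def small_panel() -> ReferencePanel:
    return ReferencePanel(pd.DataFrame({
        "SNP": ["rs1", "rs2", "rs3", "rs4", "rs5"],
        "CHR": [1, 1, 1, 2, 2],
        "BP": [1000, 2000, 3000, 1000, 2000],
        "A1": ["A", "C", "A", "T", "G"],
        "A2": ["G", "T", "G", "C", "A"],
    }))


def simulate_pair(ld, h2_a, h2_b, rg, n=50_000.0, seed=0, overlap=None,
                  pheno_corr=None) -> list[MungedTrait]:
    """Two-trait synthetic study with the given heritabilities and rg."""
    truth = SyntheticTruth(
        traits=[TraitSpec("A", h2_a, n), TraitSpec("B", h2_b, n)],
        R_true=np.array([[1.0, rg], [rg, 1.0]]),
        M=int(ld.m_total), seed=seed, overlap=overlap, pheno_corr=pheno_corr,
    )
    return simulate_sumstats(truth, ld)
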
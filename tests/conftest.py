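import numpy as np
import pandas as pd
import pytest

from brainsig import SyntheticConfig, simulate_study
from brainsig.correlate import RankedList


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """A fast study: fewer genes/samples, same structure as the default."""
    return SyntheticConfig(n_donors=3, n_genes=300, probes_per_gene=2,
                           n_samples_per_donor_per_compartment=40,
                           n_planted_per_sign=15, n_gene_sets=12,
                           n_planted_sets=3, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return simulate_study(small_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def make_ranked(scores, genes=None) -> RankedList:
    """RankedList from scores already in descending order."""
    scores = np.asarray(scores, float)
    assert np.all(np.diff(scores) <= 0), "scores must be descending"
    genes = list(genes) if genes is not None else [
        f"g{i+1}" for i in range(len(scores))]
    tab = pd.DataFrame({"gene_id": genes, "mean_r": scores,
                        "n_donors_used": 4})
    return RankedList(table=tab, n_positive=int((scores > 0).sum()),
                      n_negative=int((scores < 0).sum()))
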
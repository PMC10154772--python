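import numpy as np
import pandas as pd
import pytest

from paleogen.genotypes import GenotypeMatrix
from paleogen.simulate import ObservationSet, SNPPanel, simulate_panel


@pytest.fixture
def small_panel() -> SNPPanel:
    return simulate_panel(200, transition_fraction=0.8, seed=11)


@pytest.fixture
def tiny_panel() -> SNPPanel:
    """Fixed 4-SNP panel: two transitions, two transversions."""
    return SNPPanel(
        snp_id=np.array(["s1", "s2", "s3", "s4"], dtype=object),
        chromosome=np.array([1, 1, 1, 1]),
        position=np.array([100, 200, 300, 400]),
        ref=np.array(["C", "A", "A", "G"]),
        alt=np.array(["T", "G", "C", "T"]),
    )


def make_obs(rows) -> ObservationSet:
    """Build an ObservationSet from (snp_index, sample, base, bq, fraglen,
    dist5) tuples; dist3 derived."""
    df = pd.DataFrame(
        rows,
        columns=["snp_index", "sample_id", "base", "base_quality",
                 "fragment_length", "dist5"],
    )
    df["dist3"] = df["fragment_length"] + 1 - df["dist5"]
    df["sample_id"] = df["sample_id"].astype(object)
    return ObservationSet(df)


@pytest.fixture
def obs_factory():
    return make_obs


def make_matrix(counts, panel, ploidy="diploid", samples=None):
    counts = np.asarray(counts, dtype=np.int8)
    n = counts.shape[0]
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    return GenotypeMatrix(
        samples=samples,
        panel=panel,
        counts=counts,
        ploidy=np.array([ploidy] * n, dtype=object),
    )


@pytest.fixture
def matrix_factory():
    return make_matrix
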
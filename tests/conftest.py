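import math

import numpy as np
import pytest

from ryupop.coalescent_sim import HaplotypePanel
from ryupop.demographic_model import DemographicModel, Epoch, SplitEvent, build_fitted_model


def single_deme(n: float) -> DemographicModel:
    return DemographicModel(
        demes={"A": [Epoch(0, math.inf, n)]}, splits=[], migrations=[]
    )


def two_deme_split(t: float, n: float, n_anc: float | None = None) -> DemographicModel:
    """Two demes splitting from a common ancestor t generations ago."""
    n_anc = n if n_anc is None else n_anc
    return DemographicModel(
        demes={
            "A": [Epoch(0, t, n)],
            "B": [Epoch(0, t, n)],
            "ANC": [Epoch(t, math.inf, n_anc)],
        },
        splits=[SplitEvent(t, "A", "ANC"), SplitEvent(t, "B", "ANC")],
        migrations=[],
    )


@pytest.fixture(scope="session")
def fitted_model():
    return build_fitted_model()


def make_panel(haplotypes, spacing_cM=0.01, populations=None, chrom="1"):
    """Panel from a raw 0/1 haplotype matrix with evenly spaced sites."""
    H = np.asarray(haplotypes, dtype=np.int8)
    n_hap, S = H.shape
    assert n_hap % 2 == 0
    n = n_hap // 2
    pos_cm = np.arange(S) * spacing_cM
    pos_bp = (pos_cm * 1e6).astype(np.int64) + 1
    return HaplotypePanel(
        samples=[f"s{i}" for i in range(n)],
        populations=populations or ["P"] * n,
        haplotypes=H,
        pos_bp=pos_bp,
        pos_cM=pos_cm,
        chrom=chrom,
    )
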
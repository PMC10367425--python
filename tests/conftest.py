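import numpy as np
import pandas as pd
import pytest

from mucosanet.synthetic import SyntheticTruth, generate_cohort
from mucosanet.tables import OmicLayerTable


def make_layer(values, layer_id="cytokine", lod=None, mask=None, participants=None):
    """Small helper to build a layer table from a plain array/dict."""
    df = pd.DataFrame(values)
    if participants is not None:
        df.index = participants
    else:
        df.index = [f"P{i + 1}" for i in range(len(df))]
    lod_s = pd.Series(lod) if lod is not None else None
    mask_df = (
        pd.DataFrame(mask, index=df.index, columns=df.columns) if mask is not None else None
    )
    return OmicLayerTable(layer_id, df, lod=lod_s, missing_mask=mask_df)


@pytest.fixture(scope="session")
def small_truth():
    """A full-structure but lightweight synthetic configuration."""
    return SyntheticTruth.with_default_effects(
        n_host_proteins=30, n_metabolites=20, n_bact_proteins=80,
        n_extra_cytokines=5, seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_truth):
    return generate_cohort(small_truth)


@pytest.fixture(scope="session")
def default_cohort():
    """Default-sized cohort (43 participants, full layer sizes)."""
    return generate_cohort(SyntheticTruth.with_default_effects(seed=7))
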
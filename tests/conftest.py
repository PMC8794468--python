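import numpy as np
import pandas as pd
import pytest

from lipidims.dims import FeatureTable, META_COLUMNS
from lipidims.library import (build_intact_library, default_intact_specs,
                              enumerate_fatty_acids, group_isobars)


@pytest.fixture(scope="session")
def positive_library():
    """Built-in positive-mode intact-lipid library with isobar groups."""
    lib = build_intact_library(default_intact_specs("positive"),
                               ["[M+H]+", "[M+Na]+", "[M+NH4]+"])
    return group_isobars(lib, 9.0)


@pytest.fixture(scope="session")
def fa_library():
    return group_isobars(enumerate_fatty_acids(), 12.5)


def make_table(values, meta=None, snr=None, feature_meta=None):
    """Assemble a FeatureTable from a plain samples x features DataFrame."""
    values = pd.DataFrame(values)
    values.index = values.index.astype(str)
    if meta is None:
        meta = pd.DataFrame(index=values.index, columns=META_COLUMNS)
    else:
        meta = pd.DataFrame(meta, index=values.index)
        for col in META_COLUMNS:
            if col not in meta.columns:
                meta[col] = np.nan
        meta = meta[META_COLUMNS]
    features = pd.DataFrame(index=values.columns)
    features["mz"] = np.arange(len(values.columns), dtype=float) + 100.0
    features["label"] = features.index
    features["class_code"] = None
    features["double_bonds"] = np.nan
    features["hydroxyls"] = np.nan
    features["adduct"] = None
    features["annotated"] = False
    features["isobar_group"] = np.nan
    features["top_annotation"] = None
    if feature_meta is not None:
        for col, vals in feature_meta.items():
            features[col] = vals
    snr_frame = None
    if snr is not None:
        snr_frame = pd.DataFrame(snr, index=values.index, columns=values.columns)
    return FeatureTable(values, features, meta, snr_frame)
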
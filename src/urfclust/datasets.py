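"""Bundled example data."""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .matrix import FeatureMatrix


def load_iris() -> tuple[FeatureMatrix, np.ndarray]:
    """Fisher's iris measurements (150 samples, 4 features, 3 species).

    Returns the feature matrix and integer species labels (0 setosa,
    1 versicolor, 2 virginica) — the classic sanity check for whether a
    clustering recovers known classes.
    """
    with resources.files("urfclust.data").joinpath("iris.csv").open() as fh:
        df = pd.read_csv(fh, index_col=0)
    species = df.pop("species")
    labels = pd.Categorical(species, categories=["setosa", "versicolor", "virginica"]).codes
    return FeatureMatrix.from_dataframe(df), np.asarray(labels, np.int64)
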
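"""The 69-entry feature catalog.

The catalog CSV shipped with the package (``data/feature_catalog.csv``) is
the single source of truth for feature names and order: morphometry
aggregates, tissue-architecture features, then graph-based proximity
features.  Loading validates that the CSV agrees with the names the computing
modules emit and that there are exactly 69 entries.
"""

from __future__ import annotations

import functools
from importlib import resources

import pandas as pd

from .io import ValidationError

__all__ = ["feature_catalog", "catalog_table", "N_FEATURES"]

N_FEATURES = 69


@functools.lru_cache(maxsize=1)
def catalog_table() -> pd.DataFrame:
    """Full catalog with columns (name, family, units, aggregation, module)."""
    with resources.files("histogate.data").joinpath("feature_catalog.csv").open() as fh:
        df = pd.read_csv(fh)
    from .morphometry import MORPHOMETRY_FEATURES
    from .neighborhood import NEIGHBORHOOD_FEATURES
    from .stroma import TISSUE_FEATURES

    expected = MORPHOMETRY_FEATURES + TISSUE_FEATURES + NEIGHBORHOOD_FEATURES
    names = df["name"].tolist()
    if len(names) != N_FEATURES:
        raise ValidationError(f"catalog must have {N_FEATURES} entries, found {len(names)}")
    if names != expected:
        raise ValidationError("catalog CSV disagrees with the computing modules")
    return df


def feature_catalog() -> list[str]:
    """Ordered catalog feature names (always 69)."""
    return catalog_table()["name"].tolist()
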
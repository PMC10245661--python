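import numpy as np
import pandas as pd
import pytest

from spatiomic.community import OtuTable


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_table(rng, n_samples=6, n_taxa=8, depth=200) -> OtuTable:
    """Random multinomial OTU table with lognormal taxon weights."""
    w = rng.lognormal(0, 1, n_taxa)
    counts = np.vstack([rng.multinomial(depth, w / w.sum()) for _ in range(n_samples)])
    # guarantee non-empty rows
    counts[:, 0] += 1
    return OtuTable(
        [f"s{i}" for i in range(n_samples)],
        [f"t{j}" for j in range(n_taxa)],
        counts,
    )


def grid_metadata(n, start="2018-05-01") -> pd.DataFrame:
    """Minimal single-site metadata for n samples on a line."""
    import datetime as dt

    d0 = dt.date.fromisoformat(start)
    return pd.DataFrame(
        {
            "niche": "soil",
            "site": "S1",
            "plot": "S1P1",
            "subplot": "S1P1-control",
            "n_treatment": "control",
            "collection_date": [d0] * n,
            "easting": np.arange(n, dtype=float),
            "northing": 0.0,
        },
        index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
    )
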
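import numpy as np
import pandas as pd
import pytest

from arcticiso import FluxSeries, SitePFT


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def sedge_willow_pfts():
    """Unfitted PFT pair matching the synthetic-site configuration."""
    return [
        SitePFT("sedge", 12.0, "sedge"),
        SitePFT("willow_shrub", 6.5, "willow"),
    ]


def make_series(
    n=48,
    t=303.15,
    t24=297.15,
    t240=297.15,
    ppfd=1000.0,
    lai=1.0,
    flux=None,
    start="2021-07-01",
):
    """Small FluxSeries with acclimation columns supplied directly."""
    index = pd.date_range(start, periods=n, freq="30min")
    df = pd.DataFrame(
        {
            "t_air": np.broadcast_to(t, n).astype(float),
            "ppfd": np.broadcast_to(ppfd, n).astype(float),
            "lai": np.broadcast_to(lai, n).astype(float),
            "t24": np.broadcast_to(t24, n).astype(float),
            "t240": np.broadcast_to(t240, n).astype(float),
        },
        index=index,
    )
    if flux is not None:
        df["flux"] = np.broadcast_to(flux, n).astype(float)
    return FluxSeries(df)
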
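import numpy as np
import pytest

from pulsewalk.synth import SignalParams, default_montage
from pulsewalk.types import Montage


def small_montage(n_pairs: int = 2) -> Montage:
    """First n source-detector pairs of the default montage (both wavelengths)."""
    full = default_montage().table
    sources = full["source_id"].drop_duplicates().head(n_pairs)
    return Montage(full[full["source_id"].isin(sources)])


@pytest.fixture
def montage2() -> Montage:
    return small_montage(2)


@pytest.fixture
def fast_params(montage2) -> SignalParams:
    """Small, quick-to-simulate recording parameters."""
    return SignalParams(montage=montage2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
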
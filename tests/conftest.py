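import numpy as np
import pytest

from segfuse import ClassCatalog, LabelMask, default_catalog


@pytest.fixture(scope="session")
def catalog() -> ClassCatalog:
    return default_catalog()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240903)


def make_mask(grid, catalog) -> LabelMask:
    return LabelMask(grid=np.asarray(grid, dtype=np.uint8), catalog=catalog)


def random_mask(rng, catalog, height=16, width=16) -> LabelMask:
    grid = rng.integers(0, len(catalog), size=(height, width), dtype=np.uint8)
    return LabelMask(grid=grid, catalog=catalog)
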
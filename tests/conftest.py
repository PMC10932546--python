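import numpy as np
import pytest

from pcdhgamma import DEFAULT_REGISTRY, BinaryExpressionMatrix, IsoformCountMatrix


@pytest.fixture
def registry():
    return DEFAULT_REGISTRY


@pytest.fixture
def make_counts(registry):
    """Build an IsoformCountMatrix from a dict {barcode: {isoform: count}}."""

    def _make(spec: dict) -> IsoformCountMatrix:
        cells = list(spec)
        counts = np.zeros((len(cells), registry.n_isoforms), dtype=np.int64)
        for i, cell in enumerate(cells):
            for isoform, c in spec[cell].items():
                counts[i, registry.index(isoform)] = c
        return IsoformCountMatrix(cell_ids=cells, registry=registry, counts=counts)

    return _make


@pytest.fixture
def make_binary(registry):
    """Build a BinaryExpressionMatrix from {barcode: set of expressed isoforms}."""

    def _make(spec: dict) -> BinaryExpressionMatrix:
        cells = list(spec)
        expressed = np.zeros((len(cells), registry.n_isoforms), dtype=bool)
        for i, cell in enumerate(cells):
            for isoform in spec[cell]:
                expressed[i, registry.index(isoform)] = True
        return BinaryExpressionMatrix(cell_ids=cells, registry=registry,
                                      expressed=expressed)

    return _make
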
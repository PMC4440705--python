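import numpy as np
import pytest

from mitoqc import CellState, Mitochondrion, QCParams, Subcompartment, build_default_geometry


@pytest.fixture(scope="session")
def nominal() -> QCParams:
    return QCParams.nominal()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_cell(*mitos, t=0.0) -> CellState:
    """Cell from (chain, compartment) tuples; chain = list of (W, M)."""
    graph = build_default_geometry()
    population = [
        Mitochondrion(
            chain=[Subcompartment(w, m) for w, m in chain], compartment=comp
        )
        for chain, comp in mitos
    ]
    return CellState(graph=graph, mitochondria=population, t=t)


@pytest.fixture()
def small_cell() -> CellState:
    """Two mitochondria, (W=3,M=1) and (W=4,M=0), in adjacent compartments."""
    return make_cell(([(3, 1)], 0), ([(4, 0)], 1))
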
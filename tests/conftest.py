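import numpy as np
import pytest

from platesim.core import CellState, CellTypeParams, PlateState, TransitionSpec
from platesim.scenarios import default_cell_type


@pytest.fixture
def nih3t3() -> CellTypeParams:
    return default_cell_type("NIH3T3")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def empty_plate() -> PlateState:
    return PlateState(width=1000.0, height=1000.0)


def make_cell(cid=1, pos=(500.0, 500.0), volume=1400.0, phase="G1", **kw) -> CellState:
    return CellState(id=cid, pos=pos, volume=volume, cycle_phase=phase, **kw)


def single_edge_params(from_phase, to_phase, base_prob, prob_time, factors=()) -> CellTypeParams:
    """A minimal cell type with exactly one cycle edge and no growth."""
    p = default_cell_type("NIH3T3")
    p.transitions = [TransitionSpec(from_phase, to_phase, base_prob, prob_time, tuple(factors))]
    p.alpha_growth = {}
    return p
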
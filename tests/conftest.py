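import numpy as np
import pytest

from otogrid import CellParams, GridSpec, ParameterSet


@pytest.fixture(scope="session")
def params():
    return ParameterSet()


@pytest.fixture
def single_grid():
    return GridSpec(n_rows=1, n_cols=1)


@pytest.fixture
def small_grid():
    return GridSpec(n_rows=3, n_cols=3)


@pytest.fixture
def oscillatory_cell(params):
    """A single bundle poised well inside the oscillatory regime."""
    return CellParams.from_feedback(
        a0=np.array([1.0]), f_max=np.array([300e-12]), S=np.array([1.6]), params=params
    )


@pytest.fixture
def passive_cells():
    """Motor-disabled bundles (f_max = 0) for thermal baselines."""

    def make(n, params):
        return CellParams.from_feedback(
            a0=np.ones(n), f_max=np.zeros(n), S=np.zeros(n), params=params
        )

    return make


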
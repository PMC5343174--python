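import io

import pytest

from opticlust.pair_io import read_column_distances

TOY_COLUMN = "A B 0.02\nB C 0.01\nA C 0.05\nA D 0.20\nB D 0.21\nC D 0.22\n"


@pytest.fixture
def toy_graph():
    """Four sequences with close pairs (A,B) and (B,C); optimum is {A,B,C} | {D}."""
    return read_column_distances(io.StringIO(TOY_COLUMN), 0.03)
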
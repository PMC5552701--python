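import numpy as np
import pandas as pd
import pytest

from mapforge.rilsim import GenotypeMatrix, SimConfig, TrueMap, simulate_true_map


@pytest.fixture
def two_marker_truemap():
    """One chromosome, two markers at a fixed 10 cM spacing."""
    markers = pd.DataFrame({
        "marker": ["m1", "m2"], "chromosome": ["1A", "1A"],
        "position_cM": [0.0, 10.0], "genome": ["A", "A"], "group": [1, 1],
    })
    return TrueMap([("1A", 20.0)], markers)


@pytest.fixture
def small_truemap():
    return simulate_true_map({"1A": 100.0, "2A": 100.0}, 25, seed=11)


@pytest.fixture
def small_panel_config():
    return SimConfig(n_lines=150, n_populations=2, seed=11,
                     missing_rate=0.05, error_rate=0.005,
                     population_marker_fraction=0.8)


def matrix_from_strings(rows: dict[str, str]) -> GenotypeMatrix:
    """Build a GenotypeMatrix from {marker: 'AABB-H...'} call strings."""
    from mapforge.rilsim import CHAR_TO_CODE

    markers = list(rows)
    n_lines = len(next(iter(rows.values())))
    calls = np.array([[CHAR_TO_CODE[c] for c in rows[m]] for m in markers],
                     dtype=np.int8)
    return GenotypeMatrix(markers, [f"L{i}" for i in range(n_lines)], calls)
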
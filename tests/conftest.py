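import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_screen_df():
    """One combo well plus its two monotherapy margins (single replicate)."""
    return pd.DataFrame({
        "cell_line": ["L1"] * 3,
        "drug_a": ["A"] * 3,
        "drug_b": ["B"] * 3,
        "conc_a": [1.0, 0.0, 1.0],
        "conc_b": [0.0, 2.0, 2.0],
        "replicate": [1, 1, 1],
        "viability": [0.8, 0.7, 0.4],
    })


@pytest.fixture
def tiny_screen_csv(tiny_screen_df, tmp_path):
    path = tmp_path / "screen.csv"
    tiny_screen_df.to_csv(path, index=False)
    return path


def make_matrix_from_fa(fa_a, fa_b, fa_combo, cell_line="L1", n_rep=1):
    """Build a diagonal DoseMatrix whose well-averaged Fa values are exactly
    the given arrays (viability = 1 - fa, no noise)."""
    from blisscreen.io import DoseMatrix

    fa_a, fa_b, fa_combo = map(np.asarray, (fa_a, fa_b, fa_combo))
    k = len(fa_a)
    conc = 10.0 / 4.0 ** np.arange(k)
    rows = []
    for rep in range(1, n_rep + 1):
        rows.append(pd.DataFrame({
            "cell_line": cell_line, "drug_a": "A", "drug_b": "B",
            "conc_a": np.concatenate([conc, np.zeros(k), conc]),
            "conc_b": np.concatenate([np.zeros(k), conc, conc]),
            "replicate": rep,
            "viability": np.concatenate([1 - fa_a, 1 - fa_b, 1 - fa_combo]),
        }))
    return DoseMatrix(cell_line, "A", "B", pd.concat(rows, ignore_index=True))
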
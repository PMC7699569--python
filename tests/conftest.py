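import numpy as np
import pandas as pd
import pytest

from panelmars import DesignMatrix, PanelDataset


@pytest.fixture
def tiny_frame() -> pd.DataFrame:
    """2 countries x 3 years x 2 variables, complete."""
    rows = []
    for c in ("AT", "BE"):
        for i, yr in enumerate((2000, 2001, 2002)):
            rows.append(
                {"country": c, "year": yr, "A": 1.0 + i, "B": 10.0 + i * (c == "BE")}
            )
    return pd.DataFrame(rows)


@pytest.fixture
def tiny_panel(tiny_frame) -> PanelDataset:
    return PanelDataset(tiny_frame)


def make_design(seed: int, n: int, names=("x1", "x2")) -> DesignMatrix:
    """Random uniform design with a zero response placeholder."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.0, 1.0, size=(n, len(names)))
    return DesignMatrix(
        np.zeros(n), X, [("s", i) for i in range(n)], list(names)
    )


def with_response(D: DesignMatrix, y: np.ndarray) -> DesignMatrix:
    return DesignMatrix(y, D.X, D.row_index, list(D.column_names))
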
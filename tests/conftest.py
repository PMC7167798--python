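import numpy as np
import pandas as pd
import pytest

from maridea import PanelDataset, ReferenceSet, panel_from_frame


@pytest.fixture
def tiny_crs_ref():
    """1-input/1-output CRS reference {A:(2,4), B:(4,4), C:(1,1)}."""
    return ReferenceSet(X=np.array([[2.0, 4.0, 1.0]]),
                        Y=np.array([[4.0, 4.0, 1.0]]),
                        rts="crs",
                        members=(("A", "t"), ("B", "t"), ("C", "t")))


@pytest.fixture
def small_panel():
    """3 DMUs x 2 periods, 1 input / 1 output, hand-set values."""
    frame = pd.DataFrame({
        "dmu": ["A", "B", "C"] * 2,
        "period": ["t1"] * 3 + ["t2"] * 3,
        "input:x": [2.0, 4.0, 1.0, 2.0, 4.0, 1.0],
        "output:y": [4.0, 4.0, 1.0, 5.0, 4.5, 1.5],
    })
    return panel_from_frame(frame)


def random_panel(rng: np.random.Generator, n: int, T: int, m: int, q: int) -> PanelDataset:
    """Unstructured positive panel for stress/property tests."""
    frame_rows = []
    for i in range(n):
        for t in range(T):
            row = {"dmu": f"D{i:02d}", "period": f"P{t:02d}"}
            row.update({f"input:x{k}": rng.uniform(0.5, 10.0) for k in range(m)})
            row.update({f"output:y{k}": rng.uniform(0.5, 10.0) for k in range(q)})
            frame_rows.append(row)
    return panel_from_frame(pd.DataFrame(frame_rows))
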
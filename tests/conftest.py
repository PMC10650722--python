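import numpy as np
import pandas as pd
import pytest

from epitof import CellMatrix, EpiTofSimConfig, MarkerPanel, simulate_epitof


@pytest.fixture(scope="session")
def small_panel() -> MarkerPanel:
    return MarkerPanel(hptm_markers=("M1", "M2", "M3"))


@pytest.fixture(scope="session")
def tiny_cells(small_panel) -> CellMatrix:
    """Hand-built 6-cell matrix over two samples for IO/normalization tests."""
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.lognormal(3.0, 0.5, size=(6, 5)),
        columns=["M1", "M2", "M3", "H3", "H4"])
    return CellMatrix(
        values=values,
        sample_id=pd.Series(["a", "a", "a", "b", "b", "b"]),
        group=pd.Series(["HCB", "HCB", "HCB", "JSP", "JSP", "JSP"]),
        panel=small_panel)


@pytest.fixture(scope="session")
def null_dataset():
    """One subpopulation, zero planted effects: every downstream test is null."""
    cfg = EpiTofSimConfig(n_samples_per_group=5, cells_per_sample=200,
                          n_subpops=1, seed=123)
    return simulate_epitof(cfg)
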
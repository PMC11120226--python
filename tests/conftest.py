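import numpy as np
import pandas as pd
import pytest

from modbarcode import (
    CenteredMatrix,
    CoexpressionModules,
    SyntheticDesign,
    generate,
)


@pytest.fixture(scope="session")
def default_dataset():
    """Canonical-seed cohort of the default planted-module design."""
    return generate(SyntheticDesign())


@pytest.fixture(scope="session")
def fitted(default_dataset):
    """Modules discovered on the canonical cohort (shared across tests)."""
    return CoexpressionModules(default_dataset.expression).fit()


def make_centered(rows: dict[str, np.ndarray]) -> CenteredMatrix:
    """Wrap raw per-gene profiles as an already-centered matrix for unit tests."""
    frame = pd.DataFrame(rows).T
    frame.columns = [f"S{j:03d}" for j in range(frame.shape[1])]
    zeros = pd.Series(0.0, index=frame.index)
    return CenteredMatrix(frame, medians=zeros, averages=zeros.copy())
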
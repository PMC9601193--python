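import numpy as np
import pandas as pd
import pytest

from effluxsig.peaks import PeakTable


def make_table(
    values: np.ndarray,
    groups: list[str] | None = None,
    metabolites: list[str] | None = None,
    normalized: bool = False,
) -> PeakTable:
    """Wrap a plain matrix as a PeakTable with generated ids."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    samples = [f"s{i+1}" for i in range(n)]
    metabolites = metabolites or [f"m{j+1}" for j in range(p)]
    groups = groups or ["treated"] * (n // 2) + ["control"] * (n - n // 2)
    df = pd.DataFrame(values, index=samples, columns=metabolites)
    return PeakTable(
        areas=df, groups=pd.Series(groups, index=samples), normalized=normalized
    )


@pytest.fixture
def two_class_table() -> PeakTable:
    """12 samples x 10 metabolites, positive log-normal, one separating variable."""
    rng = np.random.default_rng(42)
    x = rng.lognormal(mean=8.0, sigma=0.3, size=(12, 10))
    x[:6, 0] *= 3.0  # treated samples elevated in m1
    return make_table(x)


@pytest.fixture
def null_table() -> PeakTable:
    """12 x 20 log-normal table with no class structure."""
    rng = np.random.default_rng(7)
    return make_table(rng.lognormal(mean=9.0, sigma=0.4, size=(12, 20)))
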
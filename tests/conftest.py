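import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from mlcqsar import load_table2, load_table3
from mlcqsar.qsar import ModelSpec, QSARModel


@pytest.fixture(scope="session")
def table3() -> pd.DataFrame:
    """Packaged 65-compound descriptor/response table."""
    return load_table3()


@pytest.fixture(scope="session")
def table2() -> pd.DataFrame:
    """Packaged 65-compound Foley parameter table."""
    return load_table2()


M5_SPEC = ModelSpec("M5", "log_bb", ("log_km_over_kam", "hba", "nrb", "parachor_P"))


@pytest.fixture(scope="session")
def m5_results(table3):
    """Fitted shortlisted log BB model (lipophilicity + HBA + NRB + parachor)."""
    return QSARModel(M5_SPEC, table3).fit()


def brute_force_loo_press(y: np.ndarray, X: np.ndarray) -> float:
    """Independent leave-one-out PRESS oracle: refit OLS n times."""
    n = len(y)
    press = 0.0
    for i in range(n):
        mask = np.arange(n) != i
        beta, *_ = np.linalg.lstsq(X[mask], y[mask], rcond=None)
        press += (y[i] - X[i] @ beta) ** 2
    return press
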
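import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from phenoclim import Marker, MarkerFile, MarkerTypeGroup

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


def make_marker_file(type_counts: dict[int, int], image: str = "sheet.jpg") -> MarkerFile:
    """A MarkerFile with the given number of markers per type, on a grid."""
    groups = []
    for tnum, n in type_counts.items():
        groups.append(
            MarkerTypeGroup(
                type_number=tnum,
                markers=[Marker(x=10 * tnum + i, y=20 + i, z=1) for i in range(n)],
            )
        )
    return MarkerFile(image_filename=image, marker_types=groups)


@pytest.fixture
def fig2_marker_file() -> MarkerFile:
    """A scored sheet: 0 buds, 12 flowers, 7 immature fruits, 26 mature fruits."""
    return make_marker_file({1: 0, 2: 12, 3: 7, 4: 26}, image="CAS0087560.jpg")


@pytest.fixture
def random_regression_data() -> pd.DataFrame:
    """Small seeded dataset with three correlated predictors and a linear signal."""
    rng = np.random.default_rng(42)
    n = 60
    x1 = rng.normal(2.0, 0.7, n)
    x2 = rng.normal(400.0, 150.0, n) + 30.0 * x1
    x3 = rng.normal(17.0, 4.0, n) - 0.5 * x1
    y = 180.0 + 17.0 * x1 + 0.02 * x2 - 4.0 * x3 + rng.normal(0, 20.0, n)
    return pd.DataFrame({"doy": y, "pi": x1, "winter_ppt_mm": x2, "spring_tmax_c": x3})


def ols_oracle(y: np.ndarray, X: np.ndarray) -> dict:
    """Textbook normal-equations OLS, independent of the fitting path.

    Returns coefficients, SEs, SSE, and the residual covariance, computed
    with nothing but numpy linear algebra.
    """
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    sse = float(resid @ resid)
    df = len(y) - X.shape[1]
    mse = sse / df
    cov = mse * np.linalg.inv(XtX)
    return {"beta": beta, "se": np.sqrt(np.diag(cov)), "sse": sse, "df": df,
            "mse": mse, "cov": cov}
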
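import numpy as np
import pytest

from troqsar import load_table2_fixture


def normal_equations(x, y):
    """Closed-form OLS oracle: solve (X'X) b = X'y directly.

    Independent of the package's regression path; returns
    (slope, intercept, r_squared, sdep).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    intercept, slope = np.linalg.solve(X.T @ X, X.T @ y)
    residuals = y - (intercept + slope * x)
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return slope, intercept, r_squared, float(np.sqrt(np.mean(residuals**2)))


@pytest.fixture(scope="session")
def table2():
    return load_table2_fixture()


@pytest.fixture()
def table2_xy(table2):
    """(log_kow, log_lc50) pairs for the 11 unique fixture records."""
    seen = set()
    xs, ys = [], []
    for rec in table2:
        if rec.cas in seen:
            continue
        seen.add(rec.cas)
        xs.append(rec.log_kow)
        ys.append(rec.endpoints.resolved_log_lc50())
    return xs, ys
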
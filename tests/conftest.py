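import numpy as np
import pytest

from rdhealth.synthetic import SyntheticConfig, generate


def irls_logit(X, y, tol=1e-12, maxiter=200):
    """Independent binary-logit oracle: iteratively reweighted least squares.

    Returns (intercept, slopes).  Coded from the textbook update, without
    reference to the package's ordered-logit machinery.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xd = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Xd.shape[1])
    for _ in range(maxiter):
        eta = Xd @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        z = eta + (y - p) / w
        WX = Xd * w[:, None]
        beta_new = np.linalg.solve(Xd.T @ WX, WX.T @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    return beta[0], beta[1:]


@pytest.fixture(scope="session")
def table5k():
    """Default-condition synthetic table, moderate size, fixed seed."""
    return generate(SyntheticConfig(n_respondents=5000, seed=7))


@pytest.fixture(scope="session")
def small_table():
    """Small synthetic table with few provinces, for fast fitting tests."""
    return generate(SyntheticConfig(n_respondents=1500, n_provinces=5, seed=3))
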
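import numpy as np
import pytest

from prepost.panel import panel_from_arrays


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def noisy_panel(rng):
    """Generic 12-unit x 8-period panel with 3 treated units and noise."""
    n, T, t_pre = 12, 8, 5
    treated = np.zeros(n, dtype=bool)
    treated[:3] = True
    unit = rng.standard_normal(n)
    time = rng.standard_normal(T)
    Y = unit[:, None] + time[None, :] + rng.standard_normal((n, T))
    Y[np.ix_(treated, np.arange(t_pre, T))] += 1.5
    X = rng.standard_normal((n, T, 1))
    Y += 0.5 * X[:, :, 0]
    return panel_from_arrays(Y, treated, t_pre, X)


def factor_panel(n_treated=4, n_control=12, T=10, t_pre=7, R=2, noise=0.0,
                 effect=0.0, seed=7, beta=None):
    """Panel generated exactly from a factor model (shared helper)."""
    rng = np.random.default_rng(seed)
    n = n_treated + n_control
    treated = np.zeros(n, dtype=bool)
    treated[:n_treated] = True
    F = rng.standard_normal((T, R))
    M = rng.standard_normal((n, R))
    alpha = rng.standard_normal(n)
    gamma = rng.standard_normal(T)
    Y = alpha[:, None] + gamma[None, :] + M @ F.T
    X = None
    if beta is not None:
        X = rng.standard_normal((n, T, 1))
        Y = Y + beta * X[:, :, 0]
    Y = Y + noise * rng.standard_normal((n, T))
    D = np.outer(treated, np.arange(1, T + 1) > t_pre)
    Y = Y + effect * D
    return panel_from_arrays(Y, treated, t_pre, X), dict(F=F, M=M, alpha=alpha,
                                                         gamma=gamma)
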
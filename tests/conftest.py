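"""Shared fixtures: synthetic scenarios and fitted models.

The flagship scenario (200 days × 15 species + mass, 6 sources) is fitted
once per session and reused by the recovery, error-estimation and
acceptance tests.
"""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from pmfrisk import pmf, receptor, synthetic


@pytest.fixture(scope="session")
def flagship():
    """(screened dataset, truth) for the default 200-day scenario."""
    ds, truth = synthetic.default_scenario(n_days=200, seed=1)
    return receptor.screen_dataset(ds), truth


@pytest.fixture(scope="session")
def flagship_fit(flagship):
    """Fitted 6-factor solution on the flagship scenario (robust off for
    exactness against the known noise model)."""
    ds, truth = flagship
    res = pmf.fit_pmf(ds, 6, n_starts=10, seed=1, robust=False)
    return ds, truth, res


@pytest.fixture(scope="session")
def met_scenario():
    """Scenario with planted wind sector and source cell (120 days)."""
    ds, truth, winds, trajs = synthetic.default_scenario(
        n_days=120, seed=3, with_met=True)
    return ds, truth, winds, trajs


def match_to_truth(results, truth):
    """Match fitted factors to truth factors by profile correlation.

    Returns (perm, r) where perm[i] is the fitted-factor index assigned to
    truth factor i and r the per-pair Pearson correlations.
    """
    P = results.profiles.drop(columns=["PM2.5"], errors="ignore")
    Ft = truth.F_true[P.columns]
    q = len(Ft.index)
    C = np.zeros((q, results.n_factors))
    for i in range(q):
        for j in range(results.n_factors):
            C[i, j] = np.corrcoef(Ft.iloc[i], P.iloc[j])[0, 1]
    row, col = linear_sum_assignment(-C)
    return col, C[row, col]
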
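"""Factorization correctness: exact recovery, oracles, diagnostics, errors."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import nnls

from pmfrisk import pmf, receptor, synthetic
from pmfrisk.pmf import PMFModel, fit_pmf, scan_factors
from tests.conftest import match_to_truth


def _exact_dataset(n=30, m=8, q=3, seed=0, sigma=1.0):
    """Dataset whose X is exactly G0·F0 with an exclusive anchor species
    per factor and a source-dominated anchor day per factor — the joint
    condition that makes the exact factorization unique up to
    permutation/scale (dense positive factorizations are not)."""
    rng = np.random.default_rng(seed)
    G0 = rng.uniform(0.5, 2.0, (n, q))
    G0[:q, :] = 0.01
    G0[:q, :][np.diag_indices(q)] = rng.uniform(1.0, 2.0, q)  # anchor days
    F0 = rng.uniform(0.2, 1.0, (q, m))
    F0[:, :q] = np.eye(q) * rng.uniform(1.0, 2.0, q)  # anchor species
    X = G0 @ F0
    cols = [f"s{j}" for j in range(m - 1)] + ["PM2.5"]
    dates = pd.date_range("2020-01-01", periods=n)
    data = pd.DataFrame(X, index=dates, columns=cols)
    sig = pd.DataFrame(np.full_like(X, sigma), index=dates, columns=cols)
    mdl = pd.Series(0.0, index=cols)
    ds = receptor.ReceptorDataset(data=data, sigma=sig, mdl=mdl)
    return ds, G0, F0


def test_exact_factorization_recovered():
    """Noise-free X = G0·F0 is fitted to Q ≈ 0 with cosine-similar profiles."""
    ds, G0, F0 = _exact_dataset()
    res = fit_pmf(ds, 3, n_starts=8, seed=0, robust=False)
    n, m = ds.data.shape
    assert res.Q_true <= 1e-6 * n * m
    # optimal matching of recovered profiles to truth by cosine similarity
    def unit(M):
        return M / np.linalg.norm(M, axis=1, keepdims=True)
    sim = unit(F0) @ unit(res.F).T
    from scipy.optimize import linear_sum_assignment
    r, c = linear_sum_assignment(-sim)
    assert (sim[r, c] >= 0.999).all()


def test_q_trace_monotone_within_run():
    ds, *_ = _exact_dataset(seed=3)
    res = fit_pmf(ds, 3, n_starts=1, seed=5, robust=False)
    trace = np.array(res.q_trace)
    assert (np.diff(trace) <= 1e-9 * np.maximum(trace[:-1], 1.0)).all()


def test_brute_force_oracle_small_matrix():
    """On a 4×3 matrix with σ=1 the fit matches an independent multi-start
    alternating-NNLS oracle implemented from scratch here."""
    rng = np.random.default_rng(42)
    X = rng.uniform(0, 1, (4, 3))
    cols = ["a", "b", "PM2.5"]
    dates = pd.date_range("2020-01-01", periods=4)
    ds = receptor.ReceptorDataset(
        data=pd.DataFrame(X, index=dates, columns=cols),
        sigma=pd.DataFrame(np.ones_like(X), index=dates, columns=cols),
        mdl=pd.Series(0.0, index=cols),
    )
    res = fit_pmf(ds, 2, n_starts=10, seed=0, robust=False)

    best = np.inf
    for s in range(200):  # oracle: random candidates + plain NNLS refinement
        r2 = np.random.default_rng(1000 + s)
        G = r2.uniform(0, 1, (4, 2))
        F = r2.uniform(0, 1, (2, 3))
        for _ in range(40):
            for i in range(4):
                G[i], _ = nnls(F.T, X[i])
            for j in range(3):
                F[:, j], _ = nnls(G, X[:, j])
        best = min(best, float(np.sum((X - G @ F) ** 2)))
    assert res.Q_true <= best + 1e-6


def test_permutation_gauge_invariance():
    """Fitting a column-permuted matrix returns the same profiles after
    matching (exact-factorization data, same seed schedule)."""
    ds, *_ = _exact_dataset(n=24, m=6, q=2, seed=7)
    perm = [3, 0, 4, 1, 5, 2]
    cols = [ds.species[p] for p in perm]
    ds2 = receptor.ReceptorDataset(
        data=ds.data[cols], sigma=ds.sigma[cols], mdl=ds.mdl[cols],
        total_species="PM2.5")
    r1 = fit_pmf(ds, 2, n_starts=6, seed=0, robust=False)
    r2 = fit_pmf(ds2, 2, n_starts=6, seed=0, robust=False)
    P1 = r1.profiles[sorted(ds.species)].to_numpy()
    P2 = r2.profiles[sorted(ds.species)].to_numpy()
    from scipy.optimize import linear_sum_assignment
    d = ((P1[:, None, :] - P2[None, :, :]) ** 2).sum(axis=2)
    r, c = linear_sum_assignment(d)
    assert np.abs(P1[r] - P2[c]).max() < 1e-6


def test_robust_equals_true_when_residuals_small():
    ds, *_ = _exact_dataset(seed=1)
    res = fit_pmf(ds, 3, n_starts=4, seed=1, robust=False)
    assert np.abs(res.scaled_residuals).max() < 4
    assert res.Q_robust == pytest.approx(res.Q_true, rel=1e-12)


def test_q_ratio_near_one_when_sigma_correct(flagship_fit):
    """With correctly specified σ and the true q, Q/Q_expected sits in the
    chi-square ballpark [0.5, 1.5]."""
    _, _, res = flagship_fit
    d = res.q_diagnostics()
    assert 0.5 <= d["Q_true_over_expected"] <= 1.5


def test_underfitting_raises_q(flagship):
    ds, _ = flagship
    r5 = fit_pmf(ds, 5, n_starts=4, seed=2, robust=False)
    r6 = fit_pmf(ds, 6, n_starts=4, seed=2, robust=False)
    assert r5.Q_true > r6.Q_true


def test_scan_factors_q_monotone():
    ds, truth = synthetic.default_scenario(n_days=80, seed=4)
    ds = receptor.screen_dataset(ds)
    table = scan_factors(ds, [4, 5, 6, 7], n_starts=4, seed=4, robust=False)
    q_true = table["Q_true"].to_numpy()
    assert (np.diff(q_true) <= 1e-6 * q_true[:-1]).all()
    # elbow: ratio closest to 1 at the true factor count
    ratio = (table["Q_true_over_expected"] - 1.0).abs()
    assert ratio.idxmin() == 6


def test_noise_scaling_improves_recovery():
    """Recovery correlation grows to 1 as noise shrinks to zero.

    Tested on an identifiable truth (exclusive marker species plus
    source-dominated days): with dense positive profiles the zero-noise
    factorization is not unique (rotational ambiguity), so the limit
    property only holds under identifiability conditions.
    """
    rng = np.random.default_rng(9)
    n, q = 100, 4
    species = ["NO3-", "SO42-", "As", "Ni", "OC", "EC", "Fe", "Zn"]
    F = np.full((q, len(species)), 0.02)
    F[:, :q] = 0.0
    F[np.arange(q), np.arange(q)] = 1.0            # exclusive markers
    F = F / F.sum(axis=1, keepdims=True)
    F = pd.DataFrame(F, index=[f"f{k}" for k in range(q)], columns=species)
    G = synthetic.make_contributions(n, q, factor_names=list(F.index), seed=9)
    vals = G.to_numpy()
    vals[:q, :] = 0.05
    vals[np.arange(q), np.arange(q)] = 8.0          # source-dominated days
    G = pd.DataFrame(vals, index=G.index, columns=G.columns)
    rs = []
    for mult in (1.0, 0.5, 0.1, 0.0):
        # fit without screening: below-detection substitution would
        # perturb the exact factorization at the zero-noise limit
        ds, truth = synthetic.assemble_dataset(F, G, noise_multiplier=mult,
                                               seed=10)
        res = fit_pmf(ds, q, n_starts=6, seed=9, robust=False)
        _, r = match_to_truth(res, truth)
        rs.append(r.mean())
    assert all(b >= a - 1e-3 for a, b in zip(rs, rs[1:]))
    assert rs[-1] > rs[0]
    assert rs[-1] > 0.9999


def test_invalid_factor_count_rejected():
    ds, *_ = _exact_dataset(n=10, m=5)
    with pytest.raises(ValueError, match="n_factors"):
        PMFModel(ds, 5)
    with pytest.raises(ValueError, match="n_factors"):
        PMFModel(ds, 0)


# ---------------------------------------------------------------------------
# mass apportionment
# ---------------------------------------------------------------------------

def test_single_factor_share_is_100():
    ds, *_ = _exact_dataset(n=12, m=4, q=2, seed=11)
    res = fit_pmf(ds, 1, n_starts=3, seed=0, robust=False)
    assert res.mass_shares().iloc[0] == pytest.approx(100.0)


def test_shares_sum_to_100(flagship_fit):
    _, _, res = flagship_fit
    assert res.mass_shares().sum() == pytest.approx(100.0, abs=1e-9)
    assert (res.factor_mass().to_numpy() >= 0).all()


def test_posthoc_mass_regression_mode(flagship):
    """Excluding PM2.5 from the fit still yields non-negative shares that
    sum to 100 via the post-hoc regression."""
    ds, _ = flagship
    res = fit_pmf(ds, 6, n_starts=3, seed=1, robust=False, include_total=False)
    assert "PM2.5" not in res.species
    shares = res.mass_shares()
    assert shares.sum() == pytest.approx(100.0)
    assert (shares >= 0).all()


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_identity_resample_maps_perfectly(flagship_fit):
    """One replicate whose block covers the whole record is a rotation of
    the data: every factor maps back to itself with r = 1."""
    _, _, res = flagship_fit
    bs = res.bootstrap(n_boot=1, block_size=res.model.X.shape[0], seed=0)
    assert bs.mapped_counts.tolist() == [1] * res.n_factors
    assert bs.unmapped == 0


def test_bootstrap_counts_are_consistent(flagship_fit):
    _, _, res = flagship_fit
    bs = res.bootstrap(n_boot=8, seed=5)
    assert (bs.mapped_counts <= bs.n_boot).all()
    # per replicate: mapped factors + unmapped factors = q
    assert bs.unmapped <= bs.n_boot * res.n_factors


def test_bootstrap_flags_collinear_factors():
    """Two sources with identical profiles are unidentifiable; bootstrap
    mapping reports the ambiguity."""
    rng = np.random.default_rng(0)
    n, m = 60, 6
    f = rng.uniform(0.1, 1.0, m)
    F0 = np.vstack([f, f])  # duplicated profile
    g = rng.lognormal(1.0, 0.6, n)
    G0 = np.column_stack([g, g * (1 + rng.normal(0, 0.01, n))])
    X = G0 @ F0 + rng.normal(0, 0.5, (n, m))
    X = np.clip(X, 0, None)
    cols = [f"s{j}" for j in range(m - 1)] + ["PM2.5"]
    dates = pd.date_range("2020-01-01", periods=n)
    ds = receptor.ReceptorDataset(
        data=pd.DataFrame(X, index=dates, columns=cols),
        sigma=pd.DataFrame(np.full_like(X, 0.5), index=dates, columns=cols),
        mdl=pd.Series(0.0, index=cols),
    )
    res = fit_pmf(ds, 2, n_starts=4, seed=0, robust=False)
    bs = res.bootstrap(n_boot=20, seed=1)
    assert bs.unmapped > 0 or bs.mapping_rate.min() < 0.8


# ---------------------------------------------------------------------------
# displacement
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def disp_result(flagship_fit):
    _, _, res = flagship_fit
    return res.disp(species_subset=["As", "NO3-"], factors=[0, 1],
                    dqmax_levels=(4, 8))


def test_disp_intervals_contain_base(disp_result):
    t = disp_result.table
    assert (t["lower"] <= t["base"] + 1e-9).all()
    assert (t["upper"] >= t["base"] - 1e-9).all()


def test_disp_intervals_nest_with_dqmax(disp_result):
    t = disp_result.table
    for (k, sp), grp in t.groupby(["factor", "species"]):
        grp = grp.sort_values("dqmax")
        assert grp["lower"].is_monotonic_decreasing
        assert grp["upper"].is_monotonic_increasing


def test_disp_unknown_species_rejected(flagship_fit):
    _, _, res = flagship_fit
    with pytest.raises(ValueError, match="not fitted"):
        res.disp(species_subset=["Xe"])
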
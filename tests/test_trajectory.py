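"""Wind-sector and trajectory-grid statistics."""

import numpy as np
import pandas as pd
import pytest

from pmfrisk import trajectory
from pmfrisk.trajectory import (
    GridSpec,
    TrajectorySet,
    cpf,
    pscf,
    read_tdump,
    write_tdump,
    wpscf,
)


def _wind(directions, speeds=None, start="2020-01-01"):
    ts = pd.date_range(start, periods=len(directions), freq="h")
    return pd.DataFrame(
        {"direction": directions,
         "speed": speeds if speeds is not None else np.full(len(directions), 3.0)},
        index=ts)


def test_cpf_single_sector_exceedance():
    """All exceedance hours from one sector: that sector's CPF is its
    exceedance fraction; other visited sectors score 0."""
    contrib = pd.Series([1.0, 1.0, 1.0, 10.0],
                        index=pd.date_range("2020-01-01", periods=4))
    # day 4 (the exceedance day) has all hours at 90°, others at 270°
    dirs = [270.0] * 72 + [90.0] * 24
    wind = _wind(dirs)
    r = cpf(contrib, wind, quantile=0.75, n_sectors=16)
    assert r.sectors.loc[90.0, "cpf"] == pytest.approx(1.0)
    assert r.sectors.loc[270.0, "cpf"] == pytest.approx(0.0)
    assert r.sectors.loc[0.0, "cpf"] != r.sectors.loc[0.0, "cpf"]  # NaN: unvisited


def test_cpf_constant_contributions_all_zero():
    """No day is strictly above the quantile of a constant series."""
    contrib = pd.Series(2.0, index=pd.date_range("2020-01-01", periods=5))
    wind = _wind(np.linspace(0, 359, 120))
    r = cpf(contrib, wind)
    vals = r.sectors["cpf"].dropna()
    assert (vals == 0).all()


def test_cpf_uniform_wind_flat():
    """Wind independent of exceedance: every sector's CPF ≈ exceedance rate."""
    rng = np.random.default_rng(7)
    n_days = 250
    contrib = pd.Series(rng.lognormal(1, 0.8, n_days),
                        index=pd.date_range("2020-01-01", periods=n_days))
    dirs = rng.uniform(0, 360, n_days * 24)
    wind = _wind(dirs)
    r = cpf(contrib, wind)
    assert (r.sectors["cpf"] - 0.25).abs().max() < 0.05


def test_cpf_aggregation_identity():
    rng = np.random.default_rng(11)
    contrib = pd.Series(rng.lognormal(0, 1, 40),
                        index=pd.date_range("2020-01-01", periods=40))
    wind = _wind(rng.uniform(0, 360, 40 * 24), speeds=rng.gamma(2, 1, 40 * 24))
    r = cpf(contrib, wind)
    frac = (contrib > r.threshold).mean()
    assert r.sectors["m"].sum() / r.sectors["n"].sum() == pytest.approx(frac, abs=0.02)
    non_calm = (wind["speed"] >= 0.5).sum()
    assert r.sectors["n"].sum() == non_calm
    assert r.n_calm == len(wind) - non_calm


def test_cpf_sector_binning_convention():
    """16 sectors, sector 1 centred north: bins are [c−11.25°, c+11.25°)."""
    contrib = pd.Series([1.0, 5.0], index=pd.date_range("2020-01-01", periods=2))
    wind = _wind([11.24, 11.25, 348.75, 348.74], start="2020-01-02")
    r = cpf(contrib, wind, quantile=0.5)
    assert r.sectors.loc[0.0, "n"] == 2      # 11.24 and 348.75 wrap to north
    assert r.sectors.loc[22.5, "n"] == 1     # 11.25 starts the NNE sector
    assert r.sectors.loc[337.5, "n"] == 1


def test_cpf_requires_date_overlap():
    contrib = pd.Series([1.0], index=pd.DatetimeIndex(["2019-01-01"]))
    wind = _wind([0.0] * 24)
    with pytest.raises(ValueError, match="overlapping"):
        cpf(contrib, wind)


# ---------------------------------------------------------------------------
# tdump I/O
# ---------------------------------------------------------------------------

TDUMP_FIXTURE = """     1     1
    GDAS    20     1     2     0     0     0
     2 BACKWARD OMEGA
    20     1     2    23   37.347  126.740    10.0
    20     1     3    23   37.347  126.740    10.0
     1 PRESSURE
     1     1    20     1     2    23     0     0     0.0   37.347  126.740   500.0  1013.0
     1     1    20     1     2    22     0     0    -1.0   37.500  126.500   500.0  1013.0
     1     1    20     1     2    21     0     0    -2.0   37.650  126.260   500.0  1013.0
     2     1    20     1     3    23     0     0     0.0   37.347  126.740   500.0  1013.0
     2     1    20     1     3    22     0     0    -1.0   37.200  127.000   500.0  1013.0
     2     1    20     1     3    21     0     0    -2.0   37.050  127.260   500.0  1013.0
"""


def test_read_tdump_fixture(tmp_path):
    p = tmp_path / "t.tdump"
    p.write_text(TDUMP_FIXTURE)
    ts = read_tdump(p)
    assert ts.n_trajectories == 2
    assert len(ts.endpoints) == 6
    ages = ts.endpoints[ts.endpoints["traj_id"] == 1]["age_h"].tolist()
    assert ages == [0.0, 1.0, 2.0]  # strictly increasing backward
    arr = ts.arrivals["arrival"]
    assert arr.loc[1] == pd.Timestamp("2020-01-02 23:00")
    assert arr.loc[2] == pd.Timestamp("2020-01-03 23:00")


def test_read_tdump_malformed_line_reports_number(tmp_path):
    bad = TDUMP_FIXTURE.replace("-2.0   37.650", "-2.0   xx.650")
    p = tmp_path / "bad.tdump"
    p.write_text(bad)
    with pytest.raises(ValueError, match="line 9"):
        read_tdump(p)


def test_tdump_roundtrip(tmp_path, met_scenario):
    _, _, _, trajs = met_scenario
    p = tmp_path / "rt.tdump"
    write_tdump(trajs, p)
    back = read_tdump(p)
    a, b = trajs.endpoints, back.endpoints
    assert len(a) == len(b)
    assert (a["traj_id"].to_numpy() == b["traj_id"].to_numpy()).all()
    assert (a["arrival"].to_numpy() == b["arrival"].to_numpy()).all()
    np.testing.assert_allclose(a["lat"], b["lat"], atol=5e-4)
    np.testing.assert_allclose(a["lon"], b["lon"], atol=5e-4)


# ---------------------------------------------------------------------------
# PSCF / WPSCF
# ---------------------------------------------------------------------------

def _toy_trajset():
    """10 trajectories through one cell; 3 arrive on exceedance days."""
    days = pd.date_range("2020-01-01", periods=10)
    rows = []
    for t, d in enumerate(days, start=1):
        for age in range(3):
            rows.append((t, d, float(age), 40.1 + 0.01 * age, 120.1, 500.0))
    return TrajectorySet(endpoints=pd.DataFrame(
        rows, columns=["traj_id", "arrival", "age_h", "lat", "lon", "height"])), days


def test_pscf_counting_formula():
    trajs, days = _toy_trajset()
    contrib = pd.Series([1.0] * 7 + [9.0] * 3, index=days)
    grid = pscf(trajs, contrib, quantile=0.70,
                grid_spec=GridSpec(40.0, 120.0, 0.5, 1, 1))
    assert grid.n[0, 0] == 30
    assert grid.m[0, 0] == 9
    assert grid.pscf[0, 0] == pytest.approx(0.3)


def test_pscf_pure_exceedance_cell_is_one():
    trajs, days = _toy_trajset()
    contrib = pd.Series([1.0] * 7 + [9.0] * 3, index=days)
    # cell visited only by trajectory 10 (exceedance day): append endpoints
    ep = trajs.endpoints.copy()
    extra = pd.DataFrame(
        [(10, days[9], 3.0, 45.2, 110.2, 500.0), (10, days[9], 4.0, 45.3, 110.3, 500.0)],
        columns=ep.columns)
    trajs2 = TrajectorySet(endpoints=pd.concat([ep, extra], ignore_index=True))
    grid = pscf(trajs2, contrib)
    i, j = grid.grid.cell_index(45.2, 110.2)
    assert grid.pscf[i, j] == pytest.approx(1.0)


def test_pscf_invariant_to_endpoint_order():
    trajs, days = _toy_trajset()
    contrib = pd.Series([1.0] * 7 + [9.0] * 3, index=days)
    g1 = pscf(trajs, contrib)
    shuffled = TrajectorySet(
        endpoints=trajs.endpoints.sample(frac=1, random_state=0)
        .sort_values(["traj_id", "age_h"]).reset_index(drop=True))
    g2 = pscf(shuffled, contrib)
    np.testing.assert_array_equal(g1.n, g2.n)
    np.testing.assert_array_equal(g1.m, g2.m)


def test_grid_refinement_preserves_totals(met_scenario):
    _, truth, _, trajs = met_scenario
    contrib = truth.G_true[truth.planted_factor]
    coarse = pscf(trajs, contrib, grid_spec=GridSpec.from_bounds(
        trajs.endpoints["lat"], trajs.endpoints["lon"], cell=1.0))
    fine = pscf(trajs, contrib, grid_spec=GridSpec.from_bounds(
        trajs.endpoints["lat"], trajs.endpoints["lon"], cell=0.5))
    assert coarse.n.sum() == fine.n.sum()
    assert coarse.m.sum() == fine.m.sum()


def test_wpscf_band_weights_exact():
    """Counts chosen so n_avg = 53/9; bands then take weights
    1.0 / 0.7 / 0.4 / 0.2 with boundary counts in the lower band."""
    g = GridSpec(0.0, 0.0, 1.0, 3, 3)
    from pmfrisk.trajectory import PscfGrid
    n = np.array([[30, 10, 7], [1, 1, 1], [1, 1, 1]])
    m = np.minimum(n, 2)
    grid = PscfGrid(grid=g, n=n, m=m, pscf=m / n)
    out = wpscf(grid)
    n_avg = 53 / 9
    assert out.n_avg == pytest.approx(n_avg)
    w = out.wpscf / out.pscf
    assert w[0, 0] == pytest.approx(1.0)   # 30 > 3·n_avg
    assert w[0, 1] == pytest.approx(0.7)   # 1.5·n_avg < 10 < 3·n_avg
    assert w[0, 2] == pytest.approx(0.4)   # n_avg < 7 < 1.5·n_avg
    assert w[1, 0] == pytest.approx(0.2)   # 1 < n_avg
    assert (out.wpscf <= out.pscf + 1e-15).all()


def test_wpscf_zero_pscf_stays_zero():
    g = GridSpec(0.0, 0.0, 1.0, 2, 2)
    n = np.array([[50, 2], [0, 4]])
    m = np.zeros_like(n)
    from pmfrisk.trajectory import PscfGrid
    grid = PscfGrid(grid=g, n=n, m=m, pscf=np.where(n > 0, 0.0, np.nan))
    out = wpscf(grid)
    assert np.nansum(out.wpscf) == 0.0


def test_planted_sector_and_cell_recovered(met_scenario):
    _, truth, winds, trajs = met_scenario
    contrib = truth.G_true[truth.planted_factor]
    r = cpf(contrib, winds)
    assert r.argmax_sector() == truth.planted_sector_deg
    grid = wpscf(pscf(trajs, contrib))
    assert grid.argmax_cell(weighted=True) == truth.planted_cell
    i, j = grid.grid.cell_index(*truth.planted_cell)
    assert grid.pscf[i, j] >= 0.95 * np.nanmax(grid.pscf)


def test_unplanted_cpf_is_flat():
    from pmfrisk import synthetic
    ds, truth, winds, trajs = synthetic.default_scenario(
        n_days=200, seed=13, with_met=True, planted_sector_deg=None,
        planted_cell=None)
    contrib = truth.G_true["oil_industry"]
    r = cpf(contrib, winds)
    assert (r.sectors["cpf"].dropna() - 0.25).abs().max() < 0.08
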
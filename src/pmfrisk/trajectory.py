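"""Source-direction statistics from winds and back-trajectory endpoints.

Two complementary conditional statistics locate the directions and regions
associated with high source contributions:

* **CPF** (conditional probability function): hourly wind records inherit
  their day's factor contribution; for wind sector θ,
  ``CPF = m_θ / n_θ`` with m_θ the number of non-calm hours whose day
  exceeds a contribution threshold (default: the upper quartile) and n_θ
  the total non-calm hours in that sector.
* **PSCF** (potential source contribution function): back-trajectory
  endpoints are binned on a lat/lon grid; ``PSCF = m_ij / n_ij`` with m_ij
  the endpoints whose arrival-day contribution exceeds a threshold
  (default: the 70th percentile) and n_ij all endpoints in cell ij.  The
  weighted variant WPSCF multiplies PSCF by 1.0 / 0.7 / 0.4 / 0.2 as the
  cell endpoint count n_ij falls relative to the mean count n_avg,
  suppressing cells whose probability rests on few trajectories.

Trajectory endpoints are read from HYSPLIT "tdump" endpoint files; running
HYSPLIT itself is out of scope — endpoint files are consumed as input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CpfResult",
    "TrajectorySet",
    "GridSpec",
    "PscfGrid",
    "cpf",
    "pscf",
    "wpscf",
    "read_tdump",
    "write_tdump",
]

DEFAULT_N_SECTORS = 16
DEFAULT_CALM_CUTOFF = 0.5  # m/s
DEFAULT_CPF_QUANTILE = 0.75
DEFAULT_PSCF_QUANTILE = 0.70
#: WPSCF weights for n_ij relative to n_avg: (>3, 1.5–3, 1–1.5, <1)·n_avg
WPSCF_WEIGHTS = (1.0, 0.7, 0.4, 0.2)


# ---------------------------------------------------------------------------
# CPF
# ---------------------------------------------------------------------------

@dataclass
class CpfResult:
    """Per-sector exceedance counts and conditional probabilities."""

    sectors: pd.DataFrame  # index: sector centre (deg); columns m, n, cpf
    threshold: float
    n_calm: int
    quantile: float

    @property
    def values(self) -> pd.Series:
        return self.sectors["cpf"]

    def argmax_sector(self) -> float:
        """Centre (degrees) of the sector with the highest CPF."""
        return float(self.sectors["cpf"].idxmax())


def _sector_index(direction_deg, n_sectors):
    """Half-open sector bins with sector 0 centred on north (0°)."""
    width = 360.0 / n_sectors
    return (np.floor((np.asarray(direction_deg, float) + width / 2.0) / width)
            .astype(int) % n_sectors)


def cpf(
    daily_contrib: pd.Series,
    hourly_wind: pd.DataFrame,
    quantile: float = DEFAULT_CPF_QUANTILE,
    n_sectors: int = DEFAULT_N_SECTORS,
    calm_cutoff: float = DEFAULT_CALM_CUTOFF,
) -> CpfResult:
    """Conditional probability function of one source's contributions.

    Parameters
    ----------
    daily_contrib : Series
        Date-indexed daily factor contributions (≥ 0).
    hourly_wind : DataFrame
        Timestamp-indexed with columns ``direction`` (degrees, [0, 360))
        and ``speed`` (m/s).
    quantile : float
        Contribution quantile defining exceedance; a day exceeds when its
        contribution is strictly greater than this empirical quantile
        (linear interpolation).  Default 0.75 — the upper 25%.
    calm_cutoff : float
        Hours with speed below this are treated as calm and excluded.

    Sectors with no paired hours are reported as missing (NaN), not zero.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    contrib = daily_contrib.copy()
    contrib.index = pd.DatetimeIndex(contrib.index).normalize()
    if np.any(contrib.to_numpy(float) < 0):
        raise ValueError("contributions must be >= 0")

    wind = hourly_wind.copy()
    ts = pd.DatetimeIndex(wind.index)
    days = ts.normalize()
    paired = pd.Series(days.isin(contrib.index), index=wind.index)
    if not paired.any():
        raise ValueError("no overlapping dates between wind and contributions")
    wind = wind.loc[paired.to_numpy()]
    days = pd.DatetimeIndex(wind.index).normalize()

    calm = wind["speed"].to_numpy(float) < calm_cutoff
    n_calm = int(calm.sum())
    wind = wind.loc[~calm]
    days = days[~calm]

    threshold = float(np.quantile(contrib.to_numpy(float), quantile))
    day_exceeds = contrib > threshold
    exceeds = day_exceeds.reindex(days).to_numpy(dtype=bool)

    sec = _sector_index(wind["direction"].to_numpy(float), n_sectors)
    width = 360.0 / n_sectors
    centres = (np.arange(n_sectors) * width) % 360.0
    m = np.zeros(n_sectors, dtype=int)
    n = np.zeros(n_sectors, dtype=int)
    np.add.at(n, sec, 1)
    np.add.at(m, sec[exceeds], 1)
    with np.errstate(invalid="ignore"):
        vals = np.where(n > 0, m / np.where(n > 0, n, 1), np.nan)
    table = pd.DataFrame({"m": m, "n": n, "cpf": vals}, index=pd.Index(centres, name="sector_deg"))
    return CpfResult(sectors=table, threshold=threshold, n_calm=n_calm, quantile=quantile)


# ---------------------------------------------------------------------------
# trajectories: HYSPLIT tdump endpoint files
# ---------------------------------------------------------------------------

@dataclass
class TrajectorySet:
    """Back-trajectory endpoints with arrival-time linkage.

    ``endpoints`` columns: traj_id, arrival (Timestamp), age_h (hours
    backward, ≥ 0 increasing along each trajectory), lat, lon, height.
    """

    endpoints: pd.DataFrame

    def __post_init__(self):
        need = {"traj_id", "arrival", "age_h", "lat", "lon"}
        missing = need - set(self.endpoints.columns)
        if missing:
            raise ValueError(f"endpoint frame missing columns {sorted(missing)}")
        ep = self.endpoints
        if not np.isfinite(ep[["lat", "lon", "age_h"]].to_numpy(float)).all():
            raise ValueError("endpoints must be finite")
        for tid, grp in ep.groupby("traj_id"):
            ages = grp["age_h"].to_numpy(float)
            if np.any(np.diff(ages) <= 0):
                raise ValueError(f"trajectory {tid}: hours-backward must be strictly increasing")

    @property
    def n_trajectories(self) -> int:
        return self.endpoints["traj_id"].nunique()

    @property
    def arrivals(self) -> pd.DataFrame:
        return (self.endpoints.groupby("traj_id")["arrival"].first()
                .to_frame())


def read_tdump(path) -> TrajectorySet:
    """Parse a HYSPLIT tdump endpoint file.

    Layout: a meteorological-grid block, a trajectory start block, a
    diagnostic-variable line, then one line per endpoint with the fixed
    fields (traj#, grid#, year, month, day, hour, minute, forecast-hour,
    age, lat, lon, height) followed by the diagnostic values.

    Raises
    ------
    ValueError
        On a malformed line, naming its line number.
    """
    lines = [ln.rstrip("\n") for ln in open(path)]
    pos = 0

    def fail(msg):
        raise ValueError(f"{path}: line {pos + 1}: {msg}")

    try:
        ngrids = int(lines[pos].split()[0])
    except (IndexError, ValueError):
        fail("expected meteorological grid count")
    pos += 1 + ngrids
    try:
        ntraj = int(lines[pos].split()[0])
    except (IndexError, ValueError):
        fail("expected trajectory count")
    pos += 1
    starts = []
    for t in range(ntraj):
        parts = lines[pos].split()
        try:
            yy, mo, da, hr = (int(p) for p in parts[:4])
        except (IndexError, ValueError):
            fail("expected trajectory start line (yy mm dd hh lat lon hgt)")
        year = yy + 2000 if yy < 70 else yy + 1900 if yy < 100 else yy
        starts.append(pd.Timestamp(year=year, month=mo, day=da, hour=hr))
        pos += 1
    try:
        nvars = int(lines[pos].split()[0])
    except (IndexError, ValueError):
        fail("expected diagnostic variable count")
    pos += 1
    records = []
    for ln in lines[pos:]:
        if not ln.strip():
            pos += 1
            continue
        parts = ln.split()
        if len(parts) < 12 + nvars:
            fail(f"endpoint line has {len(parts)} fields, expected >= {12 + nvars}")
        try:
            tid = int(parts[0])
            age = float(parts[8])
            lat = float(parts[9])
            lon = float(parts[10])
            hgt = float(parts[11])
        except ValueError:
            fail("non-numeric endpoint field")
        if not 1 <= tid <= ntraj:
            fail(f"trajectory id {tid} out of range 1..{ntraj}")
        records.append((tid, starts[tid - 1], abs(age), lat, lon, hgt))
        pos += 1
    ep = pd.DataFrame(records, columns=["traj_id", "arrival", "age_h", "lat", "lon", "height"])
    ep = ep.sort_values(["traj_id", "age_h"], kind="stable").reset_index(drop=True)
    return TrajectorySet(endpoints=ep)


def write_tdump(trajs: TrajectorySet, path) -> None:
    """Write a TrajectorySet back to the HYSPLIT tdump endpoint layout
    (inverse of :func:`read_tdump` up to float formatting)."""
    ep = trajs.endpoints
    tids = sorted(ep["traj_id"].unique())
    with open(path, "w") as fh:
        fh.write("     1     1\n")
        first = ep[ep["traj_id"] == tids[0]].iloc[0]
        a0 = first["arrival"]
        fh.write(f"    SYNT    {a0.year % 100:2d}    {a0.month:2d}    {a0.day:2d}"
                 f"    {a0.hour:2d}     0     0\n")
        fh.write(f"{len(tids):6d} BACKWARD OMEGA\n")
        for tid in tids:
            grp = ep[ep["traj_id"] == tid]
            a = grp["arrival"].iloc[0]
            r0 = grp.iloc[0]
            fh.write(f"{a.year % 100:6d}{a.month:6d}{a.day:6d}{a.hour:6d}"
                     f" {r0['lat']:8.3f} {r0['lon']:9.3f} {r0['height']:8.1f}\n")
        fh.write("     1 PRESSURE\n")
        for tid in tids:
            grp = ep[ep["traj_id"] == tid]
            a = grp["arrival"].iloc[0]
            for _, r in grp.iterrows():
                t = a - pd.Timedelta(hours=float(r["age_h"]))
                fh.write(
                    f"{tid:6d}{1:6d}{t.year % 100:6d}{t.month:6d}{t.day:6d}"
                    f"{t.hour:6d}{t.minute:6d}{0:6d}{-float(r['age_h']):8.1f}"
                    f" {r['lat']:8.3f} {r['lon']:9.3f} {r['height']:8.1f}"
                    f" {1013.0:8.1f}\n"
                )


# ---------------------------------------------------------------------------
# PSCF / WPSCF
# ---------------------------------------------------------------------------

@dataclass
class GridSpec:
    """Regular lat/lon grid: origin at the lower-left corner, square cells."""

    lat0: float
    lon0: float
    cell: float = 0.5
    n_lat: int = 0
    n_lon: int = 0

    @classmethod
    def from_bounds(cls, lat, lon, cell=0.5):
        lat = np.asarray(lat, float)
        lon = np.asarray(lon, float)
        lat0 = np.floor(lat.min() / cell) * cell
        lon0 = np.floor(lon.min() / cell) * cell
        n_lat = int(np.floor((lat.max() - lat0) / cell)) + 1
        n_lon = int(np.floor((lon.max() - lon0) / cell)) + 1
        return cls(lat0=lat0, lon0=lon0, cell=cell, n_lat=n_lat, n_lon=n_lon)

    def cell_index(self, lat, lon):
        i = np.floor((np.asarray(lat, float) - self.lat0) / self.cell).astype(int)
        j = np.floor((np.asarray(lon, float) - self.lon0) / self.cell).astype(int)
        return i, j


@dataclass
class PscfGrid:
    """Gridded endpoint counts and (weighted) source-contribution function."""

    grid: GridSpec
    n: np.ndarray            # total endpoint counts per cell
    m: np.ndarray            # exceedance-endpoint counts per cell
    pscf: np.ndarray         # m/n where n > 0, NaN elsewhere
    wpscf: np.ndarray = None
    threshold: float = np.nan
    n_unmatched_arrivals: int = 0
    n_avg: float = np.nan

    def argmax_cell(self, weighted: bool = False):
        """(lat, lon) centre of the cell with the highest (W)PSCF.

        Ties are broken toward the cell with more endpoints (the better
        sampled, hence more trustworthy, of equal probabilities)."""
        arr = self.wpscf if weighted else self.pscf
        arr = np.where(np.isnan(arr), -np.inf, arr)
        best = arr.max()
        tied = np.argwhere(arr >= best - 1e-12)
        i, j = max(map(tuple, tied), key=lambda ij: self.n[ij])
        g = self.grid
        return (g.lat0 + (i + 0.5) * g.cell, g.lon0 + (j + 0.5) * g.cell)

    def to_frame(self) -> pd.DataFrame:
        g = self.grid
        ii, jj = np.nonzero(self.n >= 0)
        rows = []
        for i, j in zip(ii, jj):
            if self.n[i, j] == 0:
                continue
            rows.append({
                "lat_lo": g.lat0 + i * g.cell, "lon_lo": g.lon0 + j * g.cell,
                "lat_hi": g.lat0 + (i + 1) * g.cell, "lon_hi": g.lon0 + (j + 1) * g.cell,
                "n": int(self.n[i, j]), "m": int(self.m[i, j]),
                "pscf": self.pscf[i, j],
                "wpscf": np.nan if self.wpscf is None else self.wpscf[i, j],
            })
        return pd.DataFrame(rows)


def pscf(
    trajs: TrajectorySet,
    daily_contrib: pd.Series,
    quantile: float = DEFAULT_PSCF_QUANTILE,
    grid_spec: GridSpec | None = None,
) -> PscfGrid:
    """Potential source contribution function on a lat/lon grid.

    Every endpoint of every trajectory increments its cell's n_ij; endpoints
    of trajectories arriving on days whose contribution is strictly above
    the ``quantile`` threshold also increment m_ij.  Arrivals with no
    matching sampled day are dropped (their count is reported).
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    contrib = daily_contrib.copy()
    contrib.index = pd.DatetimeIndex(contrib.index).normalize()
    ep = trajs.endpoints.copy()
    ep["day"] = pd.DatetimeIndex(ep["arrival"]).normalize()
    matched = ep["day"].isin(contrib.index)
    n_unmatched = int(ep.loc[~matched, "traj_id"].nunique())
    ep = ep.loc[matched]
    if ep.empty:
        raise ValueError("no trajectory arrivals match sampled days")

    threshold = float(np.quantile(contrib.to_numpy(float), quantile))
    exceeds = (contrib > threshold).reindex(ep["day"]).to_numpy(dtype=bool)

    if grid_spec is None:
        grid_spec = GridSpec.from_bounds(ep["lat"], ep["lon"])
    i, j = grid_spec.cell_index(ep["lat"].to_numpy(), ep["lon"].to_numpy())
    inside = (i >= 0) & (i < grid_spec.n_lat) & (j >= 0) & (j < grid_spec.n_lon)
    if not inside.any():
        raise ValueError("no endpoints fall inside the grid")
    i, j, exceeds = i[inside], j[inside], exceeds[inside]

    n = np.zeros((grid_spec.n_lat, grid_spec.n_lon), dtype=int)
    m = np.zeros_like(n)
    np.add.at(n, (i, j), 1)
    np.add.at(m, (i[exceeds], j[exceeds]), 1)
    with np.errstate(invalid="ignore"):
        vals = np.where(n > 0, m / np.where(n > 0, n, 1), np.nan)
    return PscfGrid(grid=grid_spec, n=n, m=m, pscf=vals, threshold=threshold,
                    n_unmatched_arrivals=n_unmatched)


def wpscf(grid: PscfGrid, n_avg_mode: str = "nonzero") -> PscfGrid:
    """Fill the weighted PSCF: WPSCF = w(n_ij)·PSCF with weights
    1.0 (n_ij > 3·n_avg), 0.7 (3·n_avg > n_ij > 1.5·n_avg),
    0.4 (1.5·n_avg > n_ij > n_avg), 0.2 (n_avg > n_ij).

    Boundary counts (n_ij exactly at a band edge) take the lower weight, as
    the strict inequalities imply.  ``n_avg`` is the mean endpoint count
    over visited cells (``"nonzero"``, default) or all cells (``"all"``).
    """
    if grid.pscf is None:
        raise ValueError("PSCF must be computed first")
    n = grid.n.astype(float)
    if n_avg_mode == "nonzero":
        nz = n[n > 0]
        n_avg = float(nz.mean()) if nz.size else 0.0
    elif n_avg_mode == "all":
        n_avg = float(n.mean())
    else:
        raise ValueError(f"unknown n_avg_mode {n_avg_mode!r}")
    w = np.full_like(n, WPSCF_WEIGHTS[3])
    w[n > n_avg] = WPSCF_WEIGHTS[2]
    w[n > 1.5 * n_avg] = WPSCF_WEIGHTS[1]
    w[n > 3.0 * n_avg] = WPSCF_WEIGHTS[0]
    grid.wpscf = w * grid.pscf
    grid.n_avg = n_avg
    return grid
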
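"""Ingestion, screening and uncertainty weighting of speciated receptor data.

A receptor dataset is a daily matrix of species concentrations X (µg/m³)
with a matching per-cell uncertainty matrix σ, per-species method detection
limits (MDL), and a strength label per species (``strong`` / ``weak`` /
``bad``) controlling how each species enters the factorization.  The
uncertainty model is the EPA one used with PMF:

    σ = (5/6)·MDL                                   if Conc ≤ MDL
    σ = sqrt((Conc·EF)² + (0.5·MDL)²)               if Conc > MDL

with EF the analytical error fraction (default 0.1).  Species whose
signal-to-noise ratio falls at or below a cutoff (default 0.2) are labelled
``bad`` and excluded from fitting; the total-mass variable (PM2.5) is kept
as a ``weak`` species with tripled uncertainty so that factor profiles
carry a mass row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ReceptorDataset",
    "compute_uncertainty",
    "signal_to_noise",
    "screen_dataset",
    "build_dataset",
    "read_concentration_csv",
    "read_mdl_csv",
]

STRONG, WEAK, BAD = "strong", "weak", "bad"
DEFAULT_ERROR_FRACTION = 0.1
DEFAULT_SNR_CUTOFF = 0.2
#: Uncertainty multiplier applied to species downweighted to "weak".
WEAK_SIGMA_FACTOR = 3.0


def compute_uncertainty(conc, mdl, error_fraction: float = DEFAULT_ERROR_FRACTION):
    """Per-cell measurement uncertainty σ (µg/m³) from concentration and MDL.

    Below-or-at the detection limit the uncertainty is (5/6)·MDL; above it,
    ``sqrt((conc·error_fraction)² + (0.5·MDL)²)``.  Inputs broadcast like
    numpy arrays; scalars return a scalar.

    Raises
    ------
    ValueError
        If any concentration or MDL is negative (the offending positions
        are named), or ``error_fraction <= 0``.
    """
    if error_fraction <= 0:
        raise ValueError(f"error_fraction must be > 0, got {error_fraction}")
    conc_arr = np.asarray(conc, dtype=float)
    mdl_arr = np.asarray(mdl, dtype=float)
    for name, arr in (("concentration", conc_arr), ("mdl", mdl_arr)):
        if np.any(arr < 0):
            where = np.argwhere(np.atleast_1d(arr) < 0)[:5].tolist()
            raise ValueError(f"negative {name} at positions {where}")
    conc_b, mdl_b = np.broadcast_arrays(conc_arr, mdl_arr)
    above = conc_b > mdl_b
    out = np.where(
        above,
        np.sqrt((conc_b * error_fraction) ** 2 + (0.5 * mdl_b) ** 2),
        (5.0 / 6.0) * mdl_b,
    )
    if np.isscalar(conc) and np.isscalar(mdl):
        return float(out)
    return out


def signal_to_noise(conc_series, sigma_series) -> float:
    """EPA PMF signal-to-noise ratio of one species.

    S/N = (1/n)·Σ dᵢ with dᵢ = (xᵢ − σᵢ)/σᵢ when xᵢ > σᵢ, else 0.  Samples
    whose concentration does not rise above its own uncertainty therefore
    contribute no signal rather than negative signal.
    """
    x = np.asarray(conc_series, dtype=float)
    s = np.asarray(sigma_series, dtype=float)
    if x.size == 0:
        raise ValueError("signal_to_noise requires at least one sample")
    if x.shape != s.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {s.shape}")
    d = np.where(x > s, (x - s) / s, 0.0)
    return float(d.mean())


@dataclass
class ReceptorDataset:
    """Daily speciated concentrations with uncertainties and metadata.

    Attributes
    ----------
    data : pandas.DataFrame
        n samples × m species concentrations (µg/m³), indexed by calendar
        date (normalized, unique, sorted).
    sigma : pandas.DataFrame
        Same shape/labels as ``data``; per-cell uncertainties (µg/m³).
    mdl : pandas.Series
        Per-species method detection limit (µg/m³).
    total_species : str
        Name of the total-mass column (default ``"PM2.5"``).
    strength : pandas.Series
        Per-species label in {strong, weak, bad}.  ``bad`` species are
        excluded from any fit or Q computation.
    """

    data: pd.DataFrame
    sigma: pd.DataFrame
    mdl: pd.Series
    total_species: str = "PM2.5"
    strength: pd.Series = None
    bdl_mask: pd.DataFrame = None
    screened: bool = False
    screening_report: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.strength is None:
            self.strength = pd.Series(STRONG, index=self.data.columns)
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        data, sigma = self.data, self.sigma
        if data.shape != sigma.shape or list(data.columns) != list(sigma.columns):
            raise ValueError("data and sigma must share shape and species labels")
        if self.total_species not in data.columns:
            raise ValueError(f"total species {self.total_species!r} not in dataset")
        idx = pd.DatetimeIndex(data.index)
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique()
            raise ValueError(f"duplicate sample dates: {list(dup[:5])}")
        missing_mdl = [s for s in data.columns if s not in self.mdl.index]
        if missing_mdl:
            raise ValueError(f"species without an MDL: {missing_mdl}")
        if np.any(self.mdl.loc[data.columns] < 0):
            raise ValueError("MDL values must be >= 0")
        fitted = self.fitted_species
        if fitted and not np.all(sigma[fitted].to_numpy() > 0):
            raise ValueError("sigma must be > 0 for every fitted cell")

    # -- species views ------------------------------------------------------
    @property
    def species(self) -> list[str]:
        return list(self.data.columns)

    @property
    def fitted_species(self) -> list[str]:
        """Species entering the factorization (strong + weak)."""
        return [s for s in self.data.columns if self.strength[s] != BAD]

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.data.index)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def fit_arrays(self, include_total: bool = True):
        """(X, σ, species) restricted to fitted species, as float ndarrays."""
        cols = self.fitted_species
        if not include_total:
            cols = [c for c in cols if c != self.total_species]
        return (
            self.data[cols].to_numpy(dtype=float),
            self.sigma[cols].to_numpy(dtype=float),
            cols,
        )

    def subset_rows(self, indexer) -> "ReceptorDataset":
        """Row subset/resample (used by the bootstrap); duplicate dates are
        disambiguated by a replicate-aware index."""
        data = self.data.iloc[indexer]
        sigma = self.sigma.iloc[indexer]
        new_index = pd.RangeIndex(len(data))
        data = data.set_axis(new_index)
        sigma = sigma.set_axis(new_index)
        out = ReceptorDataset.__new__(ReceptorDataset)
        out.data, out.sigma, out.mdl = data, sigma, self.mdl
        out.total_species = self.total_species
        out.strength = self.strength.copy()
        out.bdl_mask = None
        out.screened = self.screened
        out.screening_report = {}
        return out

    # -- I/O ----------------------------------------------------------------
    def to_csv(self, conc_path, sigma_path, report_path=None) -> None:
        self.data.to_csv(conc_path, index_label="date")
        self.sigma.to_csv(sigma_path, index_label="date")
        if report_path is not None:
            Path(report_path).write_text(
                json.dumps(self.screening_report, indent=2, sort_keys=True)
            )


def read_concentration_csv(path, species_registry=None) -> pd.DataFrame:
    """Read a wide concentration CSV (first column ISO-8601 date).

    Header names are matched case-insensitively against ``species_registry``
    (a list of canonical names); matched columns are renamed to canonical
    form, unmatched ones kept verbatim.
    """
    df = pd.read_csv(path, index_col=0, parse_dates=True)
    df.index.name = "date"
    if species_registry:
        lookup = {s.lower(): s for s in species_registry}
        df = df.rename(columns=lambda c: lookup.get(c.strip().lower(), c.strip()))
    return df


def read_mdl_csv(path) -> pd.Series:
    """Read an MDL CSV with columns (species, mdl) into a Series."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "species" not in cols or "mdl" not in cols:
        raise ValueError("MDL CSV must have columns 'species' and 'mdl'")
    return pd.Series(
        df[cols["mdl"]].to_numpy(dtype=float),
        index=df[cols["species"]].astype(str).str.strip().to_numpy(),
        name="mdl",
    )


def build_dataset(
    conc: pd.DataFrame,
    mdl: pd.Series,
    total_species: str = "PM2.5",
    error_fraction: float = DEFAULT_ERROR_FRACTION,
) -> ReceptorDataset:
    """Assemble a :class:`ReceptorDataset` from concentrations and MDLs.

    σ is the element-wise uncertainty model applied to the concentration
    matrix.  Missing cells are left as NaN (screening decides their fate).
    """
    conc = conc.sort_index()
    mdl = mdl.reindex(conc.columns)
    if mdl.isna().any():
        raise ValueError(f"species without an MDL: {list(mdl.index[mdl.isna()])}")
    sig = pd.DataFrame(
        compute_uncertainty(
            np.nan_to_num(conc.to_numpy(dtype=float), nan=0.0),
            mdl.to_numpy(dtype=float)[None, :],
            error_fraction,
        ),
        index=conc.index,
        columns=conc.columns,
    )
    return ReceptorDataset(data=conc, sigma=sig, mdl=mdl, total_species=total_species)


def screen_dataset(
    ds: ReceptorDataset,
    snr_cutoff: float = DEFAULT_SNR_CUTOFF,
    bdl_policy: str = "substitute",
    outlier_z: float | None = None,
    error_fraction: float = DEFAULT_ERROR_FRACTION,
    downweight_total: bool = True,
) -> ReceptorDataset:
    """Screen and re-weight a dataset ahead of factorization.

    Steps, in order:

    1. rows containing missing cells are dropped (values cannot be fitted
       without an uncertainty);
    2. below-detection-limit cells (conc ≤ MDL) are handled per
       ``bdl_policy``: ``"substitute"`` replaces them with MDL/2 and sets
       σ = (5/6)·MDL; ``"exclude-row"`` drops the affected sample days;
    3. optional per-species outlier screen on log-concentration
       (|z| > ``outlier_z``; off when None) drops the affected rows;
    4. species with S/N ≤ ``snr_cutoff`` (inclusive, per the "0.2 or less"
       screening convention) are labelled ``bad``;
    5. the total-mass species is downweighted to ``weak`` with σ tripled.

    The returned dataset carries a ``screening_report`` listing every
    removal with its reason.  Screening is idempotent: screening an already
    screened dataset changes nothing.

    Raises
    ------
    ValueError
        If screening would remove the total-mass species.
    """
    if snr_cutoff < 0:
        raise ValueError("snr_cutoff must be >= 0")
    if bdl_policy not in ("substitute", "exclude-row"):
        raise ValueError(f"unknown bdl_policy {bdl_policy!r}")

    report: dict = {
        "snr_cutoff": snr_cutoff,
        "bdl_policy": bdl_policy,
        "removed_species": [],
        "removed_rows": [],
        "bdl_cells": 0,
        "already_screened": ds.screened,
    }
    if ds.screened:
        out = replace(
            ds,
            data=ds.data.copy(),
            sigma=ds.sigma.copy(),
            strength=ds.strength.copy(),
            screening_report=dict(ds.screening_report),
        )
        return out

    data = ds.data.copy()
    sigma = ds.sigma.copy()
    strength = ds.strength.copy()
    mdl = ds.mdl

    # 1. missing cells
    has_nan = data.isna().any(axis=1)
    if has_nan.any():
        for d in data.index[has_nan]:
            report["removed_rows"].append({"date": str(d), "reason": "missing value"})
        data = data.loc[~has_nan]
        sigma = sigma.loc[~has_nan]

    # 2. BDL handling
    mdl_row = mdl.reindex(data.columns).to_numpy(dtype=float)
    bdl = data.to_numpy(dtype=float) <= mdl_row[None, :]
    report["bdl_cells"] = int(bdl.sum())
    bdl_mask = pd.DataFrame(bdl, index=data.index, columns=data.columns)
    if bdl_policy == "substitute":
        sub_conc = np.where(bdl, 0.5 * mdl_row[None, :], data.to_numpy(dtype=float))
        sub_sig = np.where(bdl, (5.0 / 6.0) * mdl_row[None, :], sigma.to_numpy(dtype=float))
        data = pd.DataFrame(sub_conc, index=data.index, columns=data.columns)
        sigma = pd.DataFrame(sub_sig, index=data.index, columns=data.columns)
    else:  # exclude-row
        bad_rows = bdl_mask.any(axis=1)
        for d in data.index[bad_rows]:
            report["removed_rows"].append({"date": str(d), "reason": "below detection limit"})
        data = data.loc[~bad_rows]
        sigma = sigma.loc[~bad_rows]
        bdl_mask = bdl_mask.loc[~bad_rows]

    # 3. optional log-scale outlier screen
    if outlier_z is not None:
        logx = np.log(data.where(data > 0))
        z = (logx - logx.mean()) / logx.std(ddof=0).replace(0.0, np.nan)
        out_rows = (z.abs() > outlier_z).any(axis=1)
        for d in data.index[out_rows]:
            report["removed_rows"].append({"date": str(d), "reason": f"outlier |z|>{outlier_z}"})
        data = data.loc[~out_rows]
        sigma = sigma.loc[~out_rows]
        bdl_mask = bdl_mask.loc[~out_rows]

    # 4. S/N screen (inclusive cutoff)
    for sp in data.columns:
        snr = signal_to_noise(data[sp].to_numpy(), sigma[sp].to_numpy())
        if snr <= snr_cutoff:
            if sp == ds.total_species:
                raise ValueError(
                    f"screening would remove total-mass species {sp!r} (S/N={snr:.3g})"
                )
            strength[sp] = BAD
            report["removed_species"].append(
                {"species": sp, "reason": f"S/N {snr:.4g} <= {snr_cutoff}"}
            )

    # 5. total-mass variable fitted weak with tripled sigma
    if downweight_total and strength[ds.total_species] != BAD:
        if strength[ds.total_species] != WEAK:
            strength[ds.total_species] = WEAK
            sigma[ds.total_species] = sigma[ds.total_species] * WEAK_SIGMA_FACTOR

    out = ReceptorDataset(
        data=data,
        sigma=sigma,
        mdl=mdl,
        total_species=ds.total_species,
        strength=strength,
        bdl_mask=bdl_mask,
        screened=True,
        screening_report=report,
    )
    return out
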
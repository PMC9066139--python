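"""Inhalation health risk of PM2.5-bound toxic elements.

The exposure chain is the EPA inhalation screening convention:

    ADDinh (µg/m³) = C · ET · EF · ED / AT          (dose surrogate)
    ILCRinh        = ADDinh · IUR                    (cancer risk)
    HQ             = ADDinh / RfC,   HI = Σ HQ       (non-cancer)

with C the air concentration (µg/m³), ET exposure time (h/day), EF
exposure frequency (days/year), ED exposure duration (years), AT averaging
time in hours (ED·365·24), IUR the inhalation unit risk (m³/µg) and RfC a
reference concentration (µg/m³).  With EF = 365 and AT = ED·365·24 the
dose reduces to C·ET/24.

Chromium is speciated before the cancer path: only the hexavalent form is
carcinogenic, and ambient Cr is split Cr(VI):Cr(III) = 3:7 by default (an
abundance ratio typical of industrial-city PM).

Risk bands: ILCR below 1E-06 is negligible, above 1E-04 likely harmful,
and in between tolerable but warranting reduction plans; band boundaries
fall in the tolerable band.

Source-resolved risk: per-source per-element concentration series from the
factorization (g_ik·f_kj) are summarized (median by default, optionally the
95th percentile), converted to ILCR, and arranged in a sources × elements
matrix with margins and percentage shares.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExposureParams",
    "ToxicityTable",
    "RiskMatrix",
    "add_inh",
    "ilcr",
    "speciate_chromium",
    "classify_risk",
    "source_risk_matrix",
    "required_reduction",
    "noncancer_hq",
    "DEFAULT_TOXICITY",
]

NEGLIGIBLE_LIMIT = 1e-6
HARMFUL_LIMIT = 1e-4
DEFAULT_CR_HEX_FRACTION = 0.3
CARCINOGENS = ("As", "Cr6+", "Ni", "Pb")
NONCARCINOGENS = ("As", "Cr6+", "Cu", "Ni", "Pb", "V", "Mn")

#: Default screening toxicity values (EPA regional screening level tables:
#: IUR from IRIS/OEHHA; RfC entries are generic chronic inhalation
#: references — replace with study-specific values for real assessments).
DEFAULT_TOXICITY = """element,iur,rfc,source
As,4.3e-3,1.5e-2,IRIS
Cr6+,1.2e-2,1.0e-1,IRIS
Ni,2.4e-4,1.4e-2,IRIS
Pb,1.2e-5,1.5e-1,OEHHA
Mn,,5.0e-2,IRIS
V,,1.0e-1,ATSDR
Cu,,,none
"""


@dataclass(frozen=True)
class ExposureParams:
    """Inhalation exposure parameters for an adult receptor.

    et: exposure time (h/day), ef: exposure frequency (days/year),
    ed: exposure duration (years).  The averaging time AT is defined as
    ED·365·24 hours and is enforced, not stored.

    The defaults (ET=24, EF=365, ED=30) are a deliberately transparent
    placeholder — continuous exposure — because receptor-population values
    belong to the study design.  :meth:`calibrate_et` back-solves the
    effective exposure time from a known (concentration, ILCR, IUR) triple
    so published risk tables can be reproduced without guessing ET.
    """

    et: float = 24.0
    ef: float = 365.0
    ed: float = 30.0

    def __post_init__(self):
        if not 0 < self.et <= 24:
            raise ValueError(f"ET must be in (0, 24] h/day, got {self.et}")
        if self.ef <= 0 or self.ed <= 0:
            raise ValueError("EF and ED must be > 0")

    @property
    def at(self) -> float:
        """Averaging time (hours): ED·365·24."""
        return self.ed * 365.0 * 24.0

    @property
    def dose_factor(self) -> float:
        """ET·EF·ED/AT — the factor turning concentration into dose."""
        return self.et * self.ef * self.ed / self.at

    @classmethod
    def calibrate_et(cls, conc: float, target_ilcr: float, iur: float,
                     ef: float = 365.0, ed: float = 30.0) -> "ExposureParams":
        """Exposure parameters whose ET reproduces ``target_ilcr`` at
        concentration ``conc`` (µg/m³) for unit risk ``iur`` (m³/µg)."""
        if conc <= 0 or iur <= 0 or target_ilcr <= 0:
            raise ValueError("conc, iur and target_ilcr must be > 0")
        et = 24.0 * target_ilcr / (conc * iur) * (365.0 / ef)
        return cls(et=et, ef=ef, ed=ed)


def add_inh(conc, params: ExposureParams):
    """Average daily inhaled dose surrogate (µg/m³): C·ET·EF·ED/AT."""
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    out = c * params.dose_factor
    return float(out) if np.isscalar(conc) else out


def ilcr(add, iur):
    """Incremental lifetime cancer risk: ADDinh × IUR."""
    a = np.asarray(add, dtype=float)
    u = np.asarray(iur, dtype=float)
    if np.any(a < 0) or np.any(u < 0):
        raise ValueError("dose and IUR must be >= 0")
    out = a * u
    return float(out) if np.isscalar(add) and np.isscalar(iur) else out


def speciate_chromium(cr_total, hexavalent_fraction: float = DEFAULT_CR_HEX_FRACTION):
    """Split total Cr into (Cr6+, Cr3+); only Cr6+ enters the cancer path."""
    if not 0 <= hexavalent_fraction <= 1:
        raise ValueError("hexavalent_fraction must be in [0, 1]")
    c = np.asarray(cr_total, dtype=float)
    if np.any(c < 0):
        raise ValueError("Cr concentration must be >= 0")
    hexa = c * hexavalent_fraction
    tri = c - hexa
    if np.isscalar(cr_total):
        return float(hexa), float(tri)
    return hexa, tri


def classify_risk(value):
    """Risk band of an ILCR: ``negligible`` (< 1E-06), ``tolerable``
    (1E-06 – 1E-04, boundaries included), ``harmful`` (> 1E-04)."""
    def one(v):
        if v < 0:
            raise ValueError("ILCR must be >= 0")
        if v < NEGLIGIBLE_LIMIT:
            return "negligible"
        if v > HARMFUL_LIMIT:
            return "harmful"
        return "tolerable"
    if np.isscalar(value):
        return one(value)
    return np.array([one(v) for v in np.asarray(value, float).ravel()]).reshape(
        np.asarray(value).shape)


def required_reduction(ilcr_current: float, ilcr_target: float) -> float:
    """Fractional concentration reduction bringing ILCR to the target:
    max(0, 1 − target/current); linear because ILCR is linear in C."""
    if ilcr_target <= 0:
        raise ValueError("target ILCR must be > 0")
    if ilcr_current < 0:
        raise ValueError("current ILCR must be >= 0")
    if ilcr_current <= ilcr_target:
        return 0.0
    return 1.0 - ilcr_target / ilcr_current


# ---------------------------------------------------------------------------
# toxicity table
# ---------------------------------------------------------------------------

class ToxicityTable:
    """Per-element toxicity values: IUR (m³/µg) and/or RfC (µg/m³)."""

    def __init__(self, frame: pd.DataFrame):
        need = {"iur", "rfc"}
        if not need <= set(frame.columns):
            raise ValueError("toxicity table needs columns 'iur' and 'rfc'")
        both_missing = frame["iur"].isna() & frame["rfc"].isna()
        if both_missing.any():
            raise ValueError(
                f"elements with neither IUR nor RfC: {list(frame.index[both_missing])}")
        if (frame["iur"].dropna() < 0).any() or (frame["rfc"].dropna() < 0).any():
            raise ValueError("IUR and RfC must be >= 0")
        self.frame = frame

    @classmethod
    def from_csv(cls, path_or_buf) -> "ToxicityTable":
        df = pd.read_csv(path_or_buf)
        df.columns = [c.lower() for c in df.columns]
        df = df.set_index("element")
        df = df[df["iur"].notna() | df["rfc"].notna()]
        return cls(df)

    @classmethod
    def default(cls) -> "ToxicityTable":
        return cls.from_csv(io.StringIO(DEFAULT_TOXICITY))

    def iur(self, element: str) -> float:
        if element not in self.frame.index or pd.isna(self.frame.loc[element, "iur"]):
            raise KeyError(f"no inhalation unit risk for element {element!r}")
        return float(self.frame.loc[element, "iur"])

    def rfc(self, element: str) -> float:
        if element not in self.frame.index or pd.isna(self.frame.loc[element, "rfc"]):
            raise KeyError(f"no reference concentration for element {element!r}")
        return float(self.frame.loc[element, "rfc"])

    def has_iur(self, element: str) -> bool:
        return element in self.frame.index and pd.notna(self.frame.loc[element, "iur"])

    def has_rfc(self, element: str) -> bool:
        return element in self.frame.index and pd.notna(self.frame.loc[element, "rfc"])


# ---------------------------------------------------------------------------
# source × element risk matrix
# ---------------------------------------------------------------------------

@dataclass
class RiskMatrix:
    """Sources × elements ILCR table with margins, shares, classifications."""

    table: pd.DataFrame          # ILCR per (source, element); NaN = no value
    statistic: str = "median"
    excluded_elements: tuple = ()

    @property
    def row_sums(self) -> pd.Series:
        return self.table.sum(axis=1, skipna=True)

    @property
    def col_sums(self) -> pd.Series:
        return self.table.sum(axis=0, skipna=True)

    @property
    def grand_total(self) -> float:
        return float(self.table.sum().sum())

    @property
    def row_shares(self) -> pd.Series:
        """Per-source percentage of the total ILCR."""
        return 100.0 * self.row_sums / self.grand_total

    @property
    def col_shares(self) -> pd.Series:
        """Per-element percentage of the total ILCR."""
        return 100.0 * self.col_sums / self.grand_total

    def classify(self) -> pd.Series:
        return pd.Series(
            {s: classify_risk(v) for s, v in self.row_sums.items()})

    def summary(self) -> pd.DataFrame:
        """Table 2-style layout: cells, per-source sum (+share), element
        sums (+shares) appended as the final row."""
        out = self.table.copy()
        out["sum"] = self.row_sums
        out["share_pct"] = self.row_shares
        bottom = pd.concat([self.col_sums, pd.Series(
            {"sum": self.grand_total, "share_pct": 100.0})])
        out.loc["element_sum"] = bottom
        return out

    def to_csv(self, path) -> None:
        self.summary().to_csv(path, index_label="source")

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "grand_total": self.grand_total,
            "row_sums": self.row_sums.to_dict(),
            "col_sums": self.col_sums.to_dict(),
            "row_shares_pct": self.row_shares.to_dict(),
            "col_shares_pct": self.col_shares.to_dict(),
            "classification": self.classify().to_dict(),
            "excluded_elements": list(self.excluded_elements),
        }

    @classmethod
    def from_ilcr_table(cls, table: pd.DataFrame, statistic: str = "median") -> "RiskMatrix":
        """Wrap an existing sources × elements ILCR table (e.g. published
        values) so margins/shares/classification logic can be applied."""
        return cls(table=table.astype(float), statistic=statistic)


def _series_statistic(series, statistic):
    arr = np.asarray(series, dtype=float)
    if statistic == "median":
        return float(np.median(arr))
    if statistic in ("p95", "95p", "95th"):
        return float(np.quantile(arr, 0.95))
    raise ValueError(f"unknown statistic {statistic!r}")


def source_risk_matrix(
    apportioned: dict,
    tox: ToxicityTable,
    params: ExposureParams,
    statistic: str = "median",
    cr_hex_fraction: float = DEFAULT_CR_HEX_FRACTION,
    elements=None,
) -> RiskMatrix:
    """Source-resolved carcinogenic risk matrix.

    Parameters
    ----------
    apportioned : dict
        {source name: DataFrame(dates × elements)} of apportioned
        concentration series (µg/m³), e.g. from
        :meth:`pmfrisk.pmf.PMFResults.apportion_species`.
    statistic : str
        Summary over time per (source, element): ``median`` or ``p95``.
    cr_hex_fraction : float
        Fraction of total Cr treated as carcinogenic Cr(VI); applied before
        the unit risk.  A ``Cr`` input column becomes a ``Cr6+`` output
        column.

    Elements without an IUR are excluded from the matrix but listed in
    ``excluded_elements``.
    """
    if not apportioned:
        raise ValueError("apportioned concentration dict is empty")
    rows = {}
    excluded = set()
    for source, frame in apportioned.items():
        cells = {}
        for el in (elements or frame.columns):
            if el not in frame.columns:
                continue
            series = frame[el].to_numpy(dtype=float)
            if np.any(series < 0):
                raise ValueError(f"negative concentration for {source}/{el}")
            conc = _series_statistic(series, statistic)
            out_el = el
            if el == "Cr":
                conc, _ = speciate_chromium(conc, cr_hex_fraction)
                out_el = "Cr6+"
            if not tox.has_iur(out_el):
                excluded.add(el)
                continue
            cells[out_el] = ilcr(add_inh(conc, params), tox.iur(out_el))
        rows[source] = cells
    table = pd.DataFrame.from_dict(rows, orient="index")
    if table.empty or table.shape[1] == 0:
        raise ValueError("no element with an inhalation unit risk was found")
    order = [e for e in CARCINOGENS if e in table.columns]
    order += [e for e in table.columns if e not in order]
    table = table[order]
    return RiskMatrix(table=table, statistic=statistic,
                      excluded_elements=tuple(sorted(excluded)))


def noncancer_hq(
    conc: pd.DataFrame,
    tox: ToxicityTable,
    params: ExposureParams,
    statistic: str = "median",
    cr_hex_fraction: float = DEFAULT_CR_HEX_FRACTION,
    convention: str = "dose_ratio",
) -> dict:
    """Non-carcinogenic hazard quotients and hazard index.

    HQ = ADDinh/RfC per element (``dose_ratio`` convention, RfC in µg/m³;
    the ``ec_mg`` alternative divides by RfC expressed in mg/m³, i.e.
    multiplies by 1000).  HI is the sum of HQs; HI or any HQ above 1 sets
    ``flag``.  Elements without an RfC are skipped with a warning entry.
    """
    if convention not in ("dose_ratio", "ec_mg"):
        raise ValueError(f"unknown convention {convention!r}")
    hq = {}
    skipped = []
    for el in conc.columns:
        series = conc[el].to_numpy(dtype=float)
        c = _series_statistic(series, statistic)
        out_el = el
        if el == "Cr":
            c, _ = speciate_chromium(c, cr_hex_fraction)
            out_el = "Cr6+"
        if not tox.has_rfc(out_el):
            skipped.append(el)
            continue
        dose = add_inh(c, params)
        ref = tox.rfc(out_el)
        hq[out_el] = dose / ref if convention == "dose_ratio" else dose / (ref / 1000.0)
    hq_series = pd.Series(hq, dtype=float)
    hi = float(hq_series.sum())
    return {
        "hq": hq_series,
        "hi": hi,
        "flag": bool(hi > 1.0 or (hq_series > 1.0).any()),
        "skipped": skipped,
        "statistic": statistic,
        "convention": convention,
    }
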
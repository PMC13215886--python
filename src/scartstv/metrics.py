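"""Volume and comparison metrics for manual-vs-automated STV evaluation.

Includes contour-based structure volume (slice-area summation), STV/GTV
volume ratios, dose-band summary statistics in the layout of the
21-patient comparison table (per-patient percent of GTV volume falling
in each delivered-dose band, manual vs automated arm), a paired
two-tailed t-test, and percent change.

The dose-band table's printed "STD V" row is the *population* standard
deviation (divisor n): recomputing the manual [1500, 3000) column gives
7.58 with divisor n, versus about 7.77 with divisor n-1, and only the
former matches the printed row.  ``column_summary`` therefore reports
the population SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .contour import Structure, polygon_area
from .errors import DegenerateContourError

__all__ = [
    "BANDS",
    "ARMS",
    "DoseBandTable",
    "load_table2",
    "structure_volume",
    "volume_ratio",
    "column_summary",
    "paired_two_tailed_test",
    "percent_change",
]

#: canonical dose-band labels (cGy intervals)
BANDS = ("1500-3000", "3000-4500", "4500-5400", ">5400")
ARMS = ("manual", "auto")

_BAND_ALIASES = {
    "1500-3000": "1500-3000",
    "[1500,3000)": "1500-3000",
    "3000-4500": "3000-4500",
    "[3000,4500)": "3000-4500",
    "4500-5400": "4500-5400",
    "[4500,5400)": "4500-5400",
    ">5400": ">5400",
    "5400+": ">5400",
}


def structure_volume(s: Structure) -> float:
    """Structure volume in cc from planar contours: sum of area x spacing.

    The nominal spacing is the median consecutive z difference (a
    single-slice structure uses its declared spacing).  An empty
    structure has zero volume.
    """
    if not s.slices:
        return 0.0
    spacing = s.slice_spacing
    total_mm3 = sum(polygon_area(sl) for sl in s.slices) * spacing
    return total_mm3 / 1000.0  # mm^3 -> cc


def volume_ratio(stv: Structure, gtv: Structure) -> float:
    """V_STV / V_GTV; in (0, 1) whenever the STV is a proper sub-volume."""
    v_gtv = structure_volume(gtv)
    if v_gtv <= 0:
        raise DegenerateContourError("GTV has zero volume; ratio undefined")
    return structure_volume(stv) / v_gtv


@dataclass
class DoseBandTable:
    """Per-patient percentages of GTV volume in each delivered-dose band.

    Wraps a long-format DataFrame with columns
    ``patient_id, gtv_cc, band, arm, percent`` — one row per patient x
    band x arm (manual | auto).  Percentages are of GTV volume; per
    patient and arm the four band percentages sum to at most 100 (dose
    below the lowest band is unreported).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"patient_id", "gtv_cc", "band", "arm", "percent"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"dose-band table missing columns: {sorted(missing)}")
        df = self.df.copy()
        df["band"] = df["band"].map(lambda b: _BAND_ALIASES.get(str(b).strip(), None))
        if df["band"].isna().any():
            bad = sorted(set(self.df["band"][df["band"].isna()].astype(str)))
            raise KeyError(f"unknown dose-band labels: {bad}; expected one of {list(BANDS)}")
        if not set(df["arm"]).issubset(ARMS):
            raise KeyError(f"unknown arm labels: {sorted(set(df['arm']) - set(ARMS))}")
        if ((df["percent"] < 0) | (df["percent"] > 100)).any():
            raise ValueError("band percentages must lie in [0, 100]")
        sums = df.groupby(["patient_id", "arm"])["percent"].sum()
        if (sums > 100.0 + 1e-9).any():
            raise ValueError("band percentages exceed 100% for some patient/arm")
        self.df = df

    @property
    def n_patients(self) -> int:
        return self.df["patient_id"].nunique()

    def column(self, arm: str, band: str) -> np.ndarray:
        """Per-patient percentages for one arm and band, in patient order."""
        band = _BAND_ALIASES.get(str(band).strip())
        if band is None or arm not in ARMS:
            raise KeyError(f"unknown arm/band: {arm!r}, {band!r}")
        sel = self.df[(self.df["arm"] == arm) & (self.df["band"] == band)]
        if sel.empty:
            raise KeyError(f"no rows for arm={arm!r}, band={band!r}")
        return sel.sort_values("patient_id")["percent"].to_numpy(dtype=float)

    @classmethod
    def from_csv(cls, path) -> "DoseBandTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def load_table2() -> DoseBandTable:
    """The bundled 21-patient manual-vs-auto dose-band comparison table."""
    with resources.files("scartstv.data").joinpath("table2.csv").open("r") as fh:
        return DoseBandTable(pd.read_csv(fh))


def column_summary(table: DoseBandTable, arm: str, band: str) -> tuple[float, float]:
    """Mean and population standard deviation (%) of one table column.

    The population SD (divisor n) reproduces the printed "STD V" row of
    the comparison table; see the module docstring.
    """
    values = table.column(arm, band)
    if len(values) < 2:
        raise ValueError("column summary needs at least 2 patients")
    return float(np.mean(values)), float(np.std(values, ddof=0))


def paired_two_tailed_test(x, y) -> tuple[float, float]:
    """Paired two-tailed t-test on matched vectors.

    t = mean(d) / (sd(d)/sqrt(n)) with the *sample* SD of the
    differences d = x - y (divisor n-1), p two-tailed from the t
    distribution with n-1 degrees of freedom.  Identical vectors (all
    differences zero) return (0.0, 1.0) by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"paired vectors must be equal-length 1-d, got {x.shape} vs {y.shape}")
    if len(x) < 2:
        raise ValueError("paired test needs at least 2 pairs")
    d = x - y
    if np.allclose(d, 0.0):
        return 0.0, 1.0
    sd = float(np.std(d, ddof=1))
    n = len(d)
    if sd == 0.0:  # constant non-zero shift: infinitely significant
        return math.copysign(math.inf, float(np.mean(d))), 0.0
    t = float(np.mean(d)) / (sd / math.sqrt(n))
    p = 2.0 * float(_sps.t.sf(abs(t), df=n - 1))
    return t, p


def percent_change(reference: float, new: float) -> float:
    """Signed percent change 100*(new - reference)/reference."""
    if reference == 0:
        raise ZeroDivisionError("percent change undefined for a zero reference")
    return 100.0 * (new - reference) / reference
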
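"""Physiological rate estimation from batch-culture time series.

A batch culture of *P. denitrificans* on succinate is sampled for dry
weight biomass (g/L), PHB content per dry weight (mg/g) and residual
succinate (mM).  From such a series this module estimates the specific
growth rate mu (slope of ln biomass vs time over the exponential
window), the biomass yield on succinate Y_XS (slope of biomass vs
consumed substrate), and the derived specific rates

    q_s   = 1000 * mu / Y_XS          (mmol succinate g-DW^-1 h^-1)
    q_PHB = mu * w_PHB                (mg PHB g-DW^-1 h^-1)

where w_PHB is the constant fractional PHB content during exponential
growth.  Molar PHB rates use the effective monomer mass of 96 g/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .model import PHB_MONOMER_MOLAR_MASS

#: Conversion factor from optical density at 660 nm to dry weight, g/L.
OD660_TO_GDW_PER_L = 0.365

REQUIRED_COLUMNS = ("time_h", "dry_weight_g_per_L", "phb_mg_per_g", "succinate_mM")


class KineticsError(ValueError):
    """Raised for degenerate inputs to rate estimation."""


@dataclass
class BatchTimeSeries:
    """Timed batch-culture measurements (means over replicates).

    time: h; dry_weight: g/L; phb_content: mg PHB per g dry weight;
    succinate: mM.  Optional per-point standard deviations.
    """

    time: np.ndarray
    dry_weight: np.ndarray
    phb_content: np.ndarray
    succinate: np.ndarray
    dry_weight_sd: np.ndarray | None = None
    phb_content_sd: np.ndarray | None = None
    succinate_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("time", "dry_weight", "phb_content", "succinate"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.time)
        for name in ("dry_weight", "phb_content", "succinate"):
            if len(getattr(self, name)) != n:
                raise KineticsError(f"{name} has length != time")
        if n and np.any(np.diff(self.time) <= 0):
            raise KineticsError("times must be strictly increasing")
        if np.any(self.dry_weight < 0) or np.any(self.phb_content < 0) or np.any(
            self.succinate < 0
        ):
            raise KineticsError("measurements must be non-negative")

    def __len__(self) -> int:
        return len(self.time)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BatchTimeSeries":
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise KineticsError(
                f"time series is missing required column(s) {missing}; "
                f"expected header {list(REQUIRED_COLUMNS)}"
            )
        def sd(col):
            return df[col].to_numpy(float) if col in df.columns else None
        return cls(
            time=df["time_h"].to_numpy(float),
            dry_weight=df["dry_weight_g_per_L"].to_numpy(float),
            phb_content=df["phb_mg_per_g"].to_numpy(float),
            succinate=df["succinate_mM"].to_numpy(float),
            dry_weight_sd=sd("dry_weight_g_per_L_sd"),
            phb_content_sd=sd("phb_mg_per_g_sd"),
            succinate_sd=sd("succinate_mM_sd"),
        )

    @classmethod
    def from_csv(cls, path, sep: str = ",") -> "BatchTimeSeries":
        return cls.from_frame(pd.read_csv(path, sep=sep))

    def to_frame(self) -> pd.DataFrame:
        data = {
            "time_h": self.time,
            "dry_weight_g_per_L": self.dry_weight,
            "phb_mg_per_g": self.phb_content,
            "succinate_mM": self.succinate,
        }
        for col, arr in (
            ("dry_weight_g_per_L_sd", self.dry_weight_sd),
            ("phb_mg_per_g_sd", self.phb_content_sd),
            ("succinate_mM_sd", self.succinate_sd),
        ):
            if arr is not None:
                data[col] = arr
        return pd.DataFrame(data)


def load_packaged_timeseries() -> BatchTimeSeries:
    """The packaged batch-culture fixture (duplicate means ± sd).

    Inoculated at 0.04 g/L on 25 mM succinate at 34 degC under low
    shaking; sampled over 16 h for dry weight, PHB content and residual
    succinate.
    """
    with resources.files("phbflux.data").joinpath("batch_succinate_25mM.csv").open() as fh:
        return BatchTimeSeries.from_csv(fh)


#: Index window (start, stop inclusive) of the exponential phase used
#: for the packaged fixture: samples from 2 h through 16 h.
PACKAGED_EXP_WINDOW = (2, 8)


@dataclass
class RateEstimates:
    """Derived physiological rates with standard errors.

    mu in h^-1, yield_xs in g-DW per mol substrate, q_s in
    mmol g-DW^-1 h^-1, q_phb_mass in mg g-DW^-1 h^-1, q_phb_molar in
    mmol g-DW^-1 h^-1.  ``window`` records the indices used for the
    growth-rate regression.  By construction q_s = 1000*mu/yield_xs and
    q_phb_molar = q_phb_mass/96.
    """

    mu: float
    mu_se: float
    yield_xs: float
    yield_se: float
    q_s: float
    q_phb_mass: float
    q_phb_molar: float
    window: tuple[int, int]

    def to_dict(self) -> dict:
        return {
            "mu_per_h": self.mu,
            "mu_se": self.mu_se,
            "yield_gDW_per_mol": self.yield_xs,
            "yield_se": self.yield_se,
            "q_s_mmol_per_gDW_h": self.q_s,
            "q_phb_mg_per_gDW_h": self.q_phb_mass,
            "q_phb_mmol_per_gDW_h": self.q_phb_molar,
            "window": list(self.window),
        }


def od_to_biomass(od660: float) -> float:
    """Convert OD660 to dry-weight biomass, g/L (factor 0.365)."""
    od = np.asarray(od660, dtype=float)
    if np.any(od < 0):
        raise KineticsError("OD660 must be non-negative")
    result = od * OD660_TO_GDW_PER_L
    return float(result) if np.isscalar(od660) else result


def _regress(x: np.ndarray, y: np.ndarray):
    res = stats.linregress(x, y)
    return res.slope, res.stderr, res.rvalue**2


def select_exponential_window(
    series: BatchTimeSeries, r2_threshold: float = 0.98
) -> tuple[int, int]:
    """Longest contiguous window (>= 3 points) of log-linear growth.

    Among windows whose ln(biomass)-vs-time regression has R^2 at or
    above the threshold, returns the longest (ties broken by higher
    R^2); if none qualifies, returns the window with the highest R^2.
    """
    n = len(series)
    if n < 3:
        raise KineticsError("need at least 3 points to select a window")
    if np.any(series.dry_weight <= 0):
        raise KineticsError("dry weight must be positive for log regression")
    logx = np.log(series.dry_weight)
    best = None  # (passes, length, r2, (i, j))
    for i in range(n - 2):
        for j in range(i + 2, n):
            _, _, r2 = _regress(series.time[i : j + 1], logx[i : j + 1])
            key = (r2 >= r2_threshold, j - i + 1, r2)
            if best is None or key > best[:3]:
                best = (*key, (i, j))
    return best[3]


def fit_growth_rate(
    series: BatchTimeSeries, window: tuple[int, int] | None = None
) -> tuple[float, float]:
    """Specific growth rate: slope of ln(dry weight) vs time.

    ``window`` gives (first, last) point indices, inclusive; when None
    the exponential window is selected automatically.  Returns
    (mu, standard error) in h^-1.
    """
    if window is None:
        window = select_exponential_window(series)
    i, j = window
    t = series.time[i : j + 1]
    x = series.dry_weight[i : j + 1]
    if len(t) < 3:
        raise KineticsError("growth-rate window must contain at least 3 points")
    if np.any(x <= 0):
        raise KineticsError("dry weight must be positive inside the window")
    slope, se, _ = _regress(t, np.log(x))
    return float(slope), float(se)


def fit_yield(series: BatchTimeSeries) -> tuple[float, float]:
    """Biomass yield on substrate: slope of biomass vs consumed substrate.

    Regresses dry weight (g/L) on consumed succinate (mol/L) over all
    points; returns (yield, standard error) in g-DW per mol.
    """
    if len(series) < 3:
        raise KineticsError("need at least 3 points to fit a yield")
    consumed_mol = (series.succinate[0] - series.succinate) / 1000.0
    if consumed_mol[-1] <= 0:
        raise KineticsError("no net substrate consumption in the series")
    slope, se, _ = _regress(consumed_mol, series.dry_weight)
    return float(slope), float(se)


def specific_uptake(mu: float, yield_xs: float) -> float:
    """Specific substrate uptake rate q_s = 1000*mu/Y_XS, mmol g-DW^-1 h^-1."""
    if yield_xs <= 0:
        raise KineticsError(f"yield must be positive, got {yield_xs}")
    return 1000.0 * mu / yield_xs


def phb_specific_rate(mu: float, content_mg_per_g: float) -> tuple[float, float]:
    """Specific PHB production rate at constant fractional content.

    If the PHB content per dry weight stays constant while biomass grows
    exponentially, PHB is produced at mu * content (mg g-DW^-1 h^-1).
    Returns (mass rate, molar rate via the 96 g/mol monomer mass).
    """
    mass_rate = mu * content_mg_per_g
    return mass_rate, mass_rate / PHB_MONOMER_MOLAR_MASS


def accumulation_rate(w_start: float, w_end: float, dt: float) -> float:
    """Zero-growth PHB accumulation rate from a content step.

    ``w_start``/``w_end`` in mg per g dry weight, ``dt`` in hours;
    returns mmol g-DW^-1 h^-1 (96 g/mol monomer).
    """
    if dt <= 0:
        raise KineticsError(f"dt must be positive, got {dt}")
    return (w_end - w_start) / dt / PHB_MONOMER_MOLAR_MASS


def pirt_maintenance(mu_values, qs_values) -> tuple[float, float]:
    """Maintenance substrate coefficient from the Pirt relation.

    Fits q_s = mu / Y_max + m_s by least squares over (mu, q_s) pairs
    and returns the intercept m_s with its standard error, in the units
    of q_s.  Conversion to ATP units is left to the caller via an
    ATP-per-substrate factor.
    """
    mu_values = np.asarray(mu_values, dtype=float)
    qs_values = np.asarray(qs_values, dtype=float)
    if len(mu_values) < 3 or len(qs_values) != len(mu_values):
        raise KineticsError("need at least 3 (mu, q_s) pairs")
    res = stats.linregress(mu_values, qs_values)
    n = len(mu_values)
    # standard error of the intercept
    se = res.intercept_stderr
    return float(res.intercept), float(se)


def thiolase_sensitivity(fold_drop: float) -> float:
    """Rate fold-decrease of beta-ketothiolase for a substrate fold-drop.

    The thiolase condensation consumes two acetyl-CoA molecules, so far
    below saturation its rate is second order in acetyl-CoA: an n-fold
    concentration drop gives an n^2-fold rate drop.
    """
    if fold_drop <= 0:
        raise KineticsError(f"fold_drop must be positive, got {fold_drop}")
    return fold_drop**2


def estimate_rates(
    series: BatchTimeSeries,
    window: tuple[int, int] | None = None,
    phb_content: float | None = None,
) -> RateEstimates:
    """Full rate analysis of a batch series.

    ``phb_content`` (mg/g) defaults to the mean content over the growth
    window, reflecting the constant fractional PHB content observed
    during exponential growth.
    """
    if window is None:
        window = select_exponential_window(series)
    mu, mu_se = fit_growth_rate(series, window)
    yield_xs, yield_se = fit_yield(series)
    q_s = specific_uptake(mu, yield_xs)
    if phb_content is None:
        i, j = window
        phb_content = float(np.mean(series.phb_content[i : j + 1]))
    q_mass, q_molar = phb_specific_rate(mu, phb_content)
    return RateEstimates(
        mu=mu, mu_se=mu_se, yield_xs=yield_xs, yield_se=yield_se,
        q_s=q_s, q_phb_mass=q_mass, q_phb_molar=q_molar, window=tuple(window),
    )
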
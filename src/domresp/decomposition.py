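"""Greenhouse-gas release rates from headspace time series.

Sealed anoxic microcosms accumulate CO2/CH4 in a known headspace volume;
concentrations (ppm) measured over the incubation give the release rate

    R = dc/dt * V / M_v * M_w / m      [ug C g^-1 d^-1]

with dc/dt the fitted concentration slope (ppm d^-1), V the headspace
volume (L), M_v = 22.4 L mol^-1 the molar gas volume at STP, M_w the
molar mass of carbon and m the sediment dry weight (g).  Because ppm is
1e-6 mol fraction and the result is reported in micrograms, the two
factors cancel and the formula is numerically as written.

The incubation design re-flushes the headspace with N2 after each gas
sampling, so each measured concentration is the accumulation over one
interval; the default fit regresses per-interval concentration on
interval duration.  A cumulative-sum fit and a raw-series fit are
available for designs without re-flushing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("domresp")

MOLAR_VOLUME_STP = 22.4  # L mol^-1
MOLAR_MASS_C = 12.011  # g mol^-1


class GasSeriesError(ValueError):
    """Raised for invalid gas time series."""


def ml_to_l(volume_ml: float) -> float:
    return volume_ml / 1000.0


@dataclass
class GasSeries:
    """Headspace concentrations for one microcosm and one gas."""

    sample_id: str
    gas: str  # "CO2" or "CH4"
    times: np.ndarray  # day of measurement, strictly increasing
    concentrations: np.ndarray  # ppm accumulated over the preceding interval
    headspace_volume: float = 0.006  # L
    sediment_dry_mass: float = 5.0  # g
    molar_mass_c: float = MOLAR_MASS_C
    molar_volume: float = MOLAR_VOLUME_STP

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.shape != self.concentrations.shape or self.times.ndim != 1:
            raise GasSeriesError("times and concentrations must be equal-length vectors")
        if len(self.times) < 2:
            raise GasSeriesError("need at least 2 time points")
        if (np.diff(self.times) <= 0).any():
            raise GasSeriesError("times must be strictly increasing")
        if (self.concentrations < 0).any():
            raise GasSeriesError("concentrations must be nonnegative")
        if self.headspace_volume <= 0 or self.sediment_dry_mass <= 0:
            raise GasSeriesError("headspace volume and sediment mass must be positive")

    def interval_lengths(self) -> np.ndarray:
        """Interval durations, the first measured from day 0."""
        return np.diff(np.concatenate([[0.0], self.times]))


@dataclass
class RateResult:
    sample_id: str
    gas: str
    rate: float  # ug C g^-1 d^-1
    dcdt: float  # ppm d^-1
    cumulative_flux: float  # ug C g^-1 over the whole incubation
    final_concentration: float  # ppm, last interval
    negative_slope: bool = False


def _ppm_to_ugC_per_g(series: GasSeries) -> float:
    """Conversion factor from ppm to ug C per g sediment."""
    return series.headspace_volume / series.molar_volume * series.molar_mass_c / series.sediment_dry_mass


def release_rate(series: GasSeries, mode: str = "interval") -> RateResult:
    """Fit dc/dt and evaluate the release rate.

    ``mode``: "interval" (default) regresses per-interval concentration
    on interval duration (headspace re-flushed after each sampling);
    "cumulative" regresses the running concentration sum on measurement
    day; "series" regresses the raw concentrations on day (no flushing).
    A negative fitted slope (net uptake) is allowed and flagged.
    """
    conv = _ppm_to_ugC_per_g(series)
    if mode == "interval":
        x = series.interval_lengths()
        y = series.concentrations
    elif mode == "cumulative":
        x = series.times
        y = np.cumsum(series.concentrations)
    elif mode == "series":
        x = series.times
        y = series.concentrations
    else:
        raise GasSeriesError(f"unknown fitting mode {mode!r}")
    if np.ptp(x) == 0:
        # identical interval lengths: dc/dt is the mean per-interval rate
        dcdt = float(np.mean(y / x)) if mode == "interval" else float("nan")
        if np.isnan(dcdt):
            raise GasSeriesError("cannot fit a slope to constant time values")
    else:
        dcdt = float(stats.linregress(x, y).slope)
    rate = dcdt * conv
    if rate < 0:
        logger.info("negative fitted release rate for %s/%s (net uptake)",
                    series.sample_id, series.gas)
    return RateResult(
        sample_id=series.sample_id,
        gas=series.gas,
        rate=rate,
        dcdt=dcdt,
        cumulative_flux=float(series.concentrations.sum() * conv),
        final_concentration=float(series.concentrations[-1]),
        negative_slope=rate < 0,
    )


def release_rates(series_list, mode: str = "interval") -> pd.DataFrame:
    """Release rates for a collection of series, one row per (sample, gas)."""
    rows = [release_rate(s, mode=mode).__dict__ for s in series_list]
    return pd.DataFrame(rows)


def load_gas_series(table) -> list[GasSeries]:
    """Read the gas CSV (sample_id, gas, day, ppm, headspace_L, sediment_g)."""
    df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table)
    required = {"sample_id", "gas", "day", "ppm", "headspace_L", "sediment_g"}
    missing = required - set(df.columns)
    if missing:
        raise GasSeriesError(f"gas table missing columns {sorted(missing)}")
    out = []
    for (sid, gas), grp in df.groupby(["sample_id", "gas"], sort=False):
        grp = grp.sort_values("day")
        out.append(
            GasSeries(
                sample_id=str(sid),
                gas=str(gas),
                times=grp["day"].values,
                concentrations=grp["ppm"].values,
                headspace_volume=float(grp["headspace_L"].iloc[0]),
                sediment_dry_mass=float(grp["sediment_g"].iloc[0]),
            )
        )
    return out


def icer_function_link(
    icer_table: pd.DataFrame,
    functions: pd.DataFrame,
    variables=None,
    region_column: str | None = None,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Pearson correlations between iCER and ecosystem-function variables.

    ``icer_table`` needs ``sample_id`` and ``icer`` columns (one variant);
    ``functions`` one row per sample with the functional variables (gas
    fluxes, release rates, TOC, ...).  Records are produced overall and,
    when ``region_column`` is given, per region.
    """
    icer = icer_table.set_index("sample_id")["icer"].dropna()
    func = functions.set_index("sample_id")
    if variables is None:
        variables = [c for c in func.columns
                     if c != region_column and pd.api.types.is_numeric_dtype(func[c])]
    groups = [("all", func.index)]
    if region_column is not None:
        for region, sub in func.groupby(region_column):
            groups.append((str(region), sub.index))
    records = []
    for label, ids in groups:
        common = icer.index.intersection(ids)
        for var in variables:
            y = func.loc[common, var].dropna()
            x = icer.loc[y.index]
            if len(x) < min_pairs or np.ptp(x.values) == 0 or np.ptp(y.values) == 0:
                logger.info("link %s/%s skipped (%d usable pairs)", label, var, len(x))
                continue
            r, p = stats.pearsonr(x.values, y.values)
            records.append(
                {"group": label, "variable": var, "pearson_r": float(r),
                 "p_value": float(p), "n": len(x)}
            )
    return pd.DataFrame(records)
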
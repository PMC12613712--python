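"""Leaf-area allometry, daily LAI construction and canopy light interception.

The canopy model is the standard Beer-Lambert formulation for a closed
greenhouse row crop: daily intercepted PAR is

    IL_n = SR_n * T * p * (1 - exp(-k * LAI_n))

where SR_n is outside global solar radiation (MJ m-2 d-1), T the greenhouse
light transmission (default 0.51 MJ MJ-1), p the PAR fraction of global
radiation (default 0.5) and k the canopy extinction coefficient
(default 0.9).  Individual leaf area follows the cucumber allometry

    area = 0.8072 * width * length - 1.6083     [cm^2]

with negative outputs (tiny leaves) clamped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LEAF_AREA_SLOPE = 0.8072
LEAF_AREA_INTERCEPT = -1.6083
CM2_TO_M2 = 1e-4


@dataclass(frozen=True)
class CanopyParams:
    """Constants of the light-interception model.

    transmission : greenhouse light transmission (MJ MJ-1)
    par_ratio    : PAR fraction of global solar radiation (MJ MJ-1)
    k            : canopy light extinction coefficient (dimensionless)
    """

    transmission: float = 0.51
    par_ratio: float = 0.5
    k: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 < self.transmission <= 1.0:
            raise ValueError("transmission must be in (0, 1]")
        if not 0.0 < self.par_ratio <= 1.0:
            raise ValueError("par_ratio must be in (0, 1]")
        if not 0.0 < self.k <= 2.0:
            raise ValueError("k must be in (0, 2]")


def leaf_area(width_cm, length_cm):
    """Individual leaf area (cm^2) from leaf width and length (cm).

    Vectorised; negative allometry outputs are clamped to zero.
    """
    width_cm = np.asarray(width_cm, dtype=float)
    length_cm = np.asarray(length_cm, dtype=float)
    if (width_cm < 0).any() or (length_cm < 0).any():
        raise ValueError("leaf dimensions must be non-negative")
    area = LEAF_AREA_SLOPE * width_cm * length_cm + LEAF_AREA_INTERCEPT
    area = np.maximum(area, 0.0)
    if area.ndim == 0:
        return float(area)
    return area


def interpolate_lai_series(
    meas_dats: np.ndarray, meas_lai: np.ndarray, trial_length: int
) -> pd.DataFrame:
    """Daily LAI from values at measurement dates.

    Linear interpolation between measurements, linear extrapolation from
    (0, 0) to the first measurement, and constant extension after the last
    one.  Returns a frame with ``dat``, ``lai`` and a ``provenance`` flag
    (measured | interpolated | extrapolated).

    This interpolation rule is shared by the estimator (:func:`build_lai`)
    and the synthetic-trial generator, which defines its latent LAI
    trajectory through the same rule.
    """
    meas_dats = np.asarray(meas_dats, dtype=float)
    meas_lai = np.asarray(meas_lai, dtype=float)
    order = np.argsort(meas_dats)
    meas_dats, meas_lai = meas_dats[order], meas_lai[order]

    dat = np.arange(trial_length)
    # anchor at (0, 0) unless a measurement exists at DAT 0
    if meas_dats[0] > 0:
        xs = np.concatenate(([0.0], meas_dats))
        ys = np.concatenate(([0.0], meas_lai))
    else:
        xs, ys = meas_dats, meas_lai
    lai = np.interp(dat, xs, ys)  # constant beyond the last measurement

    provenance = np.where(
        np.isin(dat, meas_dats),
        "measured",
        np.where(dat < meas_dats[0], "extrapolated", "interpolated"),
    )
    provenance = np.where(dat > meas_dats[-1], "extrapolated", provenance)
    return pd.DataFrame({"dat": dat, "lai": lai, "provenance": provenance})


def build_lai(
    leaf_obs: pd.DataFrame, density: float, trial_length: int
) -> pd.DataFrame:
    """Daily LAI series from per-stem leaf measurements.

    Parameters
    ----------
    leaf_obs
        Long table with columns ``plant`` (stem identifier), ``dat``,
        ``width_cm``, ``length_cm``; one row per leaf.
    density
        Stems per m2 of ground (leaves are recorded per stem-grown plant).
    trial_length
        Number of daily rows to emit (DAT 0..trial_length-1).

    At each measurement date, LAI is the mean over measured stems of the
    summed leaf area (cm^2 -> m^2) times ``density``.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    if leaf_obs.empty:
        raise ValueError("leaf_obs is empty")
    obs = leaf_obs.copy()
    obs["area_cm2"] = leaf_area(obs["width_cm"].to_numpy(), obs["length_cm"].to_numpy())
    per_stem = obs.groupby(["dat", "plant"])["area_cm2"].sum()
    per_date = per_stem.groupby("dat").mean() * CM2_TO_M2 * density
    return interpolate_lai_series(
        per_date.index.to_numpy(), per_date.to_numpy(), trial_length
    )


def daily_interception(
    climate: pd.DataFrame, lai: pd.DataFrame, params: CanopyParams | None = None
) -> pd.DataFrame:
    """Daily and cumulative intercepted PAR (MJ m-2).

    ``lai`` must cover every climate day.  Returns ``dat, il, cum_il`` with
    the cumulative sum running from the first climate day.
    """
    params = params or CanopyParams()
    lai_by_dat = lai.set_index("dat")["lai"]
    dats = climate["dat"].to_numpy()
    missing = np.setdiff1d(dats, lai_by_dat.index.to_numpy())
    if missing.size:
        raise ValueError(f"LAI series does not cover climate DATs {missing[:5]}...")
    lai_vals = lai_by_dat.loc[dats].to_numpy(dtype=float)
    il = (
        climate["solar"].to_numpy(dtype=float)
        * params.transmission
        * params.par_ratio
        * (1.0 - np.exp(-params.k * lai_vals))
    )
    return pd.DataFrame({"dat": dats, "il": il, "cum_il": np.cumsum(il)})


def estimate_k(above_par, below_par, lai) -> float:
    """Canopy extinction coefficient from paired above/below-canopy PAR.

    Beer-Lambert inversion: per pair k = -ln(below/above) / LAI; with
    multiple pairs the returned k is the least-squares slope of
    -ln(transmittance) on LAI through the origin.
    """
    above = np.atleast_1d(np.asarray(above_par, dtype=float))
    below = np.atleast_1d(np.asarray(below_par, dtype=float))
    lai_v = np.atleast_1d(np.asarray(lai, dtype=float))
    if (below <= 0).any() or (above <= 0).any():
        raise ValueError("PAR readings must be positive")
    if (below > above).any():
        raise ValueError("below-canopy PAR cannot exceed above-canopy PAR")
    if (lai_v <= 0).any():
        raise ValueError("LAI at measurement must be positive")
    y = -np.log(below / above)
    return float(np.dot(lai_v, y) / np.dot(lai_v, lai_v))
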
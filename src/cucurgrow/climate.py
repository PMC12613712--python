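"""Synthetic greenhouse climate driver.

Emulates a heated/ventilated glasshouse trial transplanted in mid-October:
daily mean air temperature inside the house follows a seasonal sinusoid
clipped to the heating/ventilation setpoints (15/28 degC), and outside global
solar radiation follows a seasonal sinusoid with its minimum at the winter
solstice (roughly two months into the trial).

The default mean solar level is calibrated so that cumulative intercepted
PAR over the full trial, under the default canopy (transmission 0.51, PAR
ratio 0.5, k = 0.9, LAI ramping to 2.4), is consistent with the packaged
cultivar scenarios' dry-matter targets (TDM ~ LUE x cumulative IL).  See
``cucurgrow.scenarios.calibrate_mean_solar``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

HEAT_SETPOINT = 15.0  # degC, heating-pipe setpoint
VENT_SETPOINT = 28.0  # degC, ventilation setpoint
TRANSPLANT_DOY = 288  # mid-October transplanting (DAT 0)
WINTER_SOLSTICE_DOY = 355

#: Outside global solar radiation level (MJ m-2 d-1, annual mean of the
#: seasonal sinusoid).  Calibrated once against the packaged 'josho'
#: scenario (see scenarios.calibrate_mean_solar and tests).
DEFAULT_MEAN_SOLAR = 8.495

#: Number of daily rows covering DAT 0..228 of the packaged 228-day trial.
DEFAULT_TRIAL_LENGTH = 229

CLIMATE_COLUMNS = ["dat", "doy", "t_mean", "solar", "co2"]


def _seasonal(dat: np.ndarray, transplant_doy: int) -> np.ndarray:
    """cos term with minimum at the winter solstice; -1 at the solstice."""
    doy = transplant_doy + dat
    return -np.cos(2.0 * np.pi * (doy - WINTER_SOLSTICE_DOY) / 365.0)


def generate_climate(
    trial_length: int = DEFAULT_TRIAL_LENGTH,
    seed: int = 0,
    mean_solar: float = DEFAULT_MEAN_SOLAR,
    setpoints: tuple[float, float] = (HEAT_SETPOINT, VENT_SETPOINT),
    t_base: float = 22.0,
    t_amp: float = 3.0,
    solar_amp_frac: float = 0.42,
    t_noise_sd: float = 1.2,
    solar_noise_sd: float = 0.30,
    transplant_doy: int = TRANSPLANT_DOY,
    co2_base: float = 430.0,
) -> pd.DataFrame:
    """Generate one trial's daily climate table.

    Parameters
    ----------
    trial_length
        Number of daily rows; row ``i`` is DAT ``i`` (DAT 0 = transplanting).
    seed
        Seed for the noise streams; identical arguments give identical tables.
    mean_solar
        Annual-mean level of the outside global solar radiation sinusoid
        (MJ m-2 d-1).
    setpoints
        (heating, ventilation) setpoints in degC; daily means are clipped to
        this band.
    t_base, t_amp
        Centre and seasonal amplitude of the in-house daily mean temperature
        sinusoid (degC).
    solar_amp_frac
        Seasonal amplitude of solar radiation as a fraction of ``mean_solar``.
    t_noise_sd
        SD of additive Gaussian day-to-day temperature noise (degC).
    solar_noise_sd
        SD (log scale) of mean-preserving multiplicative log-normal solar
        noise; keeps radiation non-negative.
    transplant_doy
        Calendar day-of-year of DAT 0 (default: mid-October).
    co2_base
        Daytime CO2 level (umol mol-1); decorative driver, sinusoid + noise.

    Returns
    -------
    DataFrame with columns ``dat, doy, t_mean, solar, co2``.
    """
    if trial_length < 1:
        raise ValueError(f"trial_length must be >= 1, got {trial_length}")
    heat, vent = setpoints
    if not heat < vent:
        raise ValueError("heating setpoint must be below ventilation setpoint")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    dat = np.arange(trial_length)
    season = _seasonal(dat, transplant_doy)

    t_mean = t_base + t_amp * season
    if t_noise_sd > 0:
        t_mean = t_mean + rng.normal(0.0, t_noise_sd, trial_length)
    t_mean = np.clip(t_mean, heat, vent)

    solar = mean_solar * (1.0 + solar_amp_frac * season)
    if solar_noise_sd > 0:
        # mean-preserving log-normal: E[exp(sd*Z - sd^2/2)] = 1
        z = rng.normal(0.0, 1.0, trial_length)
        solar = solar * np.exp(solar_noise_sd * z - 0.5 * solar_noise_sd**2)
    solar = np.maximum(solar, 0.0)

    co2 = co2_base - 60.0 * season + rng.normal(0.0, 15.0, trial_length)

    return pd.DataFrame(
        {
            "dat": dat,
            "doy": (transplant_doy + dat - 1) % 365 + 1,
            "t_mean": t_mean,
            "solar": solar,
            "co2": co2,
        }
    )


def validate_climate(climate: pd.DataFrame) -> None:
    """Raise ``ValueError`` if a climate table violates its invariants."""
    missing = [c for c in ("dat", "t_mean", "solar") if c not in climate.columns]
    if missing:
        raise ValueError(f"climate table missing columns: {missing}")
    dat = climate["dat"].to_numpy()
    if len(dat) == 0:
        raise ValueError("climate table is empty")
    if not np.array_equal(dat, np.arange(dat[0], dat[0] + len(dat))):
        raise ValueError("climate DATs must be consecutive daily values")
    if (climate["solar"] < 0).any():
        raise ValueError("solar radiation must be non-negative")
    t = climate["t_mean"]
    if ((t < 5.0) | (t > 40.0)).any():
        raise ValueError("daily mean temperature outside plausible [5, 40] degC")
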
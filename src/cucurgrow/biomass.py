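"""Total dry matter bookkeeping, interval DM production, fruit partitioning
and the light-use-efficiency regression.

Aboveground total dry matter (TDM) at a destructive sampling is the measured
standing biomass plus the plant's harvested-fruit and trimmed-leaf dry-weight
ledgers.  Interval DM production follows the trial's convention: each
later-timepoint plant's TDM minus the MEAN TDM at the earlier timepoint
(not plant-paired).  LUE is the slope of (per-area TDM - initial dry weight)
regressed on cumulative intercepted PAR, through the origin by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

#: Destructive-measurement interval boundaries (DAT): five terms.
DEFAULT_TERMS: tuple[tuple[int, int], ...] = (
    (0, 45),
    (45, 66),
    (66, 105),
    (105, 142),
    (142, 228),
)

ORGAN_COLUMNS = ("leaf_dw", "stem_dw", "fruit_dw")


def validate_terms(terms) -> list[tuple[int, int]]:
    terms = [tuple(t) for t in terms]
    for (s0, e0), (s1, _) in zip(terms, terms[1:]):
        if e0 != s1:
            raise ValueError("terms must be contiguous and non-overlapping")
    if any(e <= s for s, e in terms):
        raise ValueError("each term must have end > start")
    return terms


def compute_tdm(
    destructive_obs: pd.DataFrame,
    density: float,
    stems_per_plant: int = 2,
    harvest_dm_ledger: pd.DataFrame | None = None,
    trim_ledger: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-plant TDM records from the destructive table.

    ``destructive_obs`` carries per plant and DAT the standing organ dry
    weights (``leaf_dw``, ``stem_dw``, ``fruit_dw``; g) and, normally, the
    ledger columns ``harvested_fruit_dm`` and ``trimmed_leaf_dm`` (g to
    date).  Separate ledger frames (columns ``plant, value``) may override
    the embedded columns.

    Returns one row per sampled plant with ``standing_dw``, ``tdm`` (g per
    plant), ``tdm_area`` (g m-2, scaled by density / stems_per_plant) and
    ``fruit_cum_dm`` / ``fruit_cum_dm_area`` (harvested + on-plant fruit DM).
    """
    if density <= 0 or stems_per_plant <= 0:
        raise ValueError("density and stems_per_plant must be positive")
    obs = destructive_obs.copy()
    for ledger, col in ((harvest_dm_ledger, "harvested_fruit_dm"), (trim_ledger, "trimmed_leaf_dm")):
        if ledger is not None:
            obs = obs.drop(columns=[col], errors="ignore").merge(
                ledger.rename(columns={"value": col}), on="plant", how="left"
            )
    for col in ORGAN_COLUMNS + ("harvested_fruit_dm", "trimmed_leaf_dm"):
        if col not in obs.columns:
            raise ValueError(f"destructive table missing column {col!r}")
        if obs[col].isna().any():
            raise ValueError(f"missing values in destructive column {col!r}")

    plants_per_m2 = density / stems_per_plant
    standing = obs[list(ORGAN_COLUMNS)].sum(axis=1)
    tdm = standing + obs["harvested_fruit_dm"] + obs["trimmed_leaf_dm"]
    fruit_cum = obs["fruit_dw"] + obs["harvested_fruit_dm"]
    return pd.DataFrame(
        {
            "plant": obs["plant"],
            "dat": obs["dat"],
            "standing_dw": standing,
            "harvested_fruit_dm": obs["harvested_fruit_dm"],
            "trimmed_leaf_dm": obs["trimmed_leaf_dm"],
            "tdm": tdm,
            "tdm_area": tdm * plants_per_m2,
            "fruit_cum_dm": fruit_cum,
            "fruit_cum_dm_area": fruit_cum * plants_per_m2,
        }
    )


def _term_means(records: pd.DataFrame, dat: int, col: str) -> float:
    vals = records.loc[records["dat"] == dat, col]
    if vals.empty:
        raise ValueError(f"no destructive samples at term boundary DAT {dat}")
    return float(vals.mean())


def interval_dm_production(
    records: pd.DataFrame, terms=DEFAULT_TERMS
) -> pd.DataFrame:
    """Per-term DM production (g m-2) per later-timepoint plant.

    Each plant sampled at a term's end contributes its ``tdm_area`` minus
    the mean ``tdm_area`` at the term's start.  Returns long format
    ``term, start, end, plant, d_tdm`` plus per-term mean and 95% CI.
    """
    terms = validate_terms(terms)
    rows = []
    for idx, (start, end) in enumerate(terms, start=1):
        start_mean = _term_means(records, start, "tdm_area")
        later = records.loc[records["dat"] == end]
        if later.empty:
            raise ValueError(f"no destructive samples at term boundary DAT {end}")
        for row in later.itertuples(index=False):
            rows.append(
                {
                    "term": idx,
                    "start": start,
                    "end": end,
                    "plant": row.plant,
                    "d_tdm": row.tdm_area - start_mean,
                }
            )
    out = pd.DataFrame(rows)
    summary = (
        out.groupby(["term", "start", "end"])["d_tdm"]
        .agg(["mean", "count", "std"])
        .reset_index()
    )
    half = np.where(
        summary["count"] > 1,
        stats.t.ppf(0.975, np.maximum(summary["count"] - 1, 1))
        * summary["std"]
        / np.sqrt(summary["count"]),
        0.0,
    )
    summary["ci_low"] = summary["mean"] - half
    summary["ci_high"] = summary["mean"] + half
    out.attrs["summary"] = summary
    return out


def fruit_partition_fraction(
    records: pd.DataFrame,
    terms=DEFAULT_TERMS,
    fruit_dm_by_term: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-term fruit fraction of newly produced DM (g g-1).

    Fruit DM produced in a term is the change in cumulative fruit DM
    (harvested in the interval + change in on-plant fruit DM), taken per
    later-timepoint plant against the earlier timepoint's means — the same
    convention as :func:`interval_dm_production`.  Terms with non-positive
    DM production are reported as missing rather than raising.

    ``fruit_dm_by_term`` (columns ``term, fruit_dm``) may override the
    fruit-DM numerator, e.g. when fruit ledgers are tabulated separately.
    """
    terms = validate_terms(terms)
    override = (
        fruit_dm_by_term.set_index("term")["fruit_dm"]
        if fruit_dm_by_term is not None
        else None
    )
    rows = []
    for idx, (start, end) in enumerate(terms, start=1):
        tdm_start = _term_means(records, start, "tdm_area")
        fruit_start = _term_means(records, start, "fruit_cum_dm_area")
        later = records.loc[records["dat"] == end]
        fracs = []
        for row in later.itertuples(index=False):
            d_tdm = row.tdm_area - tdm_start
            if override is not None:
                d_fruit = float(override.loc[idx])
            else:
                d_fruit = row.fruit_cum_dm_area - fruit_start
            fracs.append(d_fruit / d_tdm if d_tdm > 0 else np.nan)
        fracs = np.asarray(fracs, dtype=float)
        valid = fracs[~np.isnan(fracs)]
        lo, hi = (np.nan, np.nan)
        mean = np.nan
        if valid.size:
            mean = float(valid.mean())
            if valid.size > 1:
                half = (
                    stats.t.ppf(0.975, valid.size - 1)
                    * valid.std(ddof=1)
                    / np.sqrt(valid.size)
                )
                lo, hi = mean - half, mean + half
            else:
                lo = hi = mean
        rows.append(
            {
                "term": idx,
                "start": start,
                "end": end,
                "fraction": mean,
                "ci_low": lo,
                "ci_high": hi,
                "n": int(valid.size),
                "undefined": bool(valid.size == 0),
            }
        )
    return pd.DataFrame(rows)


def cumulative_fruit_fraction(records: pd.DataFrame) -> pd.DataFrame:
    """Cumulative fruit DM relative to TDM at each destructive timepoint.

    Per plant: (harvested + on-plant fruit DM) / TDM; reported as the mean
    over plants with a t-based 95% CI.  A timepoint where TDM is zero
    (DAT 0 before any growth) reports 0 by convention.
    """
    rows = []
    for dat, grp in records.groupby("dat", sort=True):
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(
                grp["tdm_area"] > 0,
                grp["fruit_cum_dm_area"] / grp["tdm_area"],
                0.0,
            )
        mean = float(np.mean(frac))
        if len(frac) > 1:
            half = (
                stats.t.ppf(0.975, len(frac) - 1)
                * np.std(frac, ddof=1)
                / np.sqrt(len(frac))
            )
            lo, hi = mean - half, mean + half
        else:
            lo = hi = mean
        rows.append(
            {"dat": dat, "fraction": mean, "ci_low": lo, "ci_high": hi, "n": len(frac)}
        )
    return pd.DataFrame(rows)


@dataclass
class LueFit:
    """LUE regression result (slope in g DM per MJ intercepted PAR)."""

    slope: float
    se: float
    ci_low: float
    ci_high: float
    intercept: float
    n: int
    through_origin: bool


def estimate_lue(
    records: pd.DataFrame,
    cum_il: pd.DataFrame,
    initial_dw: float | None = None,
    through_origin: bool = True,
) -> LueFit:
    """Light-use efficiency from destructive TDM and cumulative interception.

    Ordinary least squares of (per-area TDM - initial dry weight) on
    cumulative intercepted PAR at the destructive DATs; through the origin
    by default (subtracting the initial dry weight makes a zero-intercept
    fit the natural model).  ``initial_dw`` defaults to the mean per-area
    TDM at the earliest destructive DAT.
    """
    if records["dat"].nunique() < 2:
        raise ValueError("need destructive samples at >= 2 timepoints")
    if initial_dw is None:
        initial_dw = _term_means(records, int(records["dat"].min()), "tdm_area")
    cum = cum_il.set_index("dat")["cum_il"]
    x = cum.loc[records["dat"]].to_numpy(dtype=float)
    y = records["tdm_area"].to_numpy(dtype=float) - initial_dw
    exog = x[:, None] if through_origin else sm.add_constant(x)
    fit = sm.OLS(y, exog).fit()
    slope_idx = 0 if through_origin else 1
    ci = fit.conf_int()[slope_idx]
    return LueFit(
        slope=float(fit.params[slope_idx]),
        se=float(fit.bse[slope_idx]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        intercept=0.0 if through_origin else float(fit.params[0]),
        n=len(y),
        through_origin=through_origin,
    )
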
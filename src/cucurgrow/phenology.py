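"""Thermal-time phenology: accumulated temperature, node-increase curves,
node formation rate (NFR) and flower-position metrics.

Thermal time is the running sum of daily mean temperature from a reference
DAT with base temperature 0 degC (the accumulation simply sums the daily
averages; a non-zero base can be passed for sensitivity analyses).  NFR is
expressed in nodes per accumulated degC day.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

NODE_OBS_START_DAT = 38  # baseline DAT of the node-count observations


def accumulate_thermal_time(
    climate: pd.DataFrame, start_dat: int = NODE_OBS_START_DAT, base_temp: float = 0.0
) -> pd.DataFrame:
    """Accumulated daily average temperature from ``start_dat``.

    AT(start_dat) = 0 and AT(d) = sum_{i=start_dat+1..d} max(t_mean(i) - base, 0).

    Returns one row per climate day from ``start_dat`` to the end, with
    columns ``dat, t_mean, at``.
    """
    dats = climate["dat"].to_numpy()
    if start_dat < dats.min() or start_dat > dats.max():
        raise ValueError(
            f"start_dat {start_dat} outside climate range [{dats.min()}, {dats.max()}]"
        )
    sub = climate.loc[climate["dat"] >= start_dat, ["dat", "t_mean"]].reset_index(
        drop=True
    )
    eff = np.maximum(sub["t_mean"].to_numpy(dtype=float) - base_temp, 0.0)
    at = np.concatenate(([0.0], np.cumsum(eff[1:])))
    out = sub.copy()
    out["at"] = at
    return out


def at_on(thermal: pd.DataFrame, dats) -> np.ndarray:
    """AT linearly interpolated to (possibly fractional) observation DATs."""
    return np.interp(
        np.asarray(dats, dtype=float),
        thermal["dat"].to_numpy(dtype=float),
        thermal["at"].to_numpy(dtype=float),
    )


def node_increase(
    node_obs: pd.DataFrame,
    thermal: pd.DataFrame,
    start_dat: int = NODE_OBS_START_DAT,
    baseline_window: int = 3,
) -> pd.DataFrame:
    """Per-plant baseline-subtracted node counts joined to thermal time.

    The baseline is each plant's observation at ``start_dat`` (or the
    nearest one within ``baseline_window`` days); plants without a baseline
    are dropped with a logged warning.  Returns columns
    ``plant, dat, node_count, node_increase, at``.
    """
    if node_obs.empty:
        raise ValueError("node_obs is empty")
    frames = []
    for plant, grp in node_obs.groupby("plant", sort=True):
        grp = grp.sort_values("dat")
        offsets = (grp["dat"] - start_dat).abs()
        if offsets.min() > baseline_window:
            log.warning(
                "plant %s has no node observation within %d days of DAT %d; dropped",
                plant,
                baseline_window,
                start_dat,
            )
            continue
        baseline = grp.loc[offsets.idxmin(), "node_count"]
        out = grp.loc[:, ["plant", "dat", "node_count"]].copy()
        out["node_increase"] = out["node_count"] - baseline
        frames.append(out)
    if not frames:
        raise ValueError("no plant has a usable baseline observation")
    curve = pd.concat(frames, ignore_index=True)
    curve["at"] = at_on(thermal, curve["dat"])
    return curve


@dataclass
class NfrEstimate:
    """Mean NFR (nodes per degC day) with a t-based 95% CI across plants."""

    method: str
    estimate: float
    ci_low: float
    ci_high: float
    per_plant: pd.Series = field(repr=False)
    windows: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_plants(self) -> int:
        return len(self.per_plant)


def _t_ci(values: np.ndarray, alpha: float = 0.05) -> tuple[float, float]:
    n = len(values)
    mean = float(np.mean(values))
    if n < 2:
        return mean, mean
    half = stats.t.ppf(1 - alpha / 2, n - 1) * np.std(values, ddof=1) / np.sqrt(n)
    return mean - half, mean + half


def estimate_nfr(curve: pd.DataFrame, method: str = "mean") -> NfrEstimate:
    """Node formation rate from a node-increase curve.

    method="mean"
        Per plant, final node increase divided by final AT; averaged over
        plants.
    method="windowed"
        Successive finite differences d(nodes)/d(AT) per inter-observation
        interval; the per-plant value is their AT-weighted mean (identical
        to "mean" by the telescoping identity).
    """
    if method not in ("mean", "windowed"):
        raise ValueError(f"unknown method {method!r}")
    per_plant = {}
    windows = []
    for plant, grp in curve.groupby("plant", sort=True):
        grp = grp.sort_values("dat")
        if len(grp) < 2:
            raise ValueError(f"plant {plant} has fewer than 2 observations")
        at = grp["at"].to_numpy(dtype=float)
        inc = grp["node_increase"].to_numpy(dtype=float)
        span = at[-1] - at[0]
        if span <= 0:
            raise ZeroDivisionError(f"plant {plant} has zero AT span")
        if method == "mean":
            per_plant[plant] = (inc[-1] - inc[0]) / span
        else:
            d_at = np.diff(at)
            if (d_at <= 0).any():
                raise ZeroDivisionError(f"plant {plant} has a zero-AT window")
            rate = np.diff(inc) / d_at
            windows.append(
                pd.DataFrame(
                    {
                        "plant": plant,
                        "at_mid": (at[1:] + at[:-1]) / 2.0,
                        "d_at": d_at,
                        "nfr": rate,
                    }
                )
            )
            per_plant[plant] = float(np.dot(rate, d_at) / d_at.sum())
    per_plant = pd.Series(per_plant, name="nfr")
    lo, hi = _t_ci(per_plant.to_numpy())
    return NfrEstimate(
        method=method,
        estimate=float(per_plant.mean()),
        ci_low=lo,
        ci_high=hi,
        per_plant=per_plant,
        windows=pd.concat(windows, ignore_index=True) if windows else None,
    )


def flower_distance_to_tip(node_obs: pd.DataFrame) -> pd.DataFrame:
    """Distance (nodes) from each open female flower to the shoot tip.

    ``node_obs`` rows carry ``node_count`` and ``flower_nodes`` (iterable or
    ';'-joined string of node positions with an open female flower).
    Returns per-plant mean distance with a t-based 95% CI.
    """
    records = []
    for row in node_obs.itertuples(index=False):
        positions = getattr(row, "flower_nodes", None)
        if positions is None or (isinstance(positions, float) and np.isnan(positions)):
            continue
        if isinstance(positions, str):
            positions = [int(p) for p in positions.split(";") if p.strip()]
        for pos in positions:
            if pos > row.node_count:
                raise ValueError(
                    f"flower position {pos} exceeds node count {row.node_count} "
                    f"(plant {row.plant}, DAT {row.dat})"
                )
            records.append((row.plant, row.dat, row.node_count - pos))
    dist = pd.DataFrame(records, columns=["plant", "dat", "distance"])
    out = []
    for plant, grp in dist.groupby("plant", sort=True):
        lo, hi = _t_ci(grp["distance"].to_numpy(dtype=float))
        out.append(
            {
                "plant": plant,
                "n_flowers": len(grp),
                "mean_distance": grp["distance"].mean(),
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(out)
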
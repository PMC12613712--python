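"""Harvest-event processing into yield components.

Daily harvest events (per plant, fruit fresh weight in g) are split into
kept and aborted fruits (aborted: fresh weight strictly below 3.0 g),
accumulated into a fresh-yield series per m2 of ground, and combined with
node counts into the female flowering rate.  Dry yield is fresh yield times
the fruit dry-matter content.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ABORTION_THRESHOLD_G = 3.0


def planting_density(
    row_spacing_m: float, plant_spacing_m: float, stems_per_plant: int
) -> float:
    """Stems per m2 of ground: stems_per_plant / (row * plant spacing)."""
    if row_spacing_m <= 0 or plant_spacing_m <= 0 or stems_per_plant <= 0:
        raise ValueError("spacings and stems per plant must be positive")
    return stems_per_plant / (row_spacing_m * plant_spacing_m)


def filter_aborted(
    harvest_events: pd.DataFrame, threshold: float = ABORTION_THRESHOLD_G
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split harvest events into (kept, aborted) by fresh weight.

    Strictly-below semantics: FW < threshold is aborted, FW == threshold is
    kept.  Negative fresh weights raise.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if harvest_events.empty:
        empty = harvest_events.copy()
        return empty, empty.copy()
    fw = harvest_events["fruit_fw_g"]
    if (fw < 0).any():
        raise ValueError("negative fruit fresh weight in harvest events")
    aborted_mask = fw < threshold
    return (
        harvest_events.loc[~aborted_mask].reset_index(drop=True),
        harvest_events.loc[aborted_mask].reset_index(drop=True),
    )


@dataclass
class YieldSummary:
    """Cultivar-level harvest summary on a per-m2 ground basis."""

    fresh_yield_kg_m2: float
    fruit_number_m2: float
    mean_fruit_fw_g: float
    abortion_ratio: float
    n_kept: int
    n_aborted: int
    n_plants: int
    series: pd.DataFrame = field(repr=False)  # dat, cum_fresh_kg_m2
    per_plant: pd.DataFrame = field(repr=False)


def yield_summary(
    kept: pd.DataFrame,
    aborted: pd.DataFrame,
    density: float,
    stems_per_plant: int = 2,
    first_harvest_dat: int = 39,
    trial_end_dat: int | None = None,
) -> YieldSummary:
    """Cumulative fresh yield, fruit number, mean fruit weight and abortion.

    Per-m2 conversion multiplies per-plant totals by density /
    stems_per_plant (plants per m2; a double-shoot plant holds two stems).
    The abortion ratio counts aborted over all events; mean fruit weight is
    over kept fruits only.  The daily cumulative series runs from
    ``first_harvest_dat`` to ``trial_end_dat``.
    """
    if density <= 0 or stems_per_plant <= 0:
        raise ValueError("density and stems_per_plant must be positive")
    plants_per_m2 = density / stems_per_plant
    plants = sorted(
        set(kept.get("plant", pd.Series(dtype=object)))
        | set(aborted.get("plant", pd.Series(dtype=object)))
    )
    n_plants = len(plants)
    n_kept, n_aborted = len(kept), len(aborted)
    total = n_kept + n_aborted

    if n_plants:
        per_plant_fw = (
            kept.groupby("plant")["fruit_fw_g"].sum().reindex(plants, fill_value=0.0)
        )
        per_plant_n = (
            kept.groupby("plant")["fruit_fw_g"].size().reindex(plants, fill_value=0)
        )
        mean_total_fw = float(per_plant_fw.mean())  # g per plant
        mean_total_n = float(per_plant_n.mean())
    else:
        per_plant_fw = pd.Series(dtype=float)
        per_plant_n = pd.Series(dtype=float)
        mean_total_fw = 0.0
        mean_total_n = 0.0

    fresh_yield = mean_total_fw * plants_per_m2 / 1000.0  # kg m-2
    fruit_number = mean_total_n * plants_per_m2

    if trial_end_dat is None:
        all_dats = pd.concat(
            [kept.get("dat", pd.Series(dtype=int)), aborted.get("dat", pd.Series(dtype=int))]
        )
        trial_end_dat = int(all_dats.max()) if len(all_dats) else first_harvest_dat
    dats = np.arange(first_harvest_dat, trial_end_dat + 1)
    if n_kept and n_plants:
        daily = (
            kept.groupby("dat")["fruit_fw_g"].sum().reindex(dats, fill_value=0.0)
            / n_plants
        )
        cum = daily.cumsum() * plants_per_m2 / 1000.0
    else:
        cum = pd.Series(0.0, index=dats)
    series = pd.DataFrame({"dat": dats, "cum_fresh_kg_m2": cum.to_numpy()})

    per_plant = pd.DataFrame(
        {
            "plant": plants,
            "fresh_yield_kg_m2": per_plant_fw.to_numpy() * plants_per_m2 / 1000.0
            if n_plants
            else [],
            "fruit_number_m2": per_plant_n.to_numpy() * plants_per_m2
            if n_plants
            else [],
        }
    )
    if n_plants:
        mean_kept = kept.groupby("plant")["fruit_fw_g"].mean()
        per_plant["mean_fruit_fw_g"] = mean_kept.reindex(plants).to_numpy()
        ab_n = (
            aborted.groupby("plant")["fruit_fw_g"].size().reindex(plants, fill_value=0)
        )
        tot_n = per_plant_n + ab_n
        with np.errstate(invalid="ignore"):
            per_plant["abortion_ratio"] = np.where(
                tot_n > 0, ab_n / tot_n, np.nan
            )

    return YieldSummary(
        fresh_yield_kg_m2=fresh_yield,
        fruit_number_m2=fruit_number,
        mean_fruit_fw_g=float(kept["fruit_fw_g"].mean()) if n_kept else np.nan,
        abortion_ratio=n_aborted / total if total else np.nan,
        n_kept=n_kept,
        n_aborted=n_aborted,
        n_plants=n_plants,
        series=series,
        per_plant=per_plant,
    )


def female_flowering_rate(
    total_fruit_number: float, final_node_number: float
) -> float:
    """Fruits (kept + aborted, premature excluded) per final node, per stem."""
    if final_node_number <= 0:
        raise ValueError("final node number must be positive")
    if total_fruit_number < 0:
        raise ValueError("fruit number cannot be negative")
    return total_fruit_number / final_node_number


def dry_yield(fresh_yield_kg_m2, fruit_dmc: float):
    """Dry yield = fresh yield x fruit dry-matter content (g dry / g fresh).

    Accepts a scalar or a series; dmc must lie in (0, 1].
    """
    if not 0.0 < fruit_dmc <= 1.0:
        raise ValueError("fruit DM content must be in (0, 1]")
    return fresh_yield_kg_m2 * fruit_dmc
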
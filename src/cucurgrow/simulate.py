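"""Synthetic greenhouse-trial generator.

Produces the five raw observation tables of one cultivar's trial (climate,
node counts with flower positions, leaf dimensions, destructive dry weights
with harvest/trim ledgers, daily harvest events) from a
:class:`~cucurgrow.scenarios.CultivarScenario`, as the statistical inverse
of the analysis pipeline:

* nodes follow ``N(t) = N38 + NFR x AT(t)`` from 38 DAT (a slower linear
  establishment phase before 38 DAT), observed as rounded counts;
* the latent daily LAI ramps to its plateau and generates per-stem leaf
  width/length records that invert the leaf-area allometry;
* latent per-area TDM is ``initial DW + LUE x cumulative intercepted PAR``
  under the realized climate; cumulative fruit DM follows the per-term
  partition schedule applied to TDM increments;
* each node from the first fruiting position sets a fruit with the
  scenario's flowering probability; fruits are harvested a fixed thermal
  lag after node formation (no earlier than the first harvest day) and
  each kept fruit's fresh weight carries the increment of the per-stem
  cumulative fruit-DM curve since the previous harvest, divided by fruit
  DM content — so fresh yield, partition fractions and fruit fraction are
  mutually consistent by construction.  Aborted fruits (scenario
  probability) are recorded below the 3 g threshold;
* destructive records budget the latent TDM into standing organs plus the
  harvested-fruit and trimmed-leaf ledgers; mass is conserved exactly
  before observation noise.

All randomness flows through per-table, per-plant substreams of the
scenario seed, so the tables are byte-identical under identical inputs and
adding plants does not perturb existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import canopy, phenology
from .biomass import DEFAULT_TERMS, validate_terms
from .scenarios import (
    ANTHESIS_WINDOW_CDD,
    DEFAULT_GEOMETRY,
    DESTRUCTIVE_DATS,
    FIRST_HARVEST_DAT,
    NODE_GRID,
    CultivarScenario,
    lai_design_values,
    leaf_measurement_dats,
)

# substream codes per table
_S_FLOWER, _S_ABORT, _S_FW, _S_LEAF, _S_ORGAN = 1, 2, 3, 4, 5

_TARGET_LEAF_AREA_CM2 = 450.0  # nominal single-leaf area for splitting stems
_LEAF_ASPECT = 1.5  # length / width


@dataclass
class TrialDataset:
    """The raw observation tables of one (synthetic or real) trial."""

    climate: pd.DataFrame
    node_obs: pd.DataFrame
    leaf_obs: pd.DataFrame
    destructive_obs: pd.DataFrame
    harvest_events: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def harvest_cohort_events(self) -> pd.DataFrame:
        """Events of the yield-assessment cohort only (destructively sampled
        plants drop out of the yield statistics)."""
        cohorts = self.meta.get("cohorts", {})
        keep = {p for p, c in cohorts.items() if c.get("cohort") == "harvest"}
        if not keep:
            return self.harvest_events
        return self.harvest_events[self.harvest_events["plant"].isin(keep)].reset_index(
            drop=True
        )


def _rng(seed: int, *codes: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, codes)]))


def _node_formation_at(scenario: CultivarScenario, at38: float, idx: np.ndarray):
    """AT0 (degC day from transplant) at which node ``idx`` forms."""
    n0 = scenario.nodes_at_transplant
    n38 = scenario.initial_nodes_at_38dat
    idx = np.asarray(idx, dtype=float)
    pre = np.clip((idx - n0) / max(n38 - n0, 1e-9), 0.0, None) * at38
    post = at38 + (idx - n38) / scenario.nfr_true
    return np.where(idx <= n38, pre, post)


def _latent_nodes(scenario: CultivarScenario, at0: np.ndarray, at38: float):
    n0 = scenario.nodes_at_transplant
    n38 = scenario.initial_nodes_at_38dat
    pre = n0 + (n38 - n0) * at0 / at38
    post = n38 + scenario.nfr_true * (at0 - at38)
    return np.where(at0 <= at38, pre, post)


def generate_trial(
    scenario: CultivarScenario,
    climate: pd.DataFrame,
    n_harvest: int = 9,
    n_growth: int = 6,
    n_leaf: int = 3,
    n_destructive: int = 3,
    geometry: tuple[float, float, int] = DEFAULT_GEOMETRY,
    destructive_dats: tuple[int, ...] = DESTRUCTIVE_DATS,
    terms=DEFAULT_TERMS,
    canopy_params: canopy.CanopyParams | None = None,
    first_harvest_dat: int = FIRST_HARVEST_DAT,
) -> TrialDataset:
    """Generate one cultivar's trial dataset.

    ``n_destructive`` plants are sampled at each destructive timepoint
    except the last, where the ``n_harvest`` yield plants are taken.
    """
    terms = validate_terms(terms)
    if len(scenario.partition_schedule) != len(terms):
        raise ValueError("partition_schedule length must match number of terms")
    dats = climate["dat"].to_numpy()
    trial_end = int(dats[-1])
    if max(destructive_dats) > trial_end or min(destructive_dats) < dats[0]:
        raise ValueError("destructive schedule extends beyond the climate range")
    row, spacing, stems_per_plant = geometry
    density = stems_per_plant / (row * spacing)  # stems m-2
    plants_per_m2 = density / stems_per_plant
    noise = scenario.noise_sd
    params = canopy_params or canopy.CanopyParams()

    # ---- latent drivers -------------------------------------------------
    thermal0 = phenology.accumulate_thermal_time(climate, start_dat=int(dats[0]))
    at0 = thermal0["at"].to_numpy()
    at38 = float(np.interp(38.0, dats, at0))
    lai_dats = leaf_measurement_dats(trial_end)
    lai_vals = lai_design_values(scenario.lai_plateau, scenario.lai_ramp_days, lai_dats)
    lai_daily = canopy.interpolate_lai_series(lai_dats, lai_vals, trial_end + 1)
    interception = canopy.daily_interception(climate, lai_daily, params)
    cum_il = interception["cum_il"].to_numpy()
    tdm_area = scenario.initial_dw_area + scenario.lue_true * cum_il

    # cumulative fruit DM (g m-2): schedule applied to TDM increments
    tdm_of = lambda d: float(np.interp(d, dats, tdm_area))
    fruit_area = np.zeros_like(tdm_area)
    for frac, (start, end) in zip(scenario.partition_schedule, terms):
        lo, hi = tdm_of(start), tdm_of(end)
        fruit_area += frac * (np.clip(tdm_area, lo, hi) - lo)
    veg_area = tdm_area - fruit_area
    ramp_end = int(round(scenario.lai_ramp_days))
    veg_ramp = float(np.interp(ramp_end, dats, veg_area))
    trim_area = scenario.trim_fraction * np.maximum(0.0, veg_area - veg_ramp)
    g_stem = fruit_area / density  # per-stem cumulative fruit DM (g)

    # ---- cohorts ---------------------------------------------------------
    cohorts: dict[str, dict] = {}
    tag = scenario.name
    plant_idx = 0

    def new_plant(cohort: str, end_dat: int) -> tuple[str, int]:
        nonlocal plant_idx
        plant_idx += 1
        pid = f"{tag}-{cohort[0].upper()}{plant_idx:02d}"
        cohorts[pid] = {"cohort": cohort, "end_dat": end_dat, "index": plant_idx}
        return pid, plant_idx

    harvest_plants = [new_plant("harvest", trial_end) for _ in range(n_harvest)]
    growth_plants = [new_plant("growth", trial_end) for _ in range(n_growth)]
    leaf_plants = [new_plant("leaf", trial_end) for _ in range(n_leaf)]
    destructive_plants: list[tuple[str, int, int]] = []
    for d in destructive_dats[:-1]:
        for _ in range(n_destructive):
            pid, idx = new_plant("destructive", int(d))
            destructive_plants.append((pid, idx, int(d)))
    # the final destructive sampling reuses the harvest cohort
    final_dat = int(destructive_dats[-1])

    # ---- fruit phenology shared quantities ------------------------------
    n_last = int(
        np.floor(
            scenario.initial_nodes_at_38dat
            + scenario.nfr_true * (at0[-1] - scenario.harvest_lag_cdd - at38)
        )
    )
    fruit_nodes = np.arange(scenario.first_fruit_node, n_last + 1)
    at_form = _node_formation_at(scenario, at38, fruit_nodes)
    harvest_dat_all = dats[np.searchsorted(at0, at_form + scenario.harvest_lag_cdd)]
    harvest_dat_all = np.maximum(harvest_dat_all, first_harvest_dat)

    def stem_events(pidx: int, stem: int, end_dat: int):
        """(kept_dats, kept_dm_latent, aborted_dats) for one stem."""
        rf = _rng(scenario.seed, _S_FLOWER, pidx, stem)
        ra = _rng(scenario.seed, _S_ABORT, pidx, stem)
        flowered = rf.random(len(fruit_nodes)) < scenario.female_flowering_rate_true
        aborted = ra.random(len(fruit_nodes)) < scenario.abortion_prob
        inside = harvest_dat_all <= end_dat
        kept_mask = flowered & ~aborted & inside
        ab_mask = flowered & aborted & inside
        kept_dats = harvest_dat_all[kept_mask]
        # assign the fruit-DM increment since the previous kept harvest;
        # same-day fruits share the day's increment equally
        kept_dm = np.zeros(len(kept_dats))
        pointer = 0.0
        i = 0
        while i < len(kept_dats):
            j = i
            while j < len(kept_dats) and kept_dats[j] == kept_dats[i]:
                j += 1
            g_now = float(np.interp(kept_dats[i], dats, g_stem))
            kept_dm[i:j] = (g_now - pointer) / (j - i)
            pointer = g_now
            i = j
        return kept_dats, kept_dm, harvest_dat_all[ab_mask]

    # ---- harvest events ---------------------------------------------------
    event_rows = []
    plant_kept: dict[str, dict] = {}  # plant -> latent/recorded harvested DM
    event_cohort = harvest_plants + [(p, i) for p, i, _ in destructive_plants]
    for pid, pidx in event_cohort:
        end_dat = cohorts[pid]["end_dat"]
        latent_dm = recorded_dm = 0.0
        for stem in range(stems_per_plant):
            kept_dats, kept_dm, ab_dats = stem_events(pidx, stem, end_dat)
            rw = _rng(scenario.seed, _S_FW, pidx, stem)
            fw = kept_dm / scenario.fruit_dmc
            if noise.get("fruit_fw_sd", 0.0) > 0:
                fw = fw + rw.normal(0.0, noise["fruit_fw_sd"], len(fw))
                fw = np.maximum(fw, 3.0)  # a kept (marketable) fruit is >= 3 g
            for d, w in zip(kept_dats, fw):
                event_rows.append((pid, stem, int(d), float(w), False))
            ab_fw = rw.uniform(0.5, 2.9, len(ab_dats))
            for d, w in zip(ab_dats, ab_fw):
                event_rows.append((pid, stem, int(d), float(w), False))
            latent_dm += float(kept_dm.sum())
            recorded_dm += float(fw.sum()) * scenario.fruit_dmc
        plant_kept[pid] = {"latent": latent_dm, "recorded": recorded_dm}
    harvest_events = pd.DataFrame(
        event_rows, columns=["plant", "stem", "dat", "fruit_fw_g", "premature"]
    ).sort_values(["dat", "plant", "stem"], kind="stable").reset_index(drop=True)

    # ---- node observations (growth cohort) -------------------------------
    node_rows = []
    obs_dats = np.arange(NODE_GRID[0], min(NODE_GRID[2], trial_end) + 1, NODE_GRID[1])
    latent_n = _latent_nodes(scenario, at0, at38)
    for pid, pidx in growth_plants:
        rf = _rng(scenario.seed, _S_FLOWER, pidx, 0)  # stem 0 is observed
        flowered = rf.random(len(fruit_nodes)) < scenario.female_flowering_rate_true
        for d in obs_dats:
            n_now = float(np.interp(d, dats, latent_n))
            count = int(round(n_now)) if scenario.quantize_nodes else n_now
            at_now = float(np.interp(d, dats, at0))
            age = at_now - at_form
            open_mask = (
                flowered
                & (age >= ANTHESIS_WINDOW_CDD[0])
                & (age <= ANTHESIS_WINDOW_CDD[1])
                & (fruit_nodes <= count)
            )
            flowers = ";".join(str(n) for n in fruit_nodes[open_mask])
            node_rows.append((pid, int(d), count, flowers))
    node_obs = pd.DataFrame(
        node_rows, columns=["plant", "dat", "node_count", "flower_nodes"]
    )

    # ---- leaf observations (per stem) ------------------------------------
    leaf_rows = []
    for pid, pidx in leaf_plants:
        for stem in range(stems_per_plant):
            rl = _rng(scenario.seed, _S_LEAF, pidx, stem)
            for d, lai_val in zip(lai_dats, lai_vals):
                stem_area = lai_val / density / canopy.CM2_TO_M2  # cm2 per stem
                if stem_area <= 0:
                    continue
                n_leaves = max(1, int(round(stem_area / _TARGET_LEAF_AREA_CM2)))
                per_leaf = stem_area / n_leaves
                wl = (per_leaf - canopy.LEAF_AREA_INTERCEPT) / canopy.LEAF_AREA_SLOPE
                w = np.sqrt(wl / _LEAF_ASPECT)
                ln = _LEAF_ASPECT * w
                cv = noise.get("leaf_dim_cv", 0.0)
                for leaf_id in range(n_leaves):
                    e1, e2 = (rl.normal(0.0, cv, 2) if cv > 0 else (0.0, 0.0))
                    leaf_rows.append(
                        (
                            f"{pid}-s{stem}",
                            int(d),
                            leaf_id + 1,
                            float(w * (1 + e1)),
                            float(ln * (1 + e2)),
                        )
                    )
    leaf_obs = pd.DataFrame(
        leaf_rows, columns=["plant", "dat", "leaf", "width_cm", "length_cm"]
    )

    # ---- destructive observations ----------------------------------------
    def destructive_record(pid: str, pidx: int, d: int):
        ro = _rng(scenario.seed, _S_ORGAN, pidx)
        cv = noise.get("organ_cv", 0.0)
        jitter = lambda x: float(x * (1.0 + (ro.normal(0.0, cv) if cv > 0 else 0.0)))
        tdm_plant = tdm_of(d) / plants_per_m2
        fruit_plant = float(np.interp(d, dats, fruit_area)) / plants_per_m2
        trim_plant = float(np.interp(d, dats, trim_area)) / plants_per_m2
        kept = plant_kept.get(pid, {"latent": 0.0, "recorded": 0.0})
        on_plant = max(0.0, fruit_plant - kept["latent"])
        veg = max(0.0, tdm_plant - trim_plant - max(fruit_plant, kept["latent"]))
        return {
            "plant": pid,
            "dat": int(d),
            "leaf_dw": jitter(0.6 * veg),
            "stem_dw": jitter(0.4 * veg),
            "fruit_dw": jitter(on_plant),
            "harvested_fruit_dm": kept["recorded"],
            "trimmed_leaf_dm": jitter(trim_plant),
        }

    destructive_rows = [
        destructive_record(pid, pidx, d) for pid, pidx, d in destructive_plants
    ]
    destructive_rows += [
        destructive_record(pid, pidx, final_dat) for pid, pidx in harvest_plants
    ]
    destructive_obs = pd.DataFrame(destructive_rows).sort_values(
        ["dat", "plant"], kind="stable"
    ).reset_index(drop=True)

    meta = {
        "scenario": scenario.name,
        "seed": int(scenario.seed),
        "geometry": {
            "row_spacing_m": row,
            "plant_spacing_m": spacing,
            "stems_per_plant": stems_per_plant,
        },
        "density_stems_m2": density,
        "plants_per_m2": plants_per_m2,
        "trial_end_dat": trial_end,
        "first_harvest_dat": first_harvest_dat,
        "destructive_dats": list(map(int, destructive_dats)),
        "terms": [list(t) for t in terms],
        "fruit_dmc": scenario.fruit_dmc,
        "initial_dw_area": scenario.initial_dw_area,
        "cohorts": cohorts,
        "scenario_params": {
            "nfr_true": scenario.nfr_true,
            "lue_true": scenario.lue_true,
            "lai_plateau": scenario.lai_plateau,
            "lai_ramp_days": scenario.lai_ramp_days,
            "partition_schedule": list(scenario.partition_schedule),
            "female_flowering_rate_true": scenario.female_flowering_rate_true,
            "abortion_prob": scenario.abortion_prob,
            "mean_fruit_fw": scenario.mean_fruit_fw,
        },
    }
    return TrialDataset(
        climate=climate.reset_index(drop=True),
        node_obs=node_obs,
        leaf_obs=leaf_obs,
        destructive_obs=destructive_obs,
        harvest_events=harvest_events,
        meta=meta,
    )
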
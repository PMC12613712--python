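"""Packaged cultivar scenarios and their calibration.

Four greenhouse cucumber cultivar scenarios ("josho", "s30", "gflush",
"yusho") parameterise the synthetic trial generator so that the full
analysis pipeline recovers the trial's published cultivar-level aggregates:
node formation rate (NFR), light-use efficiency (LUE), end-of-trial total
dry matter (TDM), cumulative fresh yield, fruit abortion ratio and the
cumulative fruit DM fraction.

Calibration is deterministic and runs against the noise-free climate
baseline:

* the climate's mean solar level is fixed so that cumulative intercepted
  PAR is consistent with TDM ~ LUE x cumIL for 'josho'
  (:func:`calibrate_mean_solar`);
* each cultivar's LAI ramp duration is solved so its cumulative
  interception equals (TDM_228 - initial DW) / LUE, with the plateau fixed
  at 2.4 m2 m-2 for all cultivars;
* the fruit partition schedule's late-term fraction is solved so that
  cumulative fruit DM at trial end equals fresh yield x fruit DM content;
* the per-node female flowering probability is solved from the target
  fruit number (fresh yield / mean fruit weight) and the number of
  fruit-bearing nodes.

Fruit DM content is itself derived from the 'josho' aggregates
(0.48 x TDM_228 / fresh yield ~ 0.019 g g-1) and shared by all cultivars.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

from . import canopy, climate as climate_mod, phenology
from .biomass import DEFAULT_TERMS

#: Initial aboveground dry weight at transplanting (g m-2).
INITIAL_DW_AREA = 5.0

#: Planting geometry: row spacing (m), plant spacing (m), stems per plant.
DEFAULT_GEOMETRY = (1.5, 0.3, 2)

#: Weekly non-destructive leaf measurement grid (start DAT, interval, end DAT).
LEAF_GRID = (32, 7, 228)
#: Node-count observation grid.
NODE_GRID = (38, 7, 227)
#: Destructive sampling schedule (DAT).
DESTRUCTIVE_DATS = (0, 45, 66, 105, 142, 228)

FIRST_HARVEST_DAT = 39
HARVEST_LAG_CDD = 200.0  # node formation -> fruit harvest, degC day
FIRST_FRUIT_NODE = 3  # lowest two nodes of each stem are deflowered
ANTHESIS_WINDOW_CDD = (60.0, 130.0)  # open-female-flower window after node formation

DEFAULT_NOISE = {
    "leaf_dim_cv": 0.05,  # CV of leaf width/length measurements
    "organ_cv": 0.10,  # CV of measured organ / trimmed-leaf dry weights
    "fruit_fw_sd": 15.0,  # SD (g) of fruit fresh-weight records
}

#: Cultivar-level calibration targets.  tdm228 None: emerges from LUE and
#: the shared canopy (value not independently constrained).
CALIBRATION: dict[str, dict] = {
    "josho": dict(
        nfr=0.022, lue=4.07, tdm228=1431.0, fresh_yield=36.3,
        abortion=0.074, term1_frac=0.15, mean_fruit_fw=100.0, n38=9,
    ),
    "s30": dict(
        nfr=0.015, lue=4.26, tdm228=1484.0, fresh_yield=31.5,
        abortion=0.005, term1_frac=0.20, mean_fruit_fw=115.0, n38=9,
    ),
    "gflush": dict(
        nfr=0.015, lue=4.08, tdm228=None, fresh_yield=30.0,
        abortion=0.008, term1_frac=0.20, mean_fruit_fw=110.0, n38=9,
    ),
    "yusho": dict(
        nfr=0.015, lue=3.86, tdm228=1329.0, fresh_yield=28.1,
        abortion=0.006, term1_frac=0.20, mean_fruit_fw=104.0, n38=9,
    ),
}

#: Fruit DM content (g dry / g fresh), derived from 'josho':
#: cumulative fruit fraction x TDM_228 / fresh yield.
FRUIT_DMC = 0.48 * CALIBRATION["josho"]["tdm228"] / (
    CALIBRATION["josho"]["fresh_yield"] * 1000.0
)


@dataclass(frozen=True)
class CultivarScenario:
    """Generative parameters for one cultivar's synthetic trial."""

    name: str
    nfr_true: float  # nodes per degC day (from 38 DAT)
    lue_true: float  # g DM per MJ intercepted PAR
    initial_nodes_at_38dat: float
    lai_plateau: float  # m2 m-2
    lai_ramp_days: float  # days from transplant to the LAI plateau
    partition_schedule: tuple[float, ...]  # fruit fraction of new DM per term
    female_flowering_rate_true: float  # per-node fruit-set probability
    abortion_prob: float  # P(set fruit stays < 3.0 g)
    fruit_dmc: float  # g dry / g fresh
    mean_fruit_fw: float  # g, expected kept-fruit fresh weight
    noise_sd: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE))
    seed: int = 42
    # secondary biology, shared defaults
    nodes_at_transplant: float = 4.0
    initial_dw_area: float = INITIAL_DW_AREA
    trim_fraction: float = 0.25  # share of post-plateau vegetative DM trimmed
    first_fruit_node: int = FIRST_FRUIT_NODE
    harvest_lag_cdd: float = HARVEST_LAG_CDD
    quantize_nodes: bool = True

    def __post_init__(self) -> None:
        if self.nfr_true <= 0 or self.lue_true <= 0:
            raise ValueError("nfr_true and lue_true must be positive")
        for name, val in (
            ("female_flowering_rate_true", self.female_flowering_rate_true),
            ("abortion_prob", self.abortion_prob),
            ("fruit_dmc", self.fruit_dmc),
        ):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {val}")
        if any(not 0.0 <= f <= 1.0 for f in self.partition_schedule):
            raise ValueError("partition fractions must lie in [0, 1]")

    def noiseless(self) -> "CultivarScenario":
        """Copy with all observation noise off (for exact-recovery checks)."""
        return replace(
            self,
            noise_sd={k: 0.0 for k in self.noise_sd},
            quantize_nodes=False,
        )


def leaf_measurement_dats(trial_end: int | None = None) -> np.ndarray:
    start, step, end = LEAF_GRID
    if trial_end is not None:
        end = min(end, trial_end)
    return np.arange(start, end + 1, step)


def lai_design_values(
    plateau: float, ramp_days: float, dats: np.ndarray
) -> np.ndarray:
    """Design LAI at the measurement grid: linear ramp to the plateau."""
    return plateau * np.minimum(1.0, np.asarray(dats, float) / ramp_days)


def latent_lai_series(
    plateau: float, ramp_days: float, trial_length: int
) -> "np.ndarray":
    """Latent daily LAI: the measurement-grid design values interpolated by
    the same rule the estimator uses (so noise-free recovery is exact)."""
    dats = leaf_measurement_dats(trial_length - 1)
    vals = lai_design_values(plateau, ramp_days, dats)
    return canopy.interpolate_lai_series(dats, vals, trial_length)


def baseline_climate(trial_length: int = climate_mod.DEFAULT_TRIAL_LENGTH,
                     mean_solar: float | None = None):
    """Noise-free climate baseline used for deterministic calibration."""
    kwargs = {} if mean_solar is None else {"mean_solar": mean_solar}
    return climate_mod.generate_climate(
        trial_length=trial_length, seed=0, t_noise_sd=0.0, solar_noise_sd=0.0,
        **kwargs,
    )


def _cum_il_at_end(clim, plateau, ramp_days, params=None) -> float:
    lai = latent_lai_series(plateau, ramp_days, len(clim))
    il = canopy.daily_interception(clim, lai, params)
    return float(il["cum_il"].iloc[-1])


def calibrate_mean_solar(
    plateau: float = 2.4, ramp_days: float = 60.0, probe: float = 10.0
) -> float:
    """Mean solar level making 'josho' cumulative IL consistent with its
    TDM / LUE targets.  Cumulative IL is linear in the solar level, so a
    single probe integration suffices."""
    tgt = CALIBRATION["josho"]
    target_il = (tgt["tdm228"] - INITIAL_DW_AREA) / tgt["lue"]
    clim = baseline_climate(mean_solar=probe)
    return probe * target_il / _cum_il_at_end(clim, plateau, ramp_days)


def _solve_ramp(clim, plateau: float, target_il: float) -> float:
    return float(
        brentq(
            lambda r: _cum_il_at_end(clim, plateau, r) - target_il,
            20.0,
            170.0,
            xtol=1e-6,
        )
    )


def packaged_scenarios(
    mean_solar: float | None = None,
    geometry: tuple[float, float, int] = DEFAULT_GEOMETRY,
) -> dict[str, CultivarScenario]:
    """The four calibrated cultivar scenarios.

    Runs the deterministic calibration described in the module docstring
    against the noise-free climate baseline and returns internally
    consistent scenarios (fresh yield = TDM x cumulative fruit fraction /
    fruit DM content by construction).
    """
    row, spacing, stems_per_plant = geometry
    density = stems_per_plant / (row * spacing)
    clim = baseline_climate(mean_solar=mean_solar)
    trial_end = int(clim["dat"].iloc[-1])
    thermal0 = phenology.accumulate_thermal_time(clim, start_dat=0)
    at0 = thermal0.set_index("dat")["at"]
    at38 = float(at0.loc[38])
    at_end = float(at0.loc[trial_end])
    plateau = 2.4

    out: dict[str, CultivarScenario] = {}
    for name, tgt in CALIBRATION.items():
        lue = tgt["lue"]
        if tgt["tdm228"] is not None:
            target_il = (tgt["tdm228"] - INITIAL_DW_AREA) / lue
            ramp = _solve_ramp(clim, plateau, target_il)
        else:
            # unconstrained TDM: share 'josho's canopy development
            ramp = out["josho"].lai_ramp_days
        lai = latent_lai_series(plateau, ramp, len(clim))
        il = canopy.daily_interception(clim, lai)
        cum_il = il.set_index("dat")["cum_il"]
        tdm = INITIAL_DW_AREA + lue * cum_il  # latent per-area TDM by day
        tdm228 = float(tdm.loc[trial_end])

        # --- partition schedule: solve the late-term fraction ---
        terms = DEFAULT_TERMS
        f1 = tgt["term1_frac"]
        fresh_g_m2 = tgt["fresh_yield"] * 1000.0
        # expected shortfall: fruit DM accruing after the last kept harvest
        nfr = tgt["nfr"]
        t_end = float(clim["t_mean"].iloc[-1])
        kept_rate = nfr * t_end * 0.9 * (1 - tgt["abortion"])  # fruits/stem/day
        dF_dt = 0.5 * lue * float(il["il"].iloc[-1])  # ~late-term fruit DM flux
        tail = 0.5 * dF_dt / max(kept_rate, 1e-9)
        f_target = fresh_g_m2 * FRUIT_DMC + tail
        d1 = float(tdm.loc[terms[0][1]]) - float(tdm.loc[terms[0][0]])
        late = (f_target - f1 * d1) / (tdm228 - float(tdm.loc[terms[0][1]]))
        if not 0.0 < late < 1.0:
            raise RuntimeError(f"{name}: infeasible partition calibration ({late:.3f})")
        schedule = (f1,) + (late,) * (len(terms) - 1)

        # --- female flowering probability from the fruit-number target ---
        n38 = tgt["n38"]
        n0 = 4.0
        # last node whose fruit is harvestable within the trial
        n_last = int(np.floor(n38 + nfr * (at_end - HARVEST_LAG_CDD - at38)))
        n_fruiting = n_last - FIRST_FRUIT_NODE + 1
        kept_per_stem = fresh_g_m2 / density / tgt["mean_fruit_fw"]
        ffr = kept_per_stem / ((1.0 - tgt["abortion"]) * n_fruiting)
        if not 0.0 < ffr <= 1.0:
            raise RuntimeError(
                f"{name}: flowering probability {ffr:.3f} outside (0, 1]"
            )

        out[name] = CultivarScenario(
            name=name,
            nfr_true=nfr,
            lue_true=lue,
            initial_nodes_at_38dat=float(n38),
            lai_plateau=plateau,
            lai_ramp_days=ramp,
            partition_schedule=schedule,
            female_flowering_rate_true=float(ffr),
            abortion_prob=tgt["abortion"],
            fruit_dmc=FRUIT_DMC,
            mean_fruit_fw=tgt["mean_fruit_fw"],
            nodes_at_transplant=n0,
        )
    return out
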
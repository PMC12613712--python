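"""End-to-end orchestration: simulate -> analyze -> compare.

`analyze_trial` turns one trial's raw tables into the full set of derived
quantities (thermal time, node curves and NFR, LAI and interception, TDM
records, interval DM production and fruit partitioning, LUE, yield
summary, yield-component row).  `run_pipeline` runs the four packaged
cultivar scenarios (or trials loaded from disk) under one climate, writes
per-figure CSV tables and a reproducibility manifest, and performs the
cross-cultivar comparisons (Tukey letters on yield, LUE slope contrasts,
the BH-adjusted yield-component correlation matrix).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, canopy, climate as climate_mod, io as io_mod
from . import biomass, phenology, stats as stats_mod, yield_components as yc
from .scenarios import DEFAULT_GEOMETRY, packaged_scenarios
from .simulate import TrialDataset, generate_trial

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    scenarios: tuple[str, ...] = ("josho", "s30", "gflush", "yusho")
    input_dir: str | None = None  # analyze pre-existing trial tables instead
    seed: int = 42
    out_dir: str | None = None
    canopy: canopy.CanopyParams = field(default_factory=canopy.CanopyParams)
    terms: tuple = biomass.DEFAULT_TERMS
    geometry: tuple = DEFAULT_GEOMETRY
    trial_length: int = climate_mod.DEFAULT_TRIAL_LENGTH
    n_harvest: int = 9
    n_growth: int = 6
    n_leaf: int = 3
    n_destructive: int = 3
    through_origin: bool = True
    base_temp: float = 0.0
    start_dat: int = phenology.NODE_OBS_START_DAT
    pooling: str = "per_plant"  # or "per_cultivar"
    fruit_dmc: float | None = None  # default: the scenario's own value
    make_plots: bool = False

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["canopy"] = asdict(self.canopy)
        d["terms"] = [list(t) for t in self.terms]
        return d


@dataclass
class TrialAnalysis:
    """All derived quantities for one cultivar's trial."""

    cultivar: str
    thermal: pd.DataFrame
    node_curve: pd.DataFrame
    nfr: phenology.NfrEstimate
    flower_distance: pd.DataFrame
    lai: pd.DataFrame
    interception: pd.DataFrame
    records: pd.DataFrame
    interval: pd.DataFrame
    partition: pd.DataFrame
    cum_fraction: pd.DataFrame
    lue: biomass.LueFit
    yields: yc.YieldSummary
    female_flowering_rate: float
    final_node_number: float
    dry_yield_kg_m2: float
    fruit_dmc: float
    components: pd.DataFrame  # per-plant rows for the correlation analysis


def analyze_trial(
    trial: TrialDataset,
    canopy_params: canopy.CanopyParams | None = None,
    terms=biomass.DEFAULT_TERMS,
    start_dat: int = phenology.NODE_OBS_START_DAT,
    base_temp: float = 0.0,
    through_origin: bool = True,
    fruit_dmc: float | None = None,
) -> TrialAnalysis:
    """Run every estimator of the pipeline on one trial."""
    meta = trial.meta
    cultivar = meta.get("scenario", "trial")
    density = meta["density_stems_m2"]
    stems_per_plant = meta["geometry"]["stems_per_plant"]
    trial_end = meta.get("trial_end_dat", int(trial.climate["dat"].iloc[-1]))
    params = canopy_params or canopy.CanopyParams()
    if fruit_dmc is None:
        fruit_dmc = meta.get("fruit_dmc")
    if fruit_dmc is None:
        raise ValueError("fruit_dmc not configured and absent from trial meta")

    thermal = phenology.accumulate_thermal_time(trial.climate, start_dat, base_temp)
    curve = phenology.node_increase(trial.node_obs, thermal, start_dat)
    nfr = phenology.estimate_nfr(curve, method="mean")
    flowers = phenology.flower_distance_to_tip(trial.node_obs)

    lai = canopy.build_lai(trial.leaf_obs, density, trial_end + 1)
    interception = canopy.daily_interception(trial.climate, lai, params)

    records = biomass.compute_tdm(trial.destructive_obs, density, stems_per_plant)
    interval = biomass.interval_dm_production(records, terms)
    partition = biomass.fruit_partition_fraction(records, terms)
    cum_fraction = biomass.cumulative_fruit_fraction(records)
    lue = biomass.estimate_lue(records, interception, through_origin=through_origin)

    events = trial.harvest_cohort_events()
    kept, aborted = yc.filter_aborted(events)
    n_filtered = len(events) - len(kept)
    log.info(
        "%s: abortion filter kept %d of %d events (%d aborted)",
        cultivar, len(kept), len(events), n_filtered,
    )
    yields = yc.yield_summary(
        kept,
        aborted,
        density,
        stems_per_plant,
        first_harvest_dat=meta.get("first_harvest_dat", 39),
        trial_end_dat=trial_end,
    )
    final_nodes = float(
        curve.sort_values("dat").groupby("plant")["node_count"].last().mean()
    )
    n_stems = max(yields.n_plants, 1) * stems_per_plant
    total_per_stem = (yields.n_kept + yields.n_aborted) / n_stems
    ffr = yc.female_flowering_rate(total_per_stem, final_nodes)
    dry = yc.dry_yield(yields.fresh_yield_kg_m2, fruit_dmc)

    final_frac = float(cum_fraction.loc[cum_fraction["dat"].idxmax(), "fraction"])
    tdm_end = float(records.loc[records["dat"] == records["dat"].max(), "tdm_area"].mean())
    cum_il_end = float(interception["cum_il"].iloc[-1])
    comp = yields.per_plant.copy()
    comp.insert(0, "cultivar", cultivar)
    comp["dry_yield_kg_m2"] = comp["fresh_yield_kg_m2"] * fruit_dmc
    comp["female_flowering_rate"] = ffr
    comp["final_node_number"] = final_nodes
    comp["nfr"] = nfr.estimate
    comp["tdm_g_m2"] = tdm_end
    comp["fruit_dm_fraction"] = final_frac
    comp["lue_g_mj"] = lue.slope
    comp["cum_il_mj_m2"] = cum_il_end
    comp["fruit_dmc"] = fruit_dmc

    return TrialAnalysis(
        cultivar=cultivar,
        thermal=thermal,
        node_curve=curve,
        nfr=nfr,
        flower_distance=flowers,
        lai=lai,
        interception=interception,
        records=records,
        interval=interval,
        partition=partition,
        cum_fraction=cum_fraction,
        lue=lue,
        yields=yields,
        female_flowering_rate=ffr,
        final_node_number=final_nodes,
        dry_yield_kg_m2=dry,
        fruit_dmc=fruit_dmc,
        components=comp,
    )


def _components_for_pooling(analyses: list[TrialAnalysis], pooling: str) -> pd.DataFrame:
    rows = pd.concat([a.components for a in analyses], ignore_index=True)
    if pooling == "per_cultivar":
        rows = rows.groupby("cultivar", as_index=False).mean(numeric_only=True)
    return rows


@dataclass
class PipelineResult:
    config: RunConfig
    analyses: dict[str, TrialAnalysis]
    tables: dict[str, pd.DataFrame]
    manifest: dict


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Simulate (or load), analyze and compare; optionally write outputs."""
    analyses: list[TrialAnalysis] = []
    if config.input_dir:
        trial = io_mod.read_trial(config.input_dir)
        trials = {trial.meta.get("scenario", "trial"): trial}
    else:
        scen = packaged_scenarios(geometry=config.geometry)
        clim = climate_mod.generate_climate(
            trial_length=config.trial_length, seed=config.seed
        )
        trials = {}
        for i, name in enumerate(config.scenarios):
            sub = int(
                np.random.SeedSequence([config.seed, i]).generate_state(1)[0]
                % 2**31
            )
            trials[name] = generate_trial(
                replace(scen[name], seed=sub),
                clim,
                n_harvest=config.n_harvest,
                n_growth=config.n_growth,
                n_leaf=config.n_leaf,
                n_destructive=config.n_destructive,
                geometry=config.geometry,
                terms=config.terms,
                canopy_params=config.canopy,
            )
    for name, trial in trials.items():
        log.info("analyzing trial %s", name)
        analyses.append(
            analyze_trial(
                trial,
                canopy_params=config.canopy,
                terms=config.terms,
                start_dat=config.start_dat,
                base_temp=config.base_temp,
                through_origin=config.through_origin,
                fruit_dmc=config.fruit_dmc,
            )
        )

    tables: dict[str, pd.DataFrame] = {}
    tables["nfr"] = pd.DataFrame(
        [
            {
                "cultivar": a.cultivar,
                "nfr": a.nfr.estimate,
                "ci_low": a.nfr.ci_low,
                "ci_high": a.nfr.ci_high,
                "n_plants": a.nfr.n_plants,
            }
            for a in analyses
        ]
    )
    tables["yield_series"] = pd.concat(
        [a.yields.series.assign(cultivar=a.cultivar) for a in analyses],
        ignore_index=True,
    )
    tables["yield_summary"] = pd.DataFrame(
        [
            {
                "cultivar": a.cultivar,
                "fresh_yield_kg_m2": a.yields.fresh_yield_kg_m2,
                "dry_yield_kg_m2": a.dry_yield_kg_m2,
                "fruit_number_m2": a.yields.fruit_number_m2,
                "mean_fruit_fw_g": a.yields.mean_fruit_fw_g,
                "abortion_ratio": a.yields.abortion_ratio,
                "female_flowering_rate": a.female_flowering_rate,
                "final_node_number": a.final_node_number,
            }
            for a in analyses
        ]
    )
    tables["partition"] = pd.concat(
        [a.partition.assign(cultivar=a.cultivar) for a in analyses],
        ignore_index=True,
    )
    tables["cum_fruit_fraction"] = pd.concat(
        [a.cum_fraction.assign(cultivar=a.cultivar) for a in analyses],
        ignore_index=True,
    )
    tables["lue"] = pd.DataFrame(
        [
            {
                "cultivar": a.cultivar,
                "lue": a.lue.slope,
                "se": a.lue.se,
                "ci_low": a.lue.ci_low,
                "ci_high": a.lue.ci_high,
                "tdm_end_g_m2": float(
                    a.records.loc[a.records["dat"] == a.records["dat"].max(), "tdm_area"].mean()
                ),
                "cum_il_mj_m2": float(a.interception["cum_il"].iloc[-1]),
            }
            for a in analyses
        ]
    )
    components = _components_for_pooling(analyses, config.pooling)
    tables["components"] = components

    # cross-cultivar comparisons need >= 2 cultivars
    if len(analyses) >= 2:
        per_plant_yield = pd.concat(
            [
                a.components[["cultivar", "fresh_yield_kg_m2"]]
                for a in analyses
            ],
            ignore_index=True,
        )
        tukey = stats_mod.tukey_letters(
            per_plant_yield["fresh_yield_kg_m2"], per_plant_yield["cultivar"]
        )
        tables["tukey_yield"] = tukey.pairwise.assign(
            letters=[tukey.letters[g] for g in tukey.pairwise["group1"]]
        )
        xs, ys_, gs = [], [], []
        for a in analyses:
            cum = a.interception.set_index("dat")["cum_il"]
            init = float(
                a.records.loc[a.records["dat"] == a.records["dat"].min(), "tdm_area"].mean()
            )
            xs.append(cum.loc[a.records["dat"]].to_numpy())
            ys_.append(a.records["tdm_area"].to_numpy() - init)
            gs.append(np.repeat(a.cultivar, len(a.records)))
        tables["lue_contrasts"] = stats_mod.compare_slopes(
            np.concatenate(xs), np.concatenate(ys_), np.concatenate(gs)
        )
        corr_cols = [
            "fresh_yield_kg_m2", "dry_yield_kg_m2", "fruit_number_m2",
            "mean_fruit_fw_g", "abortion_ratio", "female_flowering_rate",
            "final_node_number", "nfr", "tdm_g_m2", "fruit_dm_fraction",
            "lue_g_mj", "fruit_dmc",
        ]
        use = [c for c in corr_cols if c in components.columns]
        corr = stats_mod.component_correlations(components[use])
        tables["correlation_r"] = corr["r"]
        tables["correlation_p_adj"] = corr["p_adj"]
        tables["correlation_marks"] = corr["marks"]

    cfg_json = json.dumps(config.to_jsonable(), sort_keys=True)
    manifest = {
        "package": "cucurgrow",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_jsonable(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "tables": {
            name: {"rows": int(len(t)), "columns": list(map(str, t.columns))}
            for name, t in tables.items()
        },
    }
    result = PipelineResult(
        config=config,
        analyses={a.cultivar: a for a in analyses},
        tables=tables,
        manifest=manifest,
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, t in tables.items():
            t.to_csv(out / f"{name}.csv", index=True if name.startswith("correlation") else False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        if config.make_plots:
            _write_plots(result, out)
    return result


def _write_plots(result: PipelineResult, out: Path) -> None:
    """Optional summary figures (yield curves, LUE regression)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, a in result.analyses.items():
        ax.plot(a.yields.series["dat"], a.yields.series["cum_fresh_kg_m2"], label=name)
    ax.set_xlabel("days after transplanting")
    ax.set_ylabel("cumulative fresh yield (kg m$^{-2}$)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "yield_series.png", dpi=150)
    plt.close(fig)
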
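"""End-to-end pipeline: simulate -> evaluate -> indices -> warm winter ->
trends -> uncertainty -> exposure, driven by one YAML configuration.

Every stochastic stage draws from substreams of the single configured
seed, so identical (config, seed) pairs give byte-identical outputs.
Intermediate ensemble members are regenerated deterministically on demand
rather than parked on disk; daily CSVs are written only when requested
(``write_daily``), since a full ensemble is hundreds of megabytes of
text.

Outputs (all under ``out_dir``): stations.csv, population.csv,
evaluation.csv, winter_means.csv, indices.csv, warmwinter.csv,
trends.csv, uncertainty.csv, exposure.csv, derived_stats.csv,
summary.json and manifest.txt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import (
    etccdi_indices,
    exposure,
    model_evaluation,
    station_io,
    synthetic_ensemble,
    trend_stats,
    uncertainty_partition,
    warm_winter,
    winter_core,
)
from .station_io import ValidationError

logger = logging.getLogger("winterx")

#: Climate scenario -> matching population pathway.
SCENARIO_POPULATION = {"SSP245": "SSP2", "SSP585": "SSP5"}


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; defaults are the desk-scale fixture."""

    seed: int = 0
    out_dir: str = "winterx_out"
    years: tuple[int, int] = (1961, 2100)
    n_stations: int = 21
    n_models: int = 6
    scenarios: dict = field(
        default_factory=lambda: dict(synthetic_ensemble.DEFAULT_SCENARIOS))
    population_scenarios: dict = field(
        default_factory=lambda: dict(synthetic_ensemble.DEFAULT_POPULATION_SCENARIOS))
    population_decades: tuple[int, ...] = tuple(range(2010, 2101, 10))
    write_daily: bool = False

    baseline_mode: str = "dynamic"          # 'dynamic' | 'static'
    static_window: tuple[int, int] = (1961, 1990)
    percentile_window: int = 5
    base_span: int = 30
    threshold_mode: str = "dynamic"         # 'dynamic' | 'fixed'
    fixed_threshold_base: tuple[int, int] = (1961, 1990)
    alpha: float = 0.05
    poly_degree: int = 4
    reference_period: tuple[int, int] = (1995, 2014)
    evaluation_period: tuple[int, int] = (1961, 2010)
    trend_period: tuple[int, int] = (2015, 2100)
    exposure_decades: tuple[int, ...] = tuple(range(2021, 2092, 10))

    def __post_init__(self):
        if self.baseline_mode not in ("dynamic", "static"):
            raise ValidationError(f"unknown baseline mode {self.baseline_mode!r}")
        if self.threshold_mode not in ("dynamic", "fixed"):
            raise ValidationError(f"unknown threshold mode {self.threshold_mode!r}")
        specs = {}
        for name, spec in self.scenarios.items():
            if isinstance(spec, synthetic_ensemble.ClimateScenarioSpec):
                specs[name] = spec
            else:
                specs[name] = synthetic_ensemble.ClimateScenarioSpec(name=name, **spec)
        self.scenarios = specs
        pops = {}
        for name, spec in self.population_scenarios.items():
            if isinstance(spec, synthetic_ensemble.PopulationScenarioSpec):
                pops[name] = spec
            else:
                pops[name] = synthetic_ensemble.PopulationScenarioSpec(name=name, **spec)
        self.population_scenarios = pops

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        kwargs = dict(raw)
        for key in ("years", "static_window", "fixed_threshold_base", "reference_period",
                    "evaluation_period", "trend_period"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        for key in ("population_decades", "exposure_decades"):
            if key in kwargs:
                kwargs[key] = tuple(int(v) for v in kwargs[key])
        return cls(**kwargs)


class PipelineRun:
    """Lazy, cached execution of the pipeline stages for one config."""

    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.out_dir = Path(config.out_dir)

    # -- simulation -------------------------------------------------------

    @cached_property
    def network(self) -> pd.DataFrame:
        logger.info("generating station network (n=%d)", self.cfg.n_stations)
        return synthetic_ensemble.generate_network(self.cfg.n_stations, seed=self.cfg.seed)

    @cached_property
    def members(self) -> dict[str, list[station_io.EnsembleMember]]:
        out = {}
        for name in sorted(self.cfg.scenarios):
            logger.info("simulating %d members for scenario %s", self.cfg.n_models, name)
            out[name] = [
                synthetic_ensemble.simulate_member(
                    self.network, m, self.cfg.scenarios[name], self.cfg.years,
                    seed=self.cfg.seed)
                for m in range(self.cfg.n_models)]
        return out

    @cached_property
    def observations(self) -> station_io.EnsembleMember:
        first = self.cfg.scenarios[sorted(self.cfg.scenarios)[0]]
        return synthetic_ensemble.simulate_observations(
            self.network, first, self.cfg.years, seed=self.cfg.seed)

    @cached_property
    def population(self) -> pd.DataFrame:
        frames = [synthetic_ensemble.simulate_population(
            spec, self.cfg.population_decades, seed=self.cfg.seed)
            for _, spec in sorted(self.cfg.population_scenarios.items())]
        return pd.concat(frames, ignore_index=True)

    # -- derived data -----------------------------------------------------

    @cached_property
    def median_series(self) -> dict[str, dict[str, station_io.StationDailySeries]]:
        """MME-median daily series per scenario per station."""
        return {name: winter_core.ensemble_median_daily(members)
                for name, members in self.members.items()}

    @cached_property
    def winter_means(self) -> pd.DataFrame:
        frames = []
        for name in sorted(self.median_series):
            t = winter_core.winter_mean_table(self.median_series[name])
            t.insert(0, "scenario", name)
            frames.append(t)
        return pd.concat(frames, ignore_index=True)

    @cached_property
    def warm_records(self) -> dict[str, list[warm_winter.WarmWinterRecord]]:
        out = {}
        for name in sorted(self.median_series):
            wm = self.winter_means[self.winter_means["scenario"] == name]
            out[name] = warm_winter.classify_network(
                wm, self.network, mode=self.cfg.baseline_mode,
                static_window=self.cfg.static_window)
        return out

    # -- stages -----------------------------------------------------------

    def stage_simulate(self) -> dict[str, pd.DataFrame]:
        self.out_dir.mkdir(parents=True, exist_ok=True)
        station_io.write_stations(self.network, self.out_dir / "stations.csv")
        station_io.write_population(self.population, self.out_dir / "population.csv")
        self._input_files = ["stations.csv", "population.csv"]
        if self.cfg.write_daily:
            for members in self.members.values():
                for m in members:
                    self._input_files.append(station_io.write_member(m, self.out_dir).name)
            self._input_files.append(station_io.write_member(self.observations,
                                                             self.out_dir).name)
        return {}

    def stage_evaluate(self) -> dict[str, pd.DataFrame]:
        reports = []
        scen = sorted(self.members)[0]  # scenarios agree over the historical overlap
        for member in self.members[scen]:
            reports += model_evaluation.evaluate_member(
                self.observations, member, period=self.cfg.evaluation_period)
        return {"evaluation": model_evaluation.reports_to_frame(reports)}

    def _classifiable_winters(self) -> list[int]:
        """Winters whose trailing 30-year threshold base fits in the span."""
        return [wy for wy in range(self.cfg.years[0] + 1, self.cfg.years[1] + 1)
                if etccdi_indices.decade_start(wy) - self.cfg.base_span >= self.cfg.years[0]]

    def stage_indices(self) -> dict[str, pd.DataFrame]:
        winters = self._classifiable_winters()
        frames = []
        for name in sorted(self.median_series):
            logger.info("computing indices for scenario %s (%d winters)", name, len(winters))
            t = etccdi_indices.index_table(
                self.median_series[name], winters,
                day_window=self.cfg.percentile_window, base_span=self.cfg.base_span,
                mode=self.cfg.threshold_mode, fixed_base=self.cfg.fixed_threshold_base)
            t.insert(0, "scenario", name)
            frames.append(t)
        return {"indices": pd.concat(frames, ignore_index=True),
                "winter_means": self.winter_means}

    def stage_warmwinter(self) -> dict[str, pd.DataFrame]:
        frames = []
        for name in sorted(self.warm_records):
            t = warm_winter.records_to_frame(self.warm_records[name])
            t.insert(0, "scenario", name)
            frames.append(t)
        return {"warmwinter": pd.concat(frames, ignore_index=True)}

    def stage_trends(self) -> dict[str, pd.DataFrame]:
        rows = []
        t0, t1 = self.cfg.trend_period
        for name in sorted(self.median_series):
            wm = self.winter_means[self.winter_means["scenario"] == name]
            wm = wm[(wm["winter_year"] >= t0) & (wm["winter_year"] <= t1)]
            station_slopes: dict[str, dict[str, float]] = {}
            for sid, grp in wm.groupby("station_id"):
                grp = grp.sort_values("winter_year")
                for var in ("tx_bar", "tn_bar", "tm_bar"):
                    res = trend_stats.mk_test(grp[var].to_numpy(),
                                              t=grp["winter_year"].to_numpy(dtype=float))
                    rows.append({"scenario": name, "unit_id": sid, "variable": var,
                                 "slope_per_decade": res.slope_per_decade,
                                 "Z": res.z, "p": res.p_two_sided, "n": res.n})
                    station_slopes.setdefault(var, {})[sid] = res.slope_per_decade
            # regional and national mean series
            merged = wm.merge(self.network[["region"]], left_on="station_id",
                              right_index=True)
            for region, grp in merged.groupby("region"):
                series = grp.groupby("winter_year")[["tx_bar", "tn_bar", "tm_bar"]].mean()
                for var in ("tx_bar", "tn_bar", "tm_bar"):
                    res = trend_stats.mk_test(series[var].to_numpy(),
                                              t=series.index.to_numpy(dtype=float))
                    rows.append({"scenario": name, "unit_id": region, "variable": var,
                                 "slope_per_decade": res.slope_per_decade,
                                 "Z": res.z, "p": res.p_two_sided, "n": res.n})
            national = wm.groupby("winter_year")[["tx_bar", "tn_bar", "tm_bar"]].mean()
            for var in ("tx_bar", "tn_bar", "tm_bar"):
                res = trend_stats.mk_test(national[var].to_numpy(),
                                          t=national.index.to_numpy(dtype=float))
                rows.append({"scenario": name, "unit_id": "ECM", "variable": var,
                             "slope_per_decade": res.slope_per_decade,
                             "Z": res.z, "p": res.p_two_sided, "n": res.n})
            # elevation vs per-station warming rate, nationally
            for var in ("tx_bar", "tn_bar"):
                ids = sorted(station_slopes[var])
                r, p = trend_stats.elevation_correlation(
                    [station_slopes[var][sid] for sid in ids],
                    [float(self.network.loc[sid, "elevation_m"]) for sid in ids])
                rows.append({"scenario": name, "unit_id": "ECM",
                             "variable": f"elev_corr_{var}", "slope_per_decade": np.nan,
                             "Z": np.nan, "p": p, "n": len(ids), "r": r})
            # spatial coefficient of variation trend
            full = self.winter_means[self.winter_means["scenario"] == name]
            for var in ("tx_bar", "tn_bar", "tm_bar"):
                cv = winter_core.spatial_cv_series(full, var)
                res = trend_stats.mk_test(cv.to_numpy(), t=cv.index.to_numpy(dtype=float))
                rows.append({"scenario": name, "unit_id": "ECM",
                             "variable": f"cv_{var}", "slope_per_decade": res.slope_per_decade,
                             "Z": res.z, "p": res.p_two_sided, "n": res.n})
        return {"trends": pd.DataFrame(rows)}

    def stage_uncertainty(self) -> dict[str, pd.DataFrame]:
        decomps = []
        years = None
        for name in sorted(self.members):
            for member in self.members[name]:
                wm = winter_core.winter_mean_table(member)
                nat = wm.groupby("winter_year")["tm_bar"].mean()
                if years is None:
                    years = nat.index.to_numpy()
                decomps.append(uncertainty_partition.fit_member(
                    nat.index.to_numpy(), nat.to_numpy(),
                    reference_period=self.cfg.reference_period,
                    degree=self.cfg.poly_degree,
                    model=member.model_name, scenario=name))
        curves = uncertainty_partition.partition(decomps)
        return {"uncertainty": curves.to_frame()}

    def stage_exposure(self) -> dict[str, pd.DataFrame]:
        frames = []
        for name in sorted(self.warm_records):
            pop_scen = SCENARIO_POPULATION.get(name)
            if pop_scen is None:
                logger.warning("no population pathway for scenario %s; skipped", name)
                continue
            frames.append(exposure.exposure_table(
                self.warm_records[name], self.population, pop_scen,
                self.cfg.exposure_decades, climate_scenario=name))
        exp = pd.concat(frames, ignore_index=True)
        return {"exposure": exp, "derived_stats": self._derived_stats(exp)}

    def _derived_stats(self, exp: pd.DataFrame) -> pd.DataFrame:
        """Trend ratios, shares, declines and avoided risk from the run."""
        rows = []
        # population decadal trends per region under both pathways, and ratios
        trends = {}
        for scen, grp in self.population.groupby("scenario"):
            for region, g in grp.groupby("region"):
                g = g.sort_values("year")
                slope = np.polyfit(g["year"] / 10.0, g["population"], 1)[0]
                trends[(scen, region)] = slope
        pops = sorted({s for s, _ in trends})
        if len(pops) == 2:
            lo, hi = pops
            regions = sorted({r for _, r in trends})
            for region in regions:
                a, b = trends[(lo, region)], trends[(hi, region)]
                if a != 0.0:
                    rows.append({"name": "pop_trend_ratio", "unit_id": region,
                                 "value_pct": exposure.trend_ratio(a, b)})
            nat = {s: sum(trends[(s, r)] for r in regions) for s in pops}
            rows.append({"name": "pop_trend_ratio", "unit_id": "ECM",
                         "value_pct": exposure.trend_ratio(nat[lo], nat[hi])})
        d0, d1 = min(self.cfg.exposure_decades), max(self.cfg.exposure_decades)
        for scen, grp in exp.groupby("scenario"):
            table = grp.set_index(["region", "decade"])["person_times"]
            nat0, nat1 = table.get(("ECM", d0), np.nan), table.get(("ECM", d1), np.nan)
            if nat0 and np.isfinite(nat0) and nat0 > 0:
                remaining, decline = exposure.relative_change(nat0, nat1)
                rows.append({"name": "exposure_remaining", "unit_id": f"ECM/{scen}",
                             "value_pct": remaining})
                rows.append({"name": "exposure_decline", "unit_id": f"ECM/{scen}",
                             "value_pct": decline})
                for region in sorted(set(r for r, _ in table.index) - {"ECM"}):
                    rows.append({"name": f"share_{d0}", "unit_id": f"{region}/{scen}",
                                 "value_pct": exposure.share_of_total(
                                     table[(region, d0)], nat0)})
        # avoided risk between the two climate scenarios in the last decade
        scens = sorted(exp["scenario"].unique())
        if len(scens) == 2:
            e_lo = exp[(exp["scenario"] == scens[0]) & (exp["region"] == "ECM")
                       & (exp["decade"] == d1)]["person_times"]
            e_hi = exp[(exp["scenario"] == scens[1]) & (exp["region"] == "ECM")
                       & (exp["decade"] == d1)]["person_times"]
            if len(e_lo) and len(e_hi) and float(e_hi.iloc[0]) > 0:
                rows.append({"name": "avoided_risk", "unit_id": f"ECM/{d1}",
                             "value_pct": exposure.avoided_risk(
                                 float(e_lo.iloc[0]), float(e_hi.iloc[0]))})
        return pd.DataFrame(rows)

    # -- driver -----------------------------------------------------------

    STAGES = ("simulate", "evaluate", "indices", "warmwinter", "trends",
              "uncertainty", "exposure")

    def run(self, stages: Sequence[str] | None = None) -> list[str]:
        """Run the requested stages (default all) and write every output."""
        stages = list(stages) if stages is not None else list(self.STAGES)
        for s in stages:
            if s not in self.STAGES:
                raise ValidationError(f"unknown stage {s!r}")
        tables: dict[str, pd.DataFrame] = {}
        summary: dict = {"seed": self.cfg.seed, "stages": stages}
        for s in stages:
            logger.info("stage %s", s)
            try:
                tables.update(getattr(self, f"stage_{s}")())
            except Exception as exc:
                raise ValidationError(f"stage {s!r} failed: {exc}") from exc
        if "trends" in stages:
            t = tables["trends"]
            nat = t[(t["unit_id"] == "ECM") & (t["variable"] == "tx_bar")]
            summary["national_tx_slope_per_decade"] = dict(
                zip(nat["scenario"], nat["slope_per_decade"].round(4)))
        if "derived_stats" in tables:
            d = tables["derived_stats"]
            ar = d[d["name"] == "avoided_risk"]
            if len(ar):
                summary["avoided_risk_pct"] = float(ar["value_pct"].iloc[0])
        manifest = station_io.write_outputs(
            tables, self.out_dir, summary=summary,
            extra_files=getattr(self, "_input_files", ()))
        logger.info("wrote %d files to %s", len(manifest), self.out_dir)
        return manifest


def run_pipeline(config: PipelineConfig, stages: Sequence[str] | None = None) -> list[str]:
    """Convenience wrapper: run the (sub)pipeline and return the manifest."""
    return PipelineRun(config).run(stages)
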
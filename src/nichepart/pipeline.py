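"""End-to-end orchestration: ingest -> fit -> grid -> overlap -> diet -> stats.

:func:`run_full` executes the whole analysis from one :class:`RunConfig`,
writing every intermediate table and a summary report into the output
directory.  Inputs are either the three CSV tables or a named synthetic
scenario; a single seed governs all stochastic stages, so a run is a pure
function of (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diet as diet_mod
from . import gam, grid as grid_mod, io, simulate, stats

logger = logging.getLogger("nichepart")

__all__ = ["RunConfig", "run_full", "load_config"]


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    output_dir: str = "nichepart_run"
    scenario: str | None = None           # 'default' | 'partitioning' | None
    haul_table: str | None = None
    specimen_table: str | None = None
    diet_table: str | None = None
    species_pair: tuple[str, str] = ("PH", "ATF")
    size_range: tuple[float, float] = io.DEFAULT_SIZE_RANGE
    cell_size: float = 100_000.0
    standardization: str = "max"
    habitat_threshold: float = 0.25
    min_stomachs: int = 3
    dredge: bool = False
    selection_policy: str = "min_aic"
    area_scheme: str = "inpfc"
    alpha: float = 0.1
    seed: int = 0
    hauls_per_year: int = 720
    years: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.habitat_threshold <= 0 or self.min_stomachs <= 0:
            raise ValueError("thresholds must be positive")
        if self.scenario is None:
            for name in ("haul_table", "specimen_table", "diet_table"):
                path = getattr(self, name)
                if path is None:
                    raise ValueError(
                        f"{name} is required when no scenario is set"
                    )
                if not Path(path).exists():
                    raise FileNotFoundError(f"{name}: no such file {path!r}")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}")
    for key in ("species_pair", "size_range", "years"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def _stage(name):
    logger.info("stage: %s", name)
    return name


def run_full(config: RunConfig) -> dict:
    """Run every stage in order; returns the artifact bundle as a dict.

    On a stage failure, partial outputs already written are retained and a
    RuntimeError naming the stage is raised.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {"config": config}
    stage = "setup"
    try:
        # ------------------------------------------------------------------
        stage = _stage("ingest")
        if config.scenario is not None:
            factory = {
                "default": simulate.default_diet_scenario,
                "partitioning": simulate.partitioning_diet_scenario,
            }
            if config.scenario not in factory:
                raise ValueError(f"unknown scenario {config.scenario!r}")
            years = config.years or simulate._GOA_YEARS
            survey = simulate.default_scenario(
                seed=config.seed, years=years,
                hauls_per_year=config.hauls_per_year,
            )
            hauls, truth = simulate.simulate_hauls(survey)
            specimens = simulate.simulate_lengths(hauls, survey)
            diet_sc = factory[config.scenario](seed=config.seed)
            stomachs = simulate.simulate_stomachs(hauls, specimens, diet_sc)
            io.write_haul_table(hauls, out / "hauls.csv")
            io.write_specimen_table(specimens, out / "specimens.csv")
            io.write_diet_table(stomachs, out / "stomachs.csv")
            artifacts["truth"] = truth
        else:
            hauls = io.read_haul_table(config.haul_table)
            specimens = io.read_specimen_table(config.specimen_table)
            stomachs = io.read_diet_table(config.diet_table)

        retained, report = io.filter_complete_covariates(hauls)
        artifacts["filter_report"] = report
        for sp in config.species_pair:
            retained[f"adjusted_cpue_{sp}"] = io.adjusted_cpue(
                retained, specimens, sp, size_range=config.size_range
            )
        artifacts["hauls"] = retained

        # ------------------------------------------------------------------
        stage = _stage("fit")
        fits: dict[tuple[str, str], gam._BaseGAM] = {}
        tables = {}
        for sp in config.species_pair:
            acol = f"adjusted_cpue_{sp}"
            presence = (retained[acol] > 0).astype(int)
            positives = retained[retained[acol] > 0]
            for response, est, X, y in (
                ("presence", gam.PresenceGAM(), retained, presence),
                ("cpue", gam.PositiveCpueGAM(), positives, positives[acol]),
            ):
                if config.dredge:
                    table = gam.dredge_aic(est, X, y)
                    tables[(sp, response)] = table
                    table.drop(columns="terms").to_csv(
                        out / f"model_table_{sp}_{response}.csv", index=False
                    )
                    terms = gam.select_best(table, config.selection_policy)
                    fit = table.attrs["fits"][terms]
                else:
                    fit = est.fit(X, y)
                fits[(sp, response)] = fit
        artifacts["fits"] = fits
        artifacts["model_tables"] = tables

        # ------------------------------------------------------------------
        stage = _stage("grid")
        extent = (
            float(retained["lon"].min()), float(retained["lon"].max()),
            float(retained["lat"].min()), float(retained["lat"].max()),
        )
        g = grid_mod.build_grid(extent, cell_size=config.cell_size)
        env = grid_mod.cell_year_env(retained, g)
        cells = g.cells().set_index("cell_id")
        env["lon"] = cells.loc[env["cell_id"], "center_lon"].to_numpy()
        env["lat"] = cells.loc[env["cell_id"], "center_lat"].to_numpy()
        artifacts["grid"] = g
        artifacts["cell_year_env"] = env

        # ------------------------------------------------------------------
        stage = _stage("overlap")
        preds = []
        for sp in config.species_pair:
            po = fits[(sp, "presence")].predict(env)
            pa = fits[(sp, "cpue")].predict(env)
            preds.append(
                pd.DataFrame(
                    dict(species=sp, year=env["year"], cell_id=env["cell_id"],
                         po=po, pa=pa)
                )
            )
        pred = pd.concat(preds, ignore_index=True)
        abund = grid_mod.combine_and_standardize(
            pred, method=config.standardization
        )
        kept, excluded = grid_mod.exclude_low_habitat(
            abund, config.species_pair, threshold=config.habitat_threshold
        )
        overlap = grid_mod.spatial_overlap(abund, config.species_pair,
                                           cells=kept)
        wide = abund.pivot_table(
            index=["year", "cell_id"], columns="species",
            values="std_abundance",
        ).reset_index()
        field_out = overlap.merge(wide, on=["year", "cell_id"])
        field_out["center_lon"] = cells.loc[field_out["cell_id"],
                                            "center_lon"].to_numpy()
        field_out["center_lat"] = cells.loc[field_out["cell_id"],
                                            "center_lat"].to_numpy()
        field_out.to_csv(out / "spatial_overlap.csv", index=False)
        artifacts["abundance_field"] = abund
        artifacts["excluded_cells"] = excluded
        artifacts["spatial_overlap"] = overlap
        artifacts["spatial_cell_means"] = grid_mod.cell_means(overlap)

        # ------------------------------------------------------------------
        stage = _stage("diet")
        pooled, qualifying = diet_mod.group_stomachs(
            stomachs, hauls, g, size_range=config.size_range,
            min_per_predator=config.min_stomachs,
            species_pair=config.species_pair,
        )
        dfield = diet_mod.dietary_overlap_field(pooled, config.species_pair)
        pooled.to_csv(out / "diet_groups.csv", index=False)
        dfield.to_csv(out / "dietary_overlap.csv", index=False)
        artifacts["diet_groups"] = pooled
        artifacts["dietary_overlap"] = dfield

        # ------------------------------------------------------------------
        stage = _stage("stats")
        pairs = stats.pair_overlap(overlap, dfield)
        artifacts["overlap_pairs"] = pairs
        summary: dict = {
            "seed": config.seed,
            "n_hauls_input": report.n_input,
            "n_hauls_retained": report.n_retained,
            "n_spatial_year_cells": int(len(overlap)),
            "n_excluded_cells": len(excluded),
            "n_dietary_year_cells": int(len(dfield)),
            "n_paired_year_cells": int(len(pairs)),
            "spatial_overlap_mean": float(overlap["s"].mean()),
            "spatial_overlap_sd": float(overlap["s"].std(ddof=1)),
        }
        if len(dfield):
            summary["dietary_overlap_mean"] = float(dfield["d"].mean())
            summary["dietary_overlap_sd"] = float(dfield["d"].std(ddof=1))
        corr = stats.pearson_partitioning(pairs) if len(pairs) else None
        if corr is not None and corr.defined:
            summary.update(pearson_r=corr.r, pearson_t=corr.t,
                           pearson_df=corr.df, pearson_p=corr.p)
        artifacts["partitioning"] = corr
        s_area = io.assign_area(
            field_out["center_lon"], field_out["center_lat"],
            scheme=config.area_scheme,
        )
        try:
            anc = stats.ancova(
                field_out.assign(area=s_area), value="s",
                alpha=config.alpha,
            )
            artifacts["ancova_spatial"] = anc
            if (not anc.interaction_significant
                    and "C(area)" in anc.significant_terms):
                artifacts["tukey_spatial"] = stats.tukey_hsd(
                    field_out["s"], s_area, alpha=config.alpha
                )
        except ValueError as exc:
            logger.warning("spatial ANCOVA not estimable: %s", exc)
            summary["ancova_spatial_note"] = str(exc)
        artifacts["annual_spatial"] = stats.annual_summary(overlap, "s")
        if len(dfield):
            artifacts["annual_dietary"] = stats.annual_summary(dfield, "d")
        artifacts["summary"] = summary
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        _write_report(out / "report.txt", config, summary)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    return artifacts


def _write_report(path, config: RunConfig, summary: dict):
    lines = ["nichepart run summary", "=" * 21, ""]
    lines.append("config:")
    for f in dataclasses.fields(RunConfig):
        lines.append(f"  {f.name}: {getattr(config, f.name)}")
    lines.append("")
    lines.append("results:")
    for key in sorted(summary):
        val = summary[key]
        if isinstance(val, float):
            lines.append(f"  {key}: {val:.4f}")
        else:
            lines.append(f"  {key}: {val}")
    Path(path).write_text("\n".join(lines) + "\n")
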
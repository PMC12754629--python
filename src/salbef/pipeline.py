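"""End-to-end orchestration: simulate -> fit -> partition -> trends.

Each stage reads and writes the CSV schemas in :mod:`salbef.io`, so stages
can run in sequence from one seed or individually against files on disk
(including measured data supplied in the same schemas). A run manifest
records the config echo, seed, per-file row counts and warnings.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import befmodel, io, simulate, trends
from .partition import partition_experiment, partition_from_composition

log = logging.getLogger("salbef")

__all__ = ["PipelineConfig", "RunManifest", "demo_config", "run_simulate", "run_all"]


@dataclass
class PipelineConfig:
    """Configuration for a pipeline run (YAML-serializable)."""

    sim: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)
    alpha: float = 0.05
    trend_range: tuple = (0.0, 15.0)
    #: "member" partitions from per-strain yields; "composition" goes through
    #: the genus-abundance route used for the highest-diversity communities.
    partition_route: str = "member"
    #: Split rule for genus yields across congeneric strains on the
    #: composition route: "monoculture" (proportional) or "equal".
    abundance_rule: str = "monoculture"
    #: Group labels whose partition results form the treatment-level series.
    stats_groups: tuple = ("D",)
    run_simulate: bool = True
    run_fit: bool = True
    run_partition: bool = True
    run_trends: bool = True

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.partition_route not in ("member", "composition"):
            raise ValueError("partition_route must be 'member' or 'composition'")
        self.trend_range = tuple(float(v) for v in self.trend_range)

    def to_dict(self) -> dict:
        return {
            "sim": self.sim.to_dict(),
            "alpha": self.alpha,
            "trend_range": list(self.trend_range),
            "partition_route": self.partition_route,
            "abundance_rule": self.abundance_rule,
            "stats_groups": list(self.stats_groups),
            "run_simulate": self.run_simulate,
            "run_fit": self.run_fit,
            "run_partition": self.run_partition,
            "run_trends": self.run_trends,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim_cfg = simulate.SimulationConfig.from_dict(d.pop("sim", {}))
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        if "stats_groups" in known:
            known["stats_groups"] = tuple(known["stats_groups"])
        return cls(sim=sim_cfg, **known)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def demo_config(seed: int | None = None) -> PipelineConfig:
    """The shipped demo scenario: the full study design with salinity-
    dependent selection/complementarity structure (selection rising to 15%
    then dropping at 20%, complementarity declining)."""
    return _shipped_config("demo.yaml", seed)


def collapse_config(seed: int | None = None) -> PipelineConfig:
    """The hypersaline-collapse variant: a sparse halophile pool with narrow
    tolerance breadths, so low-richness communities lose function at 20%
    NaCl and the diversity-functioning exponent steepens there."""
    return _shipped_config("demo_collapse.yaml", seed)


def _shipped_config(name: str, seed: int | None) -> PipelineConfig:
    with resources.files("salbef").joinpath(name).open() as fh:
        cfg = PipelineConfig.from_dict(yaml.safe_load(fh))
    if seed is not None:
        cfg.sim = cfg.sim.with_seed(seed)
    return cfg


def exponent_contrast_study(
    config: PipelineConfig,
    n_replicates: int = 12,
    s_lo: float = 0.9,
    s_hi: float = 20.0,
) -> dict:
    """Pooled exponent contrast b(s_hi) - b(s_lo) over replicate experiments.

    Simulates ``n_replicates`` independent experiments (child seeds derived
    from the config seed), fits the power model per salinity in each, and
    pools the exponent difference by inverse variance. Returns a dict with
    the pooled difference, its standard error and z score.
    """
    pairs = []
    for k in range(n_replicates):
        child = int(np.random.SeedSequence((config.sim.seed, k)).generate_state(1)[0] % 2**31)
        sim = config.sim.with_seed(child)
        exp = simulate.simulate_experiment(sim)
        fits = {
            f.salinity: f
            for f in befmodel.fit_all_salinities(exp.observations, floor=sim.detection_floor)
        }
        pairs.append((fits[s_lo], fits[s_hi]))
    diff, se = befmodel.pooled_exponent_difference(pairs)
    return {"difference": diff, "se": se, "z": diff / se, "n_replicates": n_replicates}


@dataclass
class RunManifest:
    """What a run produced: config echo, seed, row counts, warnings."""

    config: dict
    seed: int
    versions: dict
    files: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    skipped: list = field(default_factory=list)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "seed": self.seed,
                    "versions": self.versions,
                    "files": self.files,
                    "warnings": self.warnings,
                    "skipped": self.skipped,
                },
                fh,
                indent=2,
                default=str,
            )


def _versions() -> dict:
    import numpy, scipy, statsmodels  # noqa: PLC0415

    return {
        "salbef": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
    }


def _new_manifest(config: PipelineConfig) -> RunManifest:
    return RunManifest(config=config.to_dict(), seed=config.sim.seed, versions=_versions())


def _write(df: pd.DataFrame, outdir: Path, name: str, manifest: RunManifest) -> None:
    io.write_table(df, outdir / name)
    manifest.files[name] = len(df)
    log.info("wrote %s (%d rows)", name, len(df))


def run_simulate(config: PipelineConfig, outdir) -> simulate.Experiment:
    """Simulation stage: generate and write the experiment file set."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    experiment = simulate.simulate_experiment(config.sim)
    manifest = _new_manifest(config)
    manifest.files.update(simulate.write_experiment(experiment, outdir))
    manifest.write(outdir / "manifest.json")
    return experiment


def run_all(config: PipelineConfig, outdir, input_dir=None) -> dict:
    """Run the enabled stages end to end and write all output tables.

    With ``run_simulate`` on, inputs are generated from ``config.sim``;
    otherwise they are read from ``input_dir`` (schemas as written by the
    simulation stage). Stages whose inputs are unavailable are skipped with a
    warning recorded in the manifest rather than failing the run. Returns a
    dict with the manifest and every in-memory result.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _new_manifest(config)
    results: dict = {"manifest": manifest}

    caught: list = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        # --- inputs -------------------------------------------------------
        experiment = None
        observations = designs = monocultures = member_yields = None
        if config.run_simulate:
            experiment = simulate.simulate_experiment(config.sim)
            manifest.files.update(simulate.write_experiment(experiment, outdir))
            observations = experiment.observations
            designs = experiment.designs
            monocultures = experiment.monocultures
            member_yields = experiment.member_yields
            results["experiment"] = experiment
        else:
            src = Path(input_dir) if input_dir is not None else outdir
            observations = io.read_table(src / "observations.csv", io.OBSERVATIONS_COLUMNS)
            try:
                loaded = simulate.read_experiment(src)
                designs = loaded.designs
                monocultures = loaded.monocultures
                member_yields = loaded.member_yields
            except FileNotFoundError as exc:
                manifest.skipped.append(
                    f"partitioning inputs incomplete ({exc}); only observations.csv available"
                )
        results["observations"] = observations

        # --- BEF model ----------------------------------------------------
        if config.run_fit:
            fits = befmodel.fit_all_salinities(observations, floor=config.sim.detection_floor)
            _write(befmodel.fits_table(fits), outdir, "bef_fits.csv", manifest)
            results["bef_fits"] = fits

            trend_rows = []
            for response, form in (
                ("intercept", "linear"),
                ("exponent", "linear"),
                ("exponent", "quadratic"),
            ):
                try:
                    t = befmodel.parameter_trend(fits, response, form)
                except ValueError as exc:
                    manifest.skipped.append(f"{response} {form} trend: {exc}")
                    continue
                trend_rows.append(
                    {
                        "response": t.response,
                        "form": t.form,
                        "slope": t.slope,
                        "slope2": t.slope2,
                        "R2": t.r2,
                        "p_value": t.p_value,
                        "n": t.n,
                    }
                )
                results[f"trend_{response}_{form}"] = t
            _write(pd.DataFrame(trend_rows), outdir, "trends.csv", manifest)

            try:
                results["mixed_model"] = befmodel.fit_mixed_model(
                    observations, floor=config.sim.detection_floor
                )
            except ValueError as exc:
                manifest.skipped.append(f"mixed model: {exc}")
        else:
            manifest.skipped.append("bef_model stage disabled")

        # --- partitioning -------------------------------------------------
        partition_df = None
        if config.run_partition and designs is not None:
            floor = config.sim.detection_floor
            if config.partition_route == "composition":
                if experiment is None:
                    manifest.skipped.append(
                        "composition route needs a simulated experiment (strain genera)"
                    )
                else:
                    composition = simulate.composition_table(
                        experiment, groups=config.stats_groups
                    )
                    _write(composition, outdir, "composition.csv", manifest)
                    partition_df = partition_from_composition(
                        designs,
                        experiment.library,
                        monocultures,
                        observations,
                        composition,
                        floor=floor,
                        rule=config.abundance_rule,
                    )
            else:
                partition_df = partition_experiment(
                    designs, monocultures, member_yields, floor=floor
                )
            if partition_df is not None:
                _write(partition_df, outdir, "partition.csv", manifest)
                results["partition"] = partition_df
        elif config.run_partition:
            manifest.skipped.append("partitioning skipped: designs/monocultures unavailable")
        else:
            manifest.skipped.append("partitioning stage disabled")

        # --- treatment statistics ----------------------------------------
        if config.run_trends and partition_df is not None:
            stats = trends.run_effect_stats(
                partition_df,
                groups=config.stats_groups,
                salinity_range=config.trend_range,
                alpha=config.alpha,
            )
            _write(stats["trends"], outdir, "trends_effects.csv", manifest)
            _write(stats["anova"], outdir, "anova.csv", manifest)
            _write(stats["tukey"], outdir, "tukey.csv", manifest)
            results["effect_stats"] = stats
            results["selection_share"] = trends.selection_share(
                partition_df, groups=config.stats_groups
            )
        elif config.run_trends:
            manifest.skipped.append("trends stage skipped: no partition results")
        else:
            manifest.skipped.append("trends stage disabled")

        caught = wlist

    manifest.warnings = sorted({f"{w.category.__name__}: {w.message}" for w in caught})
    manifest.write(outdir / "manifest.json")
    return results
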
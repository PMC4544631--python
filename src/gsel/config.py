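"""Run configuration and the end-to-end pipeline.

Configuration is a nested YAML file mapped strictly onto dataclasses:
unknown keys are rejected, everything has a documented default, and every
stochastic stage carries an explicit seed after resolution.  The pipeline
chains simulate -> adjust -> kinship -> cv -> qtl_share and records a
manifest (config echo, seeds, stage timings, output hashes) sufficient to
reproduce any output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .predictors import GibbsConfig

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Two-population simulation parameters (see :func:`gsel.study_populations`)."""

    n_chromosomes: int = 21
    chrom_length_cM: float = 150.0
    markers_per_chromosome: int = 120
    pool_size: int = 160
    parents_per_population: int = 110
    n_crosses: int = 70
    lines_per_cross: int = 5
    line_type_a: str = "DH"
    line_type_b: str = "RIL"
    selfing_generations: int = 8
    n_qtl: int = 100
    sigma_a: float = 1.0
    h2: float = 0.6
    seed: int = 0


@dataclass
class CVConfig:
    kind: str = "single"
    method: str = "RIDGE"
    train_fraction: float = 0.8
    n_iterations: int = 200
    seed: int = 0


@dataclass
class QTLShareConfig:
    fractions: list = field(default_factory=lambda: [round(f, 1) for f in np.arange(0.1, 1.01, 0.1)])
    h2_levels: list = field(default_factory=lambda: [0.3, 0.6])
    n_reps: int = 50
    n_qtl: int = 100
    method: str = "RIDGE"
    seed: int = 0


@dataclass
class RunConfig:
    stages: list = field(default_factory=lambda: ["simulate"])
    output_dir: str = "gsel_run"
    log_level: str = "INFO"
    seed: int = 0
    paper_scale: bool = False  # full-length Gibbs chains instead of the scaled-down demo profile
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    gibbs: GibbsConfig = field(default_factory=GibbsConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    qtl_share: QTLShareConfig = field(default_factory=QTLShareConfig)


def _merge_strict(cls, data: dict, path: str = ""):
    """Map a nested dict onto a dataclass, rejecting unknown keys."""
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in (data or {}).items():
        if key not in fields:
            raise KeyError(f"unknown config key {path + key!r}")
        ftype = fields[key].type
        target = {
            "simulation": SimulationConfig,
            "gibbs": GibbsConfig,
            "cv": CVConfig,
            "qtl_share": QTLShareConfig,
        }.get(key)
        if target is not None and isinstance(value, dict):
            kwargs[key] = _merge_strict(target, value, path=f"{path}{key}.")
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load a YAML config; defaults fill everything not given."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    cfg = _merge_strict(RunConfig, data)
    if set(cfg.stages) - {"simulate", "adjust", "kinship", "cv", "qtl_share"}:
        raise ValueError(f"unknown stage in {cfg.stages}")
    logger.info("resolved config: %s", dataclasses.asdict(cfg))
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages and write outputs plus a manifest.

    Stage outputs (all TSV/JSON) land in ``cfg.output_dir``; the returned
    manifest is also written there as ``manifest.json``.  On stage failure a
    ``<stage>.failed`` marker is left next to any partial outputs.
    """
    from . import (
        adjusted_by_location,
        anova_locations,
        combined_ibs_kinship,
        heritability_line_mean,
        impute_missing,
        intersect_markers,
        kinship_group_summary,
        normalize_kinship,
        qtl_sharing_experiment,
        run_cv,
        simulate_trait,
        study_populations,
        write_genetic_map,
        write_genotype_matrix,
        write_phenotype_table,
    )
    from .evaluation import CVScheme
    from .simulate import draw_architecture, simulate_field_trial

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(cfg),
        "stages": {},
        "outputs": {},
    }
    state = {}
    for stage in cfg.stages:
        t0 = time.time()
        try:
            _run_stage(stage, cfg, out, state)
        except Exception:
            (out / f"{stage}.failed").write_text("stage failed; see log\n")
            raise
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _run_stage(stage: str, cfg: RunConfig, out: Path, state: dict):
    from . import (
        adjusted_by_location,
        anova_locations,
        combined_ibs_kinship,
        heritability_line_mean,
        kinship_group_summary,
        normalize_kinship,
        qtl_sharing_experiment,
        run_cv,
        simulate_trait,
        study_populations,
        write_genetic_map,
        write_genotype_matrix,
        write_phenotype_table,
    )
    from .evaluation import CVScheme
    from .simulate import draw_architecture, simulate_field_trial

    sim = cfg.simulation
    if stage != "simulate" and "pop_a" not in state:
        raise ValueError(
            f"stage {stage!r} requires the 'simulate' stage earlier in the pipeline"
        )
    if stage == "simulate":
        pop_a, pop_b, founders = study_populations(
            seed=sim.seed,
            markers_per_chromosome=sim.markers_per_chromosome,
            n_chromosomes=sim.n_chromosomes,
            chrom_length_cM=sim.chrom_length_cM,
            pool_size=sim.pool_size,
            parents_per_population=sim.parents_per_population,
            n_crosses=sim.n_crosses,
            lines_per_cross=sim.lines_per_cross,
            line_type_a=sim.line_type_a,
            line_type_b=sim.line_type_b,
            selfing_generations=sim.selfing_generations,
        )
        rng = np.random.default_rng(sim.seed + 1)
        poly = pop_a.polymorphic_mask()
        arch = draw_architecture(
            np.flatnonzero(poly), sim.n_qtl, sim.sigma_a, rng, h2=sim.h2
        )
        y_a, g_a = simulate_trait(pop_a, arch, rng)
        trial = simulate_field_trial(
            dict(zip(pop_a.line_ids, g_a)), seed=rng, trait_name="simtrait"
        )
        write_genotype_matrix(pop_a, out / "genotypes_popA.tsv")
        write_genotype_matrix(pop_b, out / "genotypes_popB.tsv")
        write_genetic_map(founders.map, out / "map.tsv")
        write_phenotype_table(trial, out / "phenotypes_popA.tsv")
        pd.DataFrame({"line": pop_a.line_ids, "value": y_a}).to_csv(
            out / "trait_popA.tsv", sep="\t", index=False
        )
        truth = {
            "qtl_marker_ids": [pop_a.marker_ids[i] for i in arch.qtl_marker_indices],
            "effects": arch.effects.tolist(),
            "h2": sim.h2,
            "genetic_values": dict(zip(pop_a.line_ids, map(float, g_a))),
            "phenotypes": dict(zip(pop_a.line_ids, map(float, y_a))),
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=2))
        state.update(pop_a=pop_a, pop_b=pop_b, arch=arch, y_a=y_a, trial=trial)
    elif stage == "adjust":
        trial = state["trial"]
        adj = adjusted_by_location(trial, "simtrait")
        adj.to_csv(out / "adjusted_popA.tsv", sep="\t", index=False)
        res = anova_locations(adj)
        report = {
            "sigma2_g": res.sigma2_g,
            "sigma2_e": res.sigma2_e,
            "n_locations": res.n_locations,
            "F_genotype": res.F_genotype,
            "p_value": res.p_value,
            "h2_line_mean": heritability_line_mean(res),
            "method": res.method,
        }
        (out / "anova_popA.json").write_text(json.dumps(report, indent=2))
        state["adjusted"] = adj
    elif stage == "kinship":
        from .io import intersect_markers

        pa, pb = intersect_markers([state["pop_a"], state["pop_b"]])
        k = normalize_kinship(combined_ibs_kinship([pa, pb]))
        k.to_frame().to_csv(out / "kinship.tsv", sep="\t")
        kinship_group_summary(k).to_csv(out / "kinship_groups.tsv", sep="\t", index=False)
    elif stage == "cv":
        scheme = CVScheme(
            kind="single",
            training_populations=[state["pop_a"].population_id],
            train_fraction=cfg.cv.train_fraction,
            n_iterations=cfg.cv.n_iterations,
            seed=cfg.cv.seed,
        )
        res = run_cv(
            scheme,
            cfg.cv.method,
            {state["pop_a"].population_id: (state["pop_a"], state["y_a"])},
            trait="simtrait",
        )
        pd.DataFrame(
            {"iteration": range(len(res.per_iteration_r)), "r": res.per_iteration_r}
        ).to_csv(out / "cv_iterations.tsv", sep="\t", index=False)
        (out / "cv_summary.json").write_text(
            json.dumps(
                {
                    "scheme": scheme.kind,
                    "method": res.method,
                    "mean_r": res.mean_r,
                    "sd_r": res.sd_r,
                    "n_iterations": scheme.n_iterations,
                    "n_undefined": res.n_undefined,
                },
                indent=2,
            )
        )
    elif stage == "qtl_share":
        from .io import intersect_markers

        pa, pb = intersect_markers([state["pop_a"], state["pop_b"]])
        table = qtl_sharing_experiment(
            pa,
            pb,
            fractions=cfg.qtl_share.fractions,
            h2_levels=tuple(cfg.qtl_share.h2_levels),
            method=cfg.qtl_share.method,
            n_qtl=cfg.qtl_share.n_qtl,
            n_reps=cfg.qtl_share.n_reps,
            seed=cfg.qtl_share.seed,
        )
        table.to_csv(out / "qtl_sharing.tsv", sep="\t", index=False)
    else:
        raise ValueError(f"unknown stage {stage!r}")
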
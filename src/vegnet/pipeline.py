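"""End-to-end pipeline driver with reproducibility bookkeeping.

Stages: (optional) simulate -> infer overall consensus network -> infer one
environment-only network per species -> sign links -> build Env+Bio / Env
predictor sets -> fit and evaluate the model families -> syndrome analysis.
Every stage writes its artifact under the output directory and the manifest
records the configuration hash, seeds and package version, so a rerun with
the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import run_evaluation
from .network import consensus_network, constraints_for_table, default_constraints, parent_sets
from .plot_data import (SPATIAL_NODE, PlotTable, read_plot_table, read_syndrome_map,
                        write_plot_table, write_syndrome_map)
from .sdm import build_predictor_sets
from .signing import assign_signs
from .syndromes import chi_square_gof, classify_links, syndrome_null_proportions
from .synthetic import SimulationConfig, sample_ground_truth, simulate_plots

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_full_pipeline", "n_pairwise_interactions",
           "infer_per_species_env_networks", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.record = {"stage": stage, "error": message}


def n_pairwise_interactions(n_species: int) -> int:
    """Number of possible pairwise interactions among n species: (n^2 - n)/2."""
    if n_species < 1:
        raise ValueError("need at least one species")
    return (n_species * n_species - n_species) // 2


@dataclass
class PipelineConfig:
    output_dir: str = "results/pipeline"
    plot_table: str | None = None      # None -> simulate
    syndrome_map: str | None = None
    runs: int = 500
    score: str = "bic"
    direction_cutoff: float = 0.5
    restarts: int = 5
    alpha: float = 0.05
    basis_dim: int = 30
    frac_calibration: float = 2 / 3
    include_random: bool = True
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        obj = json.loads(Path(path).read_text())
        sim = obj.pop("simulation", None)
        cfg = cls(**obj)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        return cfg


def infer_per_species_env_networks(table: PlotTable, runs: int, score: str,
                                   direction_cutoff: float, seed: int,
                                   restarts: int = 5) -> dict:
    """One consensus network per species over {focal species + environment}.

    Uses the same runs/threshold machinery as the overall network, so the
    Env parent sets are found under the identical inference regime.
    """
    env_nodes = [a.name for a in table.env_attributes] + [SPATIAL_NODE]
    no_parent = [a.name for a in table.env_attributes if not a.may_have_parents]
    no_parent.append(SPATIAL_NODE)
    nets = {}
    ss = np.random.SeedSequence(seed)
    for sp, child_seed in zip(table.species, ss.spawn(len(table.species))):
        sub = PlotTable(
            df=table.df[["plot_id", "lon", "lat"]
                        + [a.name for a in table.env_attributes] + [sp]].copy(),
            species=[sp], env_attributes=list(table.env_attributes), scale=table.scale)
        constraints = default_constraints([sp], env_nodes, no_parent)
        nets[sp] = consensus_network(sub, constraints, runs=runs,
                                     direction_cutoff=direction_cutoff, score=score,
                                     seed=int(child_seed.generate_state(1)[0] % (2**31 - 1)),
                                     restarts=restarts)
    return nets


def run_full_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and return the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: int(s.generate_state(1)[0] % (2**31 - 1))
             for name, s in zip(
                 ["simulate", "infer", "env_nets", "evaluate"], ss.spawn(4))}

    # --- data ---------------------------------------------------------
    stage = "simulate" if config.plot_table is None else "load"
    try:
        if config.plot_table is None:
            sim = dataclasses.replace(config.simulation, seed=seeds["simulate"])
            truth = sample_ground_truth(sim)
            table = simulate_plots(truth, sim.n_plots, seed=seeds["simulate"] + 1)
            truth.to_json(out / "ground_truth.json")
            write_plot_table(table, out / "plots.csv")
            syndromes = dict(truth.syndromes)
            write_syndrome_map(syndromes, out / "syndromes.csv")
        else:
            if not Path(config.plot_table).exists():
                raise FileNotFoundError(f"plot table not found: {config.plot_table}")
            table = read_plot_table(config.plot_table)
            syndromes = (read_syndrome_map(config.syndrome_map)
                         if config.syndrome_map else {})
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(stage, str(e)) from e
    counts["plots"] = table.n_plots
    counts["species"] = len(table.species)
    logger.info("stage %s: %d plots, %d species", stage, counts["plots"], counts["species"])

    # --- networks -----------------------------------------------------
    try:
        overall = consensus_network(table, constraints_for_table(table),
                                    runs=config.runs, score=config.score,
                                    direction_cutoff=config.direction_cutoff,
                                    seed=seeds["infer"], restarts=config.restarts)
        overall.to_json(out / "overall_network.json")
        env_nets = infer_per_species_env_networks(
            table, config.runs, config.score, config.direction_cutoff,
            seeds["env_nets"], restarts=config.restarts)
        for sp, net in env_nets.items():
            net.to_json(out / f"env_net_{sp}.json")
    except Exception as e:
        raise PipelineError("infer", str(e)) from e
    counts["arcs"] = len(overall.arcs)
    counts["significant_links"] = sum(a.significant for a in overall.arcs)
    logger.info("stage infer: %d arcs, %d significant", counts["arcs"],
                counts["significant_links"])

    # --- signing ------------------------------------------------------
    try:
        links = assign_signs(overall, table, alpha=config.alpha)
        pd.DataFrame([l.as_dict() for l in links]).to_csv(
            out / "signed_links.csv", index=False)
    except Exception as e:
        raise PipelineError("sign", str(e)) from e
    counts["signed_links"] = sum(l.sign != "unsigned" for l in links)
    logger.info("stage sign: %d signed of %d", counts["signed_links"], len(links))

    # --- SDMs + evaluation -------------------------------------------
    try:
        psets = build_predictor_sets(overall, env_nets, table.species)
        (out / "predictor_sets.json").write_text(
            json.dumps(psets, indent=1, sort_keys=True))
        report = run_evaluation(table, psets, seed=seeds["evaluate"],
                                frac_calibration=config.frac_calibration,
                                include_random=config.include_random,
                                basis_dim=config.basis_dim)
        report.to_json(out / "evaluation.json")
        report.per_species.to_csv(out / "per_species_metrics.csv", index=False)
        report.per_plot.to_csv(out / "per_plot_bc.csv", index=False)
    except Exception as e:
        raise PipelineError("evaluate", str(e)) from e
    counts["fitted_models"] = 2 * len(report.per_species)
    logger.info("stage evaluate: %d species evaluated", len(report.per_species))

    # --- syndromes ----------------------------------------------------
    try:
        syndrome_report = {}
        if syndromes:
            cls_all = classify_links(links, syndromes, species=table.species)
            cls_pos = classify_links(links, syndromes, species=table.species,
                                     positive_only=True)
            syndrome_report = {"counts_all": cls_all, "counts_positive": cls_pos}
            n_links = sum(cls_all[k] for k in ("TT", "QQ", "TQ", "QT"))
            if n_links:
                for mode in ("uniform", "frequency"):
                    props = syndrome_null_proportions(syndromes, mode)
                    res = chi_square_gof({k: cls_all[k] for k in ("TT", "QQ", "TQ", "QT")},
                                         props)
                    syndrome_report[f"chi2_{mode}"] = res.as_dict()
        (out / "syndrome_analysis.json").write_text(
            json.dumps(syndrome_report, indent=1, sort_keys=True))
    except Exception as e:
        raise PipelineError("syndromes", str(e)) from e

    manifest = {"config": config.as_dict(), "config_hash": config.config_hash(),
                "seeds": seeds, "version": __version__, "counts": counts}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
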
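"""Synthetic vegetation-plot communities with known dependence structure.

The generator draws a ground-truth directed acyclic network over
environmental attributes and species, equips every node with a conditional
probability table, and samples relevé-style plot tables from it by ancestral
sampling.  It emulates the statistical features the downstream analysis
relies on: ordered cover classes, exogenous environmental drivers,
mostly-positive cross-species conditional dependencies concentrated within
trait syndromes, and coarse spatial structure.  Recovery of the known
network is the benchmark for the inference stack.

Signed dependence is built through a proportional-odds construction: each
ordered node has latent cutpoints fixed by a base marginal distribution, and
each parent shifts the latent scale by ``sign * effect_strength`` times its
(centred, rescaled) level.  A "+" arc therefore makes the child's class
distribution stochastically increasing in the parent's level, a "-" arc
stochastically decreasing; multiple parents combine additively on the latent
scale.  Unordered parents (geology, orientation, land use, growth form,
spatial block) contribute a per-level offset instead and carry no sign.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .plot_data import (
    DEFAULT_COVER_SCALE,
    DEFAULT_ENV_ATTRIBUTES,
    SPATIAL_NODE,
    CoverScale,
    EnvAttribute,
    PlotTable,
)

__all__ = [
    "SimulationConfig",
    "GroundTruthNetwork",
    "sample_ground_truth",
    "simulate_plots",
    "structure_recovery_metrics",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the simulator.

    Defaults mirror the source survey: 68 woody species over 1570 plots,
    roughly 1.94 parents per species of which slightly over half are other
    species, 95% positive signs, and association concentrated within
    syndromes.
    """

    n_species: int = 68
    n_env: int = 6
    n_plots: int = 1570
    arc_density: float = 1.94        # expected parents per species
    fraction_species_parents: float = 0.55
    fraction_positive_signs: float = 0.95
    same_syndrome_bias: float = 3.0  # weight multiplier for same-syndrome candidate arcs
    effect_strength: float = 1.5     # latent logit shift per unit parent level
    n_cover_levels: int = 4          # ordered cover classes actually used by species
    max_parents: int = 2             # keeps every CPT family estimable at survey-scale n
    spatial_parent: bool = False     # let the 9-level spatial block parent species
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_species, self.n_env, self.n_plots) < 1:
            raise ValueError("counts must be positive")
        for name in ("fraction_species_parents", "fraction_positive_signs"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.arc_density < 0:
            raise ValueError("arc_density must be nonnegative")


# Unordered-categorical env levels used by the simulator.
_ENV_LEVELS = {
    "soil": ["siliceous", "calcareous", "mix"],
    "orientation": ["N", "S", "E", "W"],
    "landuse": ["forest", "agri", "mix"],
    "dom_form": ["tree", "shrub", "mix"],
}
_N_QUART = 4
_SPAC_SIDE = 3


@dataclass
class GroundTruthNetwork:
    """A known DAG + CPT parameterisation used to simulate plot tables.

    ``arcs`` maps (parent, child) to a sign in {"+", "-", None}; None marks
    arcs from unordered parents, whose effect is a per-level latent offset
    (``offsets``) rather than a monotone shift.  ``cutpoints`` holds each
    ordered node's proportional-odds cutpoints; root unordered nodes carry
    their marginal distribution in ``root_probs``.
    """

    species: list[str]
    env_attributes: list[EnvAttribute]
    levels: dict[str, list[str]]
    parents: dict[str, list[str]]
    arcs: dict[tuple[str, str], str | None]
    cutpoints: dict[str, np.ndarray]
    offsets: dict[tuple[str, str], np.ndarray]
    effect_strength: float
    syndromes: dict[str, str]
    scale: CoverScale = field(default_factory=lambda: DEFAULT_COVER_SCALE)

    @property
    def nodes(self) -> list[str]:
        return [a.name for a in self.env_attributes] + [SPATIAL_NODE] + self.species

    @property
    def arc_set(self) -> set[tuple[str, str]]:
        return set(self.arcs)

    def is_ordered(self, node: str) -> bool:
        return node in self.cutpoints

    def _parent_shift(self, node: str, parent: str, parent_codes: np.ndarray) -> np.ndarray:
        """Latent shift contributed by one parent, per observation."""
        sign = self.arcs[(parent, node)]
        if sign is None:
            return self.offsets[(parent, node)][parent_codes]
        k = len(self.levels[parent]) - 1
        scaled = (parent_codes / k - 0.5) * 2.0  # centre levels onto [-1, 1]
        return (1.0 if sign == "+" else -1.0) * self.effect_strength * scaled

    def conditional_probs(self, node: str, parent_codes: dict[str, np.ndarray]) -> np.ndarray:
        """Class probabilities of ``node`` for each observation (rows sum to 1)."""
        n = len(next(iter(parent_codes.values()))) if parent_codes else 1
        eta = np.zeros(n)
        for p in self.parents[node]:
            eta = eta + self._parent_shift(node, p, parent_codes[p])
        cut = self.cutpoints[node]
        cum = expit(cut[None, :] - eta[:, None])  # P(Y <= k), increasing in k
        cum = np.concatenate([cum, np.ones((n, 1))], axis=1)
        probs = np.diff(np.concatenate([np.zeros((n, 1)), cum], axis=1), axis=1)
        return np.clip(probs, 0, None) / np.clip(probs, 0, None).sum(axis=1, keepdims=True)

    def cpt(self, node: str) -> np.ndarray:
        """Materialised CPT: one row per parent configuration, rows sum to 1."""
        pars = self.parents[node]
        if not self.is_ordered(node):
            if pars:
                raise ValueError("unordered nodes are roots in this generator")
            return self.root_probs(node)[None, :]
        configs = list(itertools.product(*[range(len(self.levels[p])) for p in pars])) or [()]
        codes = {p: np.array([c[i] for c in configs]) for i, p in enumerate(pars)}
        return self.conditional_probs(node, codes)

    def root_probs(self, node: str) -> np.ndarray:
        return self._root_probs[node]

    _root_probs: dict[str, np.ndarray] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "species": self.species,
            "env_attributes": [asdict(a) for a in self.env_attributes],
            "levels": self.levels,
            "parents": self.parents,
            "arcs": [{"parent": p, "child": c, "sign": s} for (p, c), s in sorted(self.arcs.items())],
            "cutpoints": {k: v.tolist() for k, v in self.cutpoints.items()},
            "offsets": [{"parent": p, "child": c, "values": v.tolist()}
                        for (p, c), v in sorted(self.offsets.items())],
            "root_probs": {k: v.tolist() for k, v in self._root_probs.items()},
            "effect_strength": self.effect_strength,
            "syndromes": self.syndromes,
            "cover_scale": self.scale.to_json(),
        }
        Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthNetwork":
        obj = json.loads(Path(path).read_text())
        net = cls(
            species=obj["species"],
            env_attributes=[EnvAttribute(**d) for d in obj["env_attributes"]],
            levels=obj["levels"],
            parents=obj["parents"],
            arcs={(d["parent"], d["child"]): d["sign"] for d in obj["arcs"]},
            cutpoints={k: np.asarray(v) for k, v in obj["cutpoints"].items()},
            offsets={(d["parent"], d["child"]): np.asarray(d["values"]) for d in obj["offsets"]},
            effect_strength=obj["effect_strength"],
            syndromes=obj["syndromes"],
            scale=CoverScale.from_json(obj["cover_scale"]),
        )
        net._root_probs = {k: np.asarray(v) for k, v in obj["root_probs"].items()}
        return net


def _cutpoints_from_marginal(probs: np.ndarray) -> np.ndarray:
    """Proportional-odds cutpoints whose eta=0 marginal equals ``probs``."""
    cum = np.cumsum(probs)[:-1]
    cum = np.clip(cum, 1e-9, 1 - 1e-9)
    return np.log(cum / (1 - cum))


def sample_ground_truth(config: SimulationConfig) -> GroundTruthNetwork:
    """Draw a ground-truth network honouring the structural constraints.

    Environmental nodes come first; exogenous ones (warmest-quarter
    temperature, annual precipitation, geology, orientation) and the spatial
    block never receive arcs.  Species receive parents only from
    environmental nodes and earlier species, so the graph is acyclic by
    construction and respects the inference blacklist.
    """
    rng = np.random.default_rng(config.seed)
    env_attributes = list(DEFAULT_ENV_ATTRIBUTES[: config.n_env])
    species = [f"sp{i + 1:02d}" for i in range(config.n_species)]

    levels: dict[str, list[str]] = {}
    for a in env_attributes:
        levels[a.name] = ([f"q{i + 1}" for i in range(_N_QUART)]
                          if a.kind == "continuous" else list(_ENV_LEVELS[a.name]))
    levels[SPATIAL_NODE] = [f"b{i}{j}" for i in range(_SPAC_SIDE) for j in range(_SPAC_SIDE)]
    species_scale = DEFAULT_COVER_SCALE.head(config.n_cover_levels)
    for sp in species:
        levels[sp] = species_scale.labels

    # Syndromes in the survey's 33:27:8 proportion.
    n_t = round(config.n_species * 33 / 68)
    n_q = round(config.n_species * 27 / 68)
    lab = ["T"] * n_t + ["Q"] * n_q + ["none"] * (config.n_species - n_t - n_q)
    syndromes = dict(zip(species, rng.permutation(lab)))

    ordered_env = [a.name for a in env_attributes if a.kind == "continuous"]
    parents: dict[str, list[str]] = {n: [] for n in levels}
    arcs: dict[tuple[str, str], str | None] = {}
    offsets: dict[tuple[str, str], np.ndarray] = {}

    env_names = [a.name for a in env_attributes]
    if config.spatial_parent:
        env_names.append(SPATIAL_NODE)
    for i, sp in enumerate(species):
        n_par = min(int(rng.poisson(config.arc_density)), config.max_parents)
        chosen: list[str] = []
        for _ in range(n_par):
            species_cands = [s for s in species[:i] if s not in chosen]
            env_cands = [e for e in env_names if e not in chosen]
            take_species = species_cands and (
                not env_cands or rng.random() < config.fraction_species_parents)
            if take_species:
                w = np.array([config.same_syndrome_bias
                              if syndromes[s] == syndromes[sp] and syndromes[sp] != "none"
                              else 1.0
                              for s in species_cands])
                parent = rng.choice(species_cands, p=w / w.sum())
            elif env_cands:
                parent = rng.choice(env_cands)
            else:
                break
            chosen.append(str(parent))
        for p in chosen:
            parents[sp].append(p)
            if p in species or p in ordered_env:
                arcs[(p, sp)] = "+" if rng.random() < config.fraction_positive_signs else "-"
            else:
                arcs[(p, sp)] = None
                k = len(levels[p])
                off = rng.uniform(-config.effect_strength, config.effect_strength, size=k)
                offsets[(p, sp)] = off - off.mean()

    # Base marginals: species mostly absent; higher classes progressively rarer.
    cutpoints: dict[str, np.ndarray] = {}
    root_probs: dict[str, np.ndarray] = {}
    for name in ordered_env:
        cutpoints[name] = _cutpoints_from_marginal(np.full(_N_QUART, 1 / _N_QUART))
    for a in env_attributes:
        if a.kind != "continuous":
            k = len(levels[a.name])
            p = rng.dirichlet(np.full(k, 8.0))
            root_probs[a.name] = p
    root_probs[SPATIAL_NODE] = np.full(_SPAC_SIDE ** 2, 1 / _SPAC_SIDE ** 2)
    base = np.array([0.45, 0.25] + [0.3 / (config.n_cover_levels - 2)] * (config.n_cover_levels - 2))
    for sp in species:
        jitter = rng.dirichlet(base * 40)
        cutpoints[sp] = _cutpoints_from_marginal(jitter)

    net = GroundTruthNetwork(
        species=species, env_attributes=env_attributes, levels=levels,
        parents=parents, arcs=arcs, cutpoints=cutpoints, offsets=offsets,
        effect_strength=config.effect_strength, syndromes=syndromes,
        scale=species_scale,
    )
    net._root_probs = root_probs
    return net


# Continuous bands used to decorate quartile classes with continuous values.
_CONT_BANDS = {"Twarm": (14.0, 30.0), "anualP": (300.0, 1500.0)}


def simulate_plots(net: GroundTruthNetwork, n_plots: int, seed: int = 0) -> PlotTable:
    """Ancestral sampling of a plot table: environment first, then species.

    Ordered continuous attributes are sampled as quartile classes in the
    network and decorated with a continuous value uniform within the class
    band, so the table carries both the categorical and continuous views.
    Coordinates are uniform within the plot's spatial block.
    """
    rng = np.random.default_rng(seed)
    codes: dict[str, np.ndarray] = {}

    def draw(probs: np.ndarray) -> np.ndarray:
        # probs: (n, k) rows; inverse-CDF sampling
        u = rng.random(n_plots)
        return (np.cumsum(probs, axis=1) < u[:, None]).sum(axis=1)

    ordered_env = {a.name for a in net.env_attributes if a.kind == "continuous"}
    for a in net.env_attributes:
        if a.name in ordered_env:
            probs = net.conditional_probs(a.name, {})
            codes[a.name] = draw(np.repeat(probs, n_plots, axis=0))
        else:
            p = net.root_probs(a.name)
            codes[a.name] = rng.choice(len(p), size=n_plots, p=p)
    p = net.root_probs(SPATIAL_NODE)
    codes[SPATIAL_NODE] = rng.choice(len(p), size=n_plots, p=p)

    for sp in net.species:  # species listed in topological order by construction
        probs = net.conditional_probs(sp, {q: codes[q] for q in net.parents[sp]})
        codes[sp] = draw(probs)

    df = pd.DataFrame({"plot_id": [f"plot{i + 1:05d}" for i in range(n_plots)]})
    block = codes[SPATIAL_NODE]
    bi, bj = block // _SPAC_SIDE, block % _SPAC_SIDE
    lon0, lat0 = -9.5, 36.0
    df["lon"] = lon0 + (bi + rng.random(n_plots)) * (12.0 / _SPAC_SIDE)
    df["lat"] = lat0 + (bj + rng.random(n_plots)) * (8.0 / _SPAC_SIDE)
    for a in net.env_attributes:
        if a.name in ordered_env:
            lo, hi = _CONT_BANDS.get(a.name, (0.0, 1.0))
            width = (hi - lo) / _N_QUART
            df[a.name] = lo + (codes[a.name] + rng.random(n_plots)) * width
        else:
            lv = net.levels[a.name]
            df[a.name] = [lv[c] for c in codes[a.name]]
    for sp in net.species:
        lv = net.levels[sp]
        df[sp] = [lv[c] for c in codes[sp]]

    return PlotTable(df=df, species=list(net.species),
                     env_attributes=list(net.env_attributes), scale=net.scale)


def structure_recovery_metrics(truth: GroundTruthNetwork, inferred) -> dict[str, float]:
    """Arc precision/recall (undirected, significant arcs) and directed SHD.

    ``inferred`` is a ConsensusNetwork.  Precision and recall compare the
    significant inferred arcs with the true arcs as undirected pairs; the
    structural Hamming distance additionally counts orientation errors among
    the shared pairs (direction-ambiguous inferred arcs count as wrongly
    oriented unless the true arc is matched either way).
    """
    if set(inferred.nodes) != set(truth.nodes):
        raise ValueError("node sets differ between truth and inferred network")
    true_dir = truth.arc_set
    true_und = {frozenset(a) for a in true_dir}
    inf_arcs = [a for a in inferred.arcs if a.significant]
    inf_und = {frozenset((a.parent, a.child)) for a in inf_arcs}
    tp = len(inf_und & true_und)
    precision = tp / len(inf_und) if inf_und else (1.0 if not true_und else 0.0)
    recall = tp / len(true_und) if true_und else 1.0
    shd = len(inf_und ^ true_und)
    for a in inf_arcs:
        if frozenset((a.parent, a.child)) in true_und:
            if not a.oriented or (a.parent, a.child) not in true_dir:
                shd += 1
    return {"arc_precision": precision, "arc_recall": recall, "shd": float(shd)}
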
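"""Constrained multinomial Bayesian-network structure learning and consensus.

The learner is score-based greedy hill climbing over directed acyclic
graphs: starting from the empty graph (plus random restarts), it repeatedly
applies the single arc addition, deletion or reversal that most improves the
network score, subject to acyclicity and a constraint blacklist, until no
move improves.  The default score is BIC for multinomial networks,

    score(G) = sum_v [ loglik(v | parents_v) - (log n)/2 * (r_v - 1) * q_v ]

with r_v the child's level count and q_v the number of parent
configurations.  The score decomposes over families, so move deltas touch
only the families they change and family scores are cached per dataset.

Robustness comes from learning the structure many times on nonparametric
bootstrap resamples of the plots: an arc's *strength* is the fraction of
runs containing it in either direction, its *direction support* the
fraction of those runs agreeing on the orientation.  Arcs whose majority
orientation does not exceed the direction cut-off are kept as
direction-ambiguous and feed no parent set.  Significance is decided by a
data-driven threshold on the strength distribution: the cut minimising the
L1 distance between the empirical CDF of strengths and the ideal two-point
CDF that sends every arc at or below the cut to 0 and every arc above it
to 1.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .plot_data import SPATIAL_NODE, PlotTable, to_categorical

logger = logging.getLogger(__name__)

__all__ = [
    "ConstraintSet",
    "Arc",
    "ConsensusNetwork",
    "learn_structure",
    "consensus_network",
    "significance_threshold",
    "parent_sets",
    "default_constraints",
]


@dataclass(frozen=True)
class ConstraintSet:
    """Forbidden directed arcs.

    Derived from two rules: species may not influence environmental
    variables, and exogenous environmental variables (warmest-quarter
    temperature, annual precipitation, geology, orientation — and the
    spatial block) accept no parents at all.
    """

    blacklist: frozenset[tuple[str, str]]

    def forbids(self, parent: str, child: str) -> bool:
        return (parent, child) in self.blacklist


def default_constraints(species: Sequence[str], env_nodes: Sequence[str],
                        no_parent_nodes: Iterable[str]) -> ConstraintSet:
    """Blacklist from the structural rules, over explicit node lists."""
    bl: set[tuple[str, str]] = set()
    all_nodes = list(species) + list(env_nodes)
    for sp in species:
        for e in env_nodes:
            bl.add((sp, e))
    for tgt in no_parent_nodes:
        for n in all_nodes:
            if n != tgt:
                bl.add((n, tgt))
    return ConstraintSet(frozenset(bl))


def constraints_for_table(table: PlotTable) -> ConstraintSet:
    env_nodes = [a.name for a in table.env_attributes] + [SPATIAL_NODE]
    no_parent = [a.name for a in table.env_attributes if not a.may_have_parents]
    no_parent.append(SPATIAL_NODE)
    return default_constraints(table.species, env_nodes, no_parent)


# ---------------------------------------------------------------------------
# Data encoding and family scores

def encode_categorical(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Integer-code an all-categorical frame; returns (data, cardinalities, names)."""
    cols, cards, names = [], [], []
    for c in df.columns:
        codes, uniques = pd.factorize(df[c].astype(str), sort=True)
        cols.append(codes.astype(np.int64))
        cards.append(len(uniques))
        names.append(c)
    return np.column_stack(cols), np.asarray(cards), names


class _Scorer:
    """Cached decomposable family scores on one encoded dataset."""

    def __init__(self, data: np.ndarray, cards: np.ndarray, score: str = "bic"):
        if score not in ("bic", "bde"):
            raise ValueError(f"unknown score {score!r}")
        self.data = data
        self.cards = cards
        self.n = data.shape[0]
        self.score = score
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def family(self, child: int, parents: tuple[int, ...]) -> float:
        key = (child, parents)
        got = self._cache.get(key)
        if got is not None:
            return got
        r = int(self.cards[child])
        q = 1
        idx = np.zeros(self.n, dtype=np.int64)
        for p in parents:  # parent configuration is the major index, child the minor
            idx = idx * self.cards[p] + self.data[:, p]
            q *= int(self.cards[p])
        idx = idx * r + self.data[:, child]
        counts = np.bincount(idx, minlength=r * q).reshape(q, r)
        row_tot = counts.sum(axis=1)
        if self.score == "bic":
            nz = counts > 0
            ll = float((counts[nz] * np.log(counts[nz])).sum())
            occ = row_tot > 0
            ll -= float((row_tot[occ] * np.log(row_tot[occ])).sum())
            val = ll - 0.5 * np.log(self.n) * (r - 1) * q
        else:  # BDeu with equivalent sample size 1
            from scipy.special import gammaln
            a = 1.0 / (r * q)
            val = float(
                (gammaln(counts + a) - gammaln(a)).sum()
                + (gammaln(1.0 / q) - gammaln(row_tot + 1.0 / q)).sum())
        self._cache[key] = val
        return val


# ---------------------------------------------------------------------------
# Hill climbing

class _HillClimber:
    def __init__(self, scorer: _Scorer, p: int, forbidden: np.ndarray):
        self.scorer = scorer
        self.p = p
        self.forbidden = forbidden  # boolean (p, p), forbidden[u, v] bans u -> v

    def _creates_cycle(self, pa: list[set[int]], u: int, v: int) -> bool:
        # would u -> v close a cycle?  check for a directed path v ~> u
        stack, seen = [u], {u}
        while stack:
            x = stack.pop()
            for w in pa[x]:
                if w == v:
                    return True
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return False

    def climb(self, start: list[set[int]]) -> tuple[list[set[int]], float]:
        sc = self.scorer
        pa = [set(s) for s in start]
        fam = [sc.family(v, tuple(sorted(pa[v]))) for v in range(self.p)]
        while True:
            best_delta, best_move = 1e-9, None
            for u in range(self.p):
                for v in range(self.p):
                    if u == v:
                        continue
                    if u in pa[v]:
                        # delete u -> v
                        new = tuple(sorted(pa[v] - {u}))
                        d = sc.family(v, new) - fam[v]
                        if d > best_delta:
                            best_delta, best_move = d, ("del", u, v)
                        # reverse: u -> v becomes v -> u
                        if not self.forbidden[v, u] and \
                                not self._creates_cycle_without(pa, u, v):
                            d2 = (sc.family(v, new) - fam[v]
                                  + sc.family(u, tuple(sorted(pa[u] | {v}))) - fam[u])
                            if d2 > best_delta:
                                best_delta, best_move = d2, ("rev", u, v)
                    else:
                        if self.forbidden[u, v] or self._creates_cycle(pa, u, v):
                            continue
                        d = sc.family(v, tuple(sorted(pa[v] | {u}))) - fam[v]
                        if d > best_delta:
                            best_delta, best_move = d, ("add", u, v)
            if best_move is None:
                break
            kind, u, v = best_move
            if kind == "add":
                pa[v].add(u)
            elif kind == "del":
                pa[v].discard(u)
            else:
                pa[v].discard(u)
                pa[u].add(v)
                fam[u] = sc.family(u, tuple(sorted(pa[u])))
            fam[v] = sc.family(v, tuple(sorted(pa[v])))
        total = sum(fam)
        return pa, total

    def _creates_cycle_without(self, pa: list[set[int]], u: int, v: int) -> bool:
        # would v -> u close a cycle once u -> v is removed?
        pa[v].discard(u)
        try:
            return self._creates_cycle(pa, v, u)
        finally:
            pa[v].add(u)


def _random_start(rng: np.random.Generator, p: int, forbidden: np.ndarray,
                  density: float = 1.0) -> list[set[int]]:
    """A random admissible DAG: arcs added in random order, skipping cycles."""
    pa: list[set[int]] = [set() for _ in range(p)]
    pairs = [(u, v) for u in range(p) for v in range(p) if u != v and not forbidden[u, v]]
    rng.shuffle(pairs)
    hc = _HillClimber(None, p, forbidden)  # only for cycle checks
    target = int(density * p)
    added = 0
    for u, v in pairs:
        if added >= target:
            break
        if not hc._creates_cycle(pa, u, v):
            pa[v].add(u)
            added += 1
    return pa


def _prepare(table_cat: pd.DataFrame, constraints: ConstraintSet
             ) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray]:
    if len(table_cat) == 0:
        raise ValueError("empty table")
    data, cards, names = encode_categorical(table_cat)
    keep = cards > 1
    for name, ok in zip(names, keep):
        if not ok:
            warnings.warn(f"variable {name!r} has a single observed level; excluded")
            logger.warning("excluding single-level variable %s", name)
    data, cards = data[:, keep], cards[keep]
    names = [n for n, ok in zip(names, keep) if ok]
    p = len(names)
    idx = {n: i for i, n in enumerate(names)}
    forbidden = np.zeros((p, p), dtype=bool)
    for (a, b) in constraints.blacklist:
        if a in idx and b in idx:
            forbidden[idx[a], idx[b]] = True
    return data, cards, names, forbidden


def learn_structure(table_cat: pd.DataFrame, constraints: ConstraintSet,
                    score: str = "bic", seed: int = 0, restarts: int = 5
                    ) -> set[tuple[str, str]]:
    """One structure-learning run; returns the learned directed arc set.

    Hill climbing starts once from the empty graph and ``restarts - 1``
    times from random admissible DAGs; the best-scoring local optimum wins.
    Ties break toward the graph found first (empty start first, then restart
    order), which makes the result deterministic under a fixed seed.
    """
    arcs, _ = _learn(table_cat, constraints, score, seed, restarts)
    return arcs


def _learn(table_cat: pd.DataFrame, constraints: ConstraintSet,
           score: str, seed: int, restarts: int
           ) -> tuple[set[tuple[str, str]], float]:
    data, cards, names, forbidden = _prepare(table_cat, constraints)
    p = len(names)
    scorer = _Scorer(data, cards, score)
    hc = _HillClimber(scorer, p, forbidden)
    rng = np.random.default_rng(seed)
    best_pa, best_score = hc.climb([set() for _ in range(p)])
    for _ in range(max(0, restarts - 1)):
        pa, s = hc.climb(_random_start(rng, p, forbidden))
        if s > best_score + 1e-12:
            best_pa, best_score = pa, s
    arcs = {(names[u], names[v]) for v in range(p) for u in best_pa[v]}
    return arcs, best_score


# ---------------------------------------------------------------------------
# Consensus over bootstrap resamples

@dataclass(frozen=True)
class Arc:
    """A consensus arc with bootstrap support."""

    parent: str
    child: str
    strength: float          # fraction of runs containing the arc, either direction
    direction_support: float  # fraction of containing runs with this orientation
    significant: bool = False
    oriented: bool = True     # False: support <= cutoff both ways (no parent-set use)

    def as_dict(self) -> dict:
        return {"parent": self.parent, "child": self.child, "strength": self.strength,
                "direction_support": self.direction_support,
                "significant": self.significant, "oriented": self.oriented}


@dataclass
class ConsensusNetwork:
    nodes: list[str]
    arcs: list[Arc]
    threshold: float
    runs: int
    seed: int

    def to_json(self, path: str | Path) -> None:
        obj = {"nodes": self.nodes, "arcs": [a.as_dict() for a in self.arcs],
               "threshold": self.threshold, "runs": self.runs, "seed": self.seed}
        Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ConsensusNetwork":
        obj = json.loads(Path(path).read_text())
        return cls(nodes=obj["nodes"], arcs=[Arc(**d) for d in obj["arcs"]],
                   threshold=obj["threshold"], runs=obj["runs"], seed=obj["seed"])


def significance_threshold(strengths: Sequence[float]) -> float:
    """Data-driven significance cut on arc strengths.

    For each candidate threshold t (the observed strengths and the midpoints
    between consecutive distinct values), idealise the strength distribution
    by sending every strength <= t to 0 and every strength > t to 1, and
    measure the L1 distance between the empirical CDF and the idealised CDF
    over [0, 1].  The returned threshold minimises that distance; arcs with
    strength strictly above it are significant.
    """
    s = np.sort(np.asarray(strengths, dtype=float))
    if s.size == 0:
        raise ValueError("empty strength list")
    if ((s < 0) | (s > 1)).any():
        raise ValueError("strengths must lie in [0, 1]")
    uniq = np.unique(s)
    candidates = [0.0] + list(uniq) + [float(m) for m in (uniq[:-1] + uniq[1:]) / 2]
    # knots of both step functions
    grid = np.unique(np.concatenate([[0.0, 1.0], s]))
    n = s.size

    def l1(t: float) -> float:
        p0 = float((s <= t).sum()) / n  # idealised mass at 0
        tot = 0.0
        for a, b in zip(grid[:-1], grid[1:]):
            f_emp = float((s <= a).sum()) / n  # ECDF on [a, b)
            f_ideal = p0 if a < 1.0 else 1.0
            tot += abs(f_emp - f_ideal) * (b - a)
        return tot

    best_t, best_d = None, np.inf
    for t in sorted(candidates):
        d = l1(t)
        if d < best_d - 1e-12:
            best_t, best_d = float(t), d
    return best_t


def consensus_network(table: PlotTable, constraints: ConstraintSet | None = None,
                      runs: int = 500, direction_cutoff: float = 0.5,
                      score: str = "bic", seed: int = 0, restarts: int = 5,
                      resample: bool = True) -> ConsensusNetwork:
    """Bootstrap-consensus network over repeated structure learning.

    Each run learns a structure on a nonparametric bootstrap resample of the
    plots (``resample=False`` falls back to restart-only replication on the
    original data).  Per undirected pair: strength = fraction of runs
    containing the arc; the majority orientation is kept only when its
    support exceeds ``direction_cutoff``.  The oriented significant arc set
    is kept acyclic by demoting, in increasing strength order, any oriented
    arc that closes a cycle to direction-ambiguous.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    if constraints is None:
        constraints = constraints_for_table(table)
    cat = to_categorical(table)
    rng = np.random.default_rng(seed)
    n = len(cat)
    pair_counts: dict[frozenset, int] = {}
    dir_counts: dict[tuple[str, str], int] = {}
    for r in range(runs):
        sub = cat.iloc[rng.integers(0, n, size=n)] if resample else cat
        run_seed = int(rng.integers(0, 2**31 - 1))
        arcs = learn_structure(sub, constraints, score=score, seed=run_seed,
                               restarts=restarts)
        for (u, v) in arcs:
            key = frozenset((u, v))
            pair_counts[key] = pair_counts.get(key, 0) + 1
            dir_counts[(u, v)] = dir_counts.get((u, v), 0) + 1

    arcs_out: list[Arc] = []
    for key, cnt in pair_counts.items():
        u, v = sorted(key)
        c_uv = dir_counts.get((u, v), 0)
        c_vu = dir_counts.get((v, u), 0)
        if c_uv >= c_vu:
            parent, child, c_dir = u, v, c_uv
        else:
            parent, child, c_dir = v, u, c_vu
        support = c_dir / cnt
        arcs_out.append(Arc(parent=parent, child=child, strength=cnt / runs,
                            direction_support=support,
                            oriented=support > direction_cutoff))

    thr = significance_threshold([a.strength for a in arcs_out]) if arcs_out else 0.0
    arcs_out = [Arc(a.parent, a.child, a.strength, a.direction_support,
                    significant=a.strength > thr, oriented=a.oriented)
                for a in arcs_out]

    # enforce acyclicity of the oriented significant subgraph
    arcs_out.sort(key=lambda a: (-a.strength, a.parent, a.child))
    pa: dict[str, set[str]] = {}

    def reaches(src: str, dst: str) -> bool:
        stack, seen = [src], {src}
        while stack:
            x = stack.pop()
            for w in pa.get(x, ()):  # walk parent-ward
                if w == dst:
                    return True
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return False

    final: list[Arc] = []
    for a in arcs_out:
        if a.oriented and a.significant and reaches(a.parent, a.child):
            logger.warning("demoting arc %s->%s to direction-ambiguous (cycle)",
                           a.parent, a.child)
            a = Arc(a.parent, a.child, a.strength, a.direction_support,
                    significant=a.significant, oriented=False)
        if a.oriented and a.significant:
            pa.setdefault(a.child, set()).add(a.parent)
        final.append(a)
    final.sort(key=lambda a: (a.parent, a.child))
    return ConsensusNetwork(nodes=list(cat.columns), arcs=final,
                            threshold=thr, runs=runs, seed=seed)


def parent_sets(net: ConsensusNetwork) -> dict[str, list[str]]:
    """Significant, direction-resolved parents per node."""
    out: dict[str, list[str]] = {n: [] for n in net.nodes}
    for a in net.arcs:
        if a.significant and a.oriented:
            out[a.child].append(a.parent)
    for v in out.values():
        v.sort()
    return out
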
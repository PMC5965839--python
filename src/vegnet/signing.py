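"""Signing significant links with the Jonckheere-Terpstra trend test.

Each significant parent -> child link whose parent has an ordered domain is
tested for a monotone trend of the child's cover class across the parent's
ordered levels.  The statistic counts concordant cross-group pairs with the
mid-rank tie convention,

    JT = sum_{i<j} #{(x in G_i, y in G_j): y > x} + 0.5 * #{ties},

standardised by its null mean (N^2 - sum n_i^2)/4 and the tie-corrected
null variance.  For N <= 10 the two-sided p-value comes from exhaustive
permutation enumeration instead of the normal approximation.  The sign is
read post hoc from z: "+" for an increasing trend at p < alpha, "-" for a
decreasing one, "unsigned" otherwise or when the parent is
unordered-categorical (geology, land use, orientation, growth form,
spatial block).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .network import ConsensusNetwork
from .plot_data import PlotTable, node_order_info, to_categorical

__all__ = ["SignedLink", "jonckheere_test", "assign_signs", "EXACT_N_MAX"]

EXACT_N_MAX = 10


@dataclass(frozen=True)
class SignedLink:
    parent: str
    child: str
    strength: float
    direction_support: float
    jt: float
    z: float
    p_value: float
    sign: str  # "+", "-", "unsigned"

    def as_dict(self) -> dict:
        return {"parent": self.parent, "child": self.child, "strength": self.strength,
                "direction_support": self.direction_support, "jt": self.jt,
                "z": self.z, "p": self.p_value, "sign": self.sign}


def _jt_statistic(groups: Sequence[np.ndarray]) -> float:
    jt = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            gi = groups[i][:, None]
            gj = groups[j][None, :]
            jt += float((gj > gi).sum()) + 0.5 * float((gj == gi).sum())
    return jt


def _null_moments(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    ns = np.array([len(g) for g in groups], dtype=float)
    n = ns.sum()
    pooled = np.concatenate(groups)
    _, tie = np.unique(pooled, return_counts=True)
    tie = tie.astype(float)
    mean = (n * n - (ns ** 2).sum()) / 4.0
    var = (n * (n - 1) * (2 * n + 5)
           - (ns * (ns - 1) * (2 * ns + 5)).sum()
           - (tie * (tie - 1) * (2 * tie + 5)).sum()) / 72.0
    if n > 2:
        var += ((ns * (ns - 1) * (ns - 2)).sum() * (tie * (tie - 1) * (tie - 2)).sum()
                / (36.0 * n * (n - 1) * (n - 2)))
    var += ((ns * (ns - 1)).sum() * (tie * (tie - 1)).sum()) / (8.0 * n * (n - 1))
    return mean, var


def _exact_two_sided(groups: Sequence[np.ndarray], jt_obs: float, mean: float) -> float:
    """Exhaustive permutation p-value: P(|JT - mean| >= |jt_obs - mean|)."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    n = len(pooled)
    idx = list(range(n))
    total = 0
    extreme = 0
    dev = abs(jt_obs - mean) - 1e-9

    def rec(remaining: tuple[int, ...], gi: int, acc: list[np.ndarray]):
        nonlocal total, extreme
        if gi == len(sizes) - 1:
            split = acc + [pooled[list(remaining)]]
            jt = _jt_statistic(split)
            total += 1
            if abs(jt - mean) >= dev:
                extreme += 1
            return
        for pick in itertools.combinations(remaining, sizes[gi]):
            rest = tuple(x for x in remaining if x not in pick)
            rec(rest, gi + 1, acc + [pooled[list(pick)]])

    rec(tuple(idx), 0, [])
    assert total == _multinomial(sizes)
    return extreme / total


def _multinomial(sizes: Sequence[int]) -> int:
    n = sum(sizes)
    out = 1
    for s in sizes:
        out *= comb(n, s)
        n -= s
    return out


def jonckheere_test(groups: Sequence[Sequence[float]]) -> tuple[float, float, float]:
    """Jonckheere-Terpstra trend test over ordered groups.

    Returns ``(jt, z, p)`` with a two-sided p-value; exact by enumeration
    for pooled N <= EXACT_N_MAX, normal approximation otherwise.
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty ordered groups")
    pooled = np.concatenate(groups)
    jt = _jt_statistic(groups)
    if np.all(pooled == pooled[0]):
        return jt, 0.0, 1.0
    mean, var = _null_moments(groups)
    z = (jt - mean) / np.sqrt(var) if var > 0 else 0.0
    if len(pooled) <= EXACT_N_MAX:
        p = _exact_two_sided(groups, jt, mean)
    else:
        p = 2.0 * float(norm.sf(abs(z)))
        p = min(p, 1.0)
    return jt, float(z), float(p)


def assign_signs(net: ConsensusNetwork, table: PlotTable, alpha: float = 0.05,
                 group_by: str = "parent") -> list[SignedLink]:
    """Sign every significant oriented link of a consensus network.

    ``group_by="parent"`` (default) groups the child's values by the
    parent's ordered levels; ``"child"`` swaps the roles.  Links whose
    grouping variable has no natural order are reported unsigned.
    """
    if group_by not in ("parent", "child"):
        raise ValueError("group_by must be 'parent' or 'child'")
    cat = to_categorical(table)
    order = node_order_info(table)

    def rank_codes(node: str) -> np.ndarray:
        levels = order[node]
        col = cat[node].astype(str)
        if levels is not None:
            lut = {lv: i for i, lv in enumerate(levels)}
            return col.map(lut).to_numpy(dtype=float)
        codes, _ = col.factorize(sort=True)
        return codes.astype(float)

    out: list[SignedLink] = []
    for arc in net.arcs:
        if not (arc.significant and arc.oriented):
            continue
        grp_node, val_node = ((arc.parent, arc.child) if group_by == "parent"
                              else (arc.child, arc.parent))
        if order[grp_node] is None or order[val_node] is None:
            out.append(SignedLink(arc.parent, arc.child, arc.strength,
                                  arc.direction_support, np.nan, np.nan, np.nan,
                                  "unsigned"))
            continue
        g = rank_codes(grp_node)
        v = rank_codes(val_node)
        groups = [v[g == lv] for lv in np.unique(g)]
        groups = [grp for grp in groups if len(grp) > 0]
        if len(groups) < 2:
            out.append(SignedLink(arc.parent, arc.child, arc.strength,
                                  arc.direction_support, np.nan, 0.0, 1.0, "unsigned"))
            continue
        jt, z, p = jonckheere_test(groups)
        if p < alpha and z > 0:
            sign = "+"
        elif p < alpha and z < 0:
            sign = "-"
        else:
            sign = "unsigned"
        out.append(SignedLink(arc.parent, arc.child, arc.strength,
                              arc.direction_support, jt, z, p, sign))
    return out
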
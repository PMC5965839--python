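"""Syndrome composition of species-species links and chi-square analyses.

Mediterranean woody species fall into two trait syndromes — Tertiary (T),
ancient sclerophyll lineages, and Quaternary (Q), recent drought-adapted
lineages — plus species with no assigned syndrome, which are excluded.
Each signed species-species link is classified by the directed syndrome
pair (parent syndrome first: TQ = T parent, Q child), and a chi-square
goodness-of-fit test asks whether links concentrate within syndromes more
than a null expectation.  Because the appropriate null is a modelling
choice, both a uniform null and a syndrome-frequency null (directed-pair
probabilities from the marginal syndrome frequencies, with or without
replacement) are available and reported side by side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .signing import SignedLink

__all__ = ["ContingencyResult", "classify_links", "chi_square_gof",
           "syndrome_null_proportions", "PAIR_CLASSES"]

PAIR_CLASSES = ("TT", "QQ", "TQ", "QT")


@dataclass(frozen=True)
class ContingencyResult:
    observed: dict[str, int]
    expected: dict[str, float]
    chi2: float
    df: int
    p: float

    def as_dict(self) -> dict:
        return {"observed": self.observed, "expected": self.expected,
                "chi2": self.chi2, "df": self.df, "p": self.p}


def classify_links(links: Iterable[SignedLink], syndromes: Mapping[str, str],
                   species: Sequence[str] | None = None,
                   positive_only: bool = False) -> dict[str, int]:
    """Count species-species links by directed syndrome-pair class.

    Links touching a species without a T/Q syndrome are excluded; with
    ``positive_only`` only "+"-signed links are counted.  Returns the four
    directed classes plus the same/different totals.
    """
    species_set = set(species) if species is not None else {
        s for s, v in syndromes.items()}
    counts = {k: 0 for k in PAIR_CLASSES}
    for link in links:
        if link.parent not in species_set or link.child not in species_set:
            continue  # not a species-species link
        sp_par = syndromes.get(link.parent, "none")
        sp_chi = syndromes.get(link.child, "none")
        if sp_par not in ("T", "Q") or sp_chi not in ("T", "Q"):
            continue
        if positive_only and link.sign != "+":
            continue
        counts[sp_par + sp_chi] += 1
    counts["same"] = counts["TT"] + counts["QQ"]
    counts["different"] = counts["TQ"] + counts["QT"]
    return counts


def chi_square_gof(observed: Mapping[str, int] | Sequence[int],
                   expected_proportions: Mapping[str, float] | Sequence[float]
                   ) -> ContingencyResult:
    """Pearson chi-square goodness of fit against fixed class proportions."""
    if isinstance(observed, Mapping):
        keys = list(observed.keys())
        obs = np.array([observed[k] for k in keys], dtype=float)
        props = np.array([expected_proportions[k] for k in keys], dtype=float)
    else:
        obs = np.asarray(observed, dtype=float)
        props = np.asarray(expected_proportions, dtype=float)
        keys = [str(i) for i in range(len(obs))]
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("expected proportions must sum to 1")
    n = obs.sum()
    if n < 1:
        raise ValueError("need at least one observation")
    exp = n * props
    if (exp == 0).any():
        raise ValueError("expected count of zero")
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = len(obs) - 1
    p = float(stats.chi2.sf(chi2, df))
    return ContingencyResult(observed={k: int(o) for k, o in zip(keys, obs)},
                             expected={k: float(e) for k, e in zip(keys, exp)},
                             chi2=chi2, df=df, p=p)


def syndrome_null_proportions(syndromes: Mapping[str, str],
                              mode: str = "frequency") -> dict[str, float]:
    """Null proportions of the four directed pair classes.

    ``uniform``: 1/4 each.  ``frequency``: products of the marginal T/Q
    frequencies (ordered pairs with replacement).  ``frequency_no_replacement``:
    the same but forbidding self-pairs, with n(n-1) denominators.
    """
    labelled = [v for v in syndromes.values() if v in ("T", "Q")]
    if len(labelled) < 2:
        raise ValueError("need at least two syndrome-labelled species")
    if mode == "uniform":
        return {k: 0.25 for k in PAIR_CLASSES}
    n_t = labelled.count("T")
    n_q = labelled.count("Q")
    n = n_t + n_q
    if mode == "frequency":
        f = {"T": n_t / n, "Q": n_q / n}
        return {a + b: f[a] * f[b] for a in "TQ" for b in "TQ"}
    if mode == "frequency_no_replacement":
        denom = n * (n - 1)
        return {"TT": n_t * (n_t - 1) / denom, "QQ": n_q * (n_q - 1) / denom,
                "TQ": n_t * n_q / denom, "QT": n_q * n_t / denom}
    raise ValueError(f"unknown null mode {mode!r}")
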
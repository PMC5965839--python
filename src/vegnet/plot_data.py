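"""Relevé (vegetation-plot) tables: cover classes, environmental attributes, I/O.

A plot table holds one row per phytosociological plot with the plot's
coordinates (the centroid of its 10-km grid cell), its environmental
attributes, and the cover of every study species recorded on an ordered
cover-class scale.  Species abundance is categorical for network inference
and numeric (class midpoint, percent) for the distribution models, so the
cover scale is the bridge between the two representations and travels with
the table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CoverClass",
    "CoverScale",
    "DEFAULT_COVER_SCALE",
    "EnvAttribute",
    "DEFAULT_ENV_ATTRIBUTES",
    "PlotTable",
    "discretize_cover",
    "assign_dominant_category",
    "classify_growth_form",
    "read_plot_table",
    "write_plot_table",
    "read_syndrome_map",
    "write_syndrome_map",
    "to_categorical",
]


class PlotDataError(ValueError):
    """Domain or parse error in plot-table handling."""


@dataclass(frozen=True)
class CoverClass:
    """One ordered band of percent ground cover.

    The interval convention is half-open ``(lower, upper]`` except for the
    absence class, which is the single point 0.  ``midpoint_pct`` is the
    numeric abundance used wherever a percent is needed.
    """

    label: str
    lower_pct: float
    upper_pct: float
    midpoint_pct: float

    def __post_init__(self) -> None:
        if not (0 <= self.lower_pct <= self.upper_pct <= 100):
            raise PlotDataError(f"cover class {self.label!r}: bounds outside [0, 100]")
        if self.lower_pct == self.upper_pct:  # the absence class
            if self.midpoint_pct != self.lower_pct:
                raise PlotDataError(f"point class {self.label!r} must have midpoint == bound")
        elif not (self.lower_pct < self.midpoint_pct <= self.upper_pct):
            raise PlotDataError(f"cover class {self.label!r}: midpoint outside (lower, upper]")


class CoverScale:
    """A totally ordered, non-overlapping cover-class scale covering [0, 100]."""

    def __init__(self, classes: Sequence[CoverClass]):
        classes = sorted(classes, key=lambda c: c.upper_pct)
        if not classes:
            raise PlotDataError("empty cover scale")
        if classes[0].lower_pct != 0 or classes[0].upper_pct != 0:
            raise PlotDataError("scale must start with a point class at 0 ('absent')")
        prev = 0.0
        for c in classes[1:]:
            if c.lower_pct != prev:
                raise PlotDataError(f"gap or overlap before class {c.label!r}")
            prev = c.upper_pct
        if prev != 100:
            raise PlotDataError("scale must cover up to 100")
        if len({c.label for c in classes}) != len(classes):
            raise PlotDataError("duplicate class labels")
        self.classes: tuple[CoverClass, ...] = tuple(classes)
        self._by_label = {c.label: i for i, c in enumerate(self.classes)}

    def __len__(self) -> int:
        return len(self.classes)

    def __iter__(self):
        return iter(self.classes)

    def __eq__(self, other) -> bool:
        return isinstance(other, CoverScale) and self.classes == other.classes

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.classes]

    def rank(self, label: str) -> int:
        try:
            return self._by_label[label]
        except KeyError:
            raise PlotDataError(f"unknown cover-class label {label!r}") from None

    def midpoint(self, label: str) -> float:
        return self.classes[self.rank(label)].midpoint_pct

    def head(self, n_levels: int) -> "CoverScale":
        """Truncated scale keeping the lowest ``n_levels`` classes.

        The last kept class is stretched to cover up to 100 so the result is
        again a valid scale (used by the community simulator, where species
        rarely occupy the highest cover bands).
        """
        if not (2 <= n_levels <= len(self.classes)):
            raise PlotDataError("n_levels must be in [2, len(scale)]")
        kept = list(self.classes[: n_levels - 1])
        last = self.classes[n_levels - 1]
        kept.append(CoverClass(last.label, last.lower_pct, 100.0, last.midpoint_pct))
        return CoverScale(kept)

    def to_json(self) -> list[dict]:
        return [
            {"label": c.label, "lower_pct": c.lower_pct, "upper_pct": c.upper_pct,
             "midpoint_pct": c.midpoint_pct}
            for c in self.classes
        ]

    @classmethod
    def from_json(cls, obj: Iterable[Mapping]) -> "CoverScale":
        return cls([CoverClass(d["label"], d["lower_pct"], d["upper_pct"], d["midpoint_pct"])
                    for d in obj])


#: Braun-Blanquet-style default scale.
DEFAULT_COVER_SCALE = CoverScale([
    CoverClass("0", 0, 0, 0),
    CoverClass("+", 0, 1, 0.5),
    CoverClass("1", 1, 5, 3),
    CoverClass("2", 5, 25, 15),
    CoverClass("3", 25, 50, 37.5),
    CoverClass("4", 50, 75, 62.5),
    CoverClass("5", 75, 100, 87.5),
])


def discretize_cover(percent: float, scale: CoverScale = DEFAULT_COVER_SCALE) -> CoverClass:
    """Map a percent cover to its cover class; 0 maps to the absence class."""
    if not np.isfinite(percent) or percent < 0 or percent > 100:
        raise PlotDataError(f"percent cover {percent!r} outside [0, 100]")
    if percent == 0:
        return scale.classes[0]
    for c in scale.classes[1:]:
        if c.lower_pct < percent <= c.upper_pct:
            return c
    raise PlotDataError(f"no class contains {percent}")  # unreachable on a valid scale


def assign_dominant_category(area_fractions: Mapping[str, float],
                             threshold: float = 0.70) -> str:
    """Dominant-category rule for grid-cell attributes (geology, land use).

    Returns the category covering at least ``threshold`` of the cell, or
    ``"mix"`` when none does.
    """
    if not area_fractions:
        raise PlotDataError("empty category mapping")
    fracs = dict(area_fractions)
    if any(v < 0 for v in fracs.values()):
        raise PlotDataError("negative area fraction")
    if sum(fracs.values()) > 1 + 1e-9:
        raise PlotDataError("area fractions sum above 1")
    best = max(fracs, key=lambda k: fracs[k])
    return best if fracs[best] >= threshold else "mix"


def classify_growth_form(tree_cover_pct: float) -> str:
    """Dominant growth form from percent tree cover: tree >50, shrub <25, else mix."""
    if not np.isfinite(tree_cover_pct) or not (0 <= tree_cover_pct <= 100):
        raise PlotDataError(f"tree cover {tree_cover_pct!r} outside [0, 100]")
    if tree_cover_pct > 50:
        return "tree"
    if tree_cover_pct < 25:
        return "shrub"
    return "mix"


@dataclass(frozen=True)
class EnvAttribute:
    """Declaration of one environmental variable.

    ``kind`` governs how the variable enters the two model families
    (continuous in the additive models, quartile-binned in the network) and
    whether links from it can carry a sign.  ``may_have_parents`` is False for
    exogenous drivers (warmest-quarter temperature, annual precipitation,
    geology, orientation): no arc may point into them.
    """

    name: str
    kind: str  # "continuous" | "ordered-categorical" | "unordered-categorical"
    may_have_parents: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "ordered-categorical", "unordered-categorical"):
            raise PlotDataError(f"unknown attribute kind {self.kind!r}")


#: The study's environmental attributes (coordinates are carried separately).
DEFAULT_ENV_ATTRIBUTES = (
    EnvAttribute("Twarm", "continuous", may_have_parents=False),
    EnvAttribute("anualP", "continuous", may_have_parents=False),
    EnvAttribute("soil", "unordered-categorical", may_have_parents=False),
    EnvAttribute("orientation", "unordered-categorical", may_have_parents=False),
    EnvAttribute("landuse", "unordered-categorical", may_have_parents=True),
    EnvAttribute("dom_form", "unordered-categorical", may_have_parents=True),
)

#: Node name of the categorical spatial-location variable used in the network.
SPATIAL_NODE = "spac"


@dataclass
class PlotTable:
    """A plot-by-variable table.

    ``df`` has columns ``plot_id, lon, lat, <env attributes>, <species>``;
    species columns hold cover-class labels from ``scale``.
    """

    df: pd.DataFrame
    species: list[str]
    env_attributes: list[EnvAttribute] = field(
        default_factory=lambda: list(DEFAULT_ENV_ATTRIBUTES))
    scale: CoverScale = field(default_factory=lambda: DEFAULT_COVER_SCALE)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.df
        required = ["plot_id", "lon", "lat"] + [a.name for a in self.env_attributes] + self.species
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise PlotDataError(f"missing columns: {missing}")
        if df["plot_id"].duplicated().any():
            dup = df.loc[df["plot_id"].duplicated(), "plot_id"].iloc[0]
            raise PlotDataError(f"duplicate plot id {dup!r}")
        if not np.isfinite(df[["lon", "lat"]].to_numpy(float)).all():
            raise PlotDataError("non-finite coordinates")
        labels = set(self.scale.labels)
        for sp in self.species:
            bad = ~df[sp].astype(str).isin(labels)
            if bad.any():
                row = df.index[bad][0]
                raise PlotDataError(
                    f"row {row}, column {sp!r}: cover label {df.loc[row, sp]!r} "
                    f"not in scale {sorted(labels)}")

    @property
    def n_plots(self) -> int:
        return len(self.df)

    def env_attribute(self, name: str) -> EnvAttribute:
        for a in self.env_attributes:
            if a.name == name:
                return a
        raise PlotDataError(f"unknown environmental attribute {name!r}")

    def cover_midpoints(self, species: str | None = None) -> pd.DataFrame | pd.Series:
        """Numeric abundance: class midpoints, percent cover."""
        mids = {c.label: c.midpoint_pct for c in self.scale}
        if species is not None:
            return self.df[species].astype(str).map(mids)
        return self.df[self.species].astype(str).apply(lambda s: s.map(mids))

    def equals(self, other: "PlotTable") -> bool:
        return (self.species == other.species
                and self.scale == other.scale
                and self.env_attributes == other.env_attributes
                and self.df.reset_index(drop=True).equals(other.df.reset_index(drop=True)))


# ---------------------------------------------------------------------------
# I/O: CSV with a JSON sidecar declaring attribute kinds and the cover scale.

def _sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".meta.json")


def write_plot_table(table: PlotTable, path: str | Path) -> None:
    path = Path(path)
    table.df.to_csv(path, index=False)
    meta = {
        "species": table.species,
        "env_attributes": [
            {"name": a.name, "kind": a.kind, "may_have_parents": a.may_have_parents}
            for a in table.env_attributes
        ],
        "cover_scale": table.scale.to_json(),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_plot_table(path: str | Path) -> PlotTable:
    path = Path(path)
    meta_path = _sidecar_path(path)
    if not meta_path.exists():
        raise PlotDataError(f"missing sidecar config {meta_path}")
    meta = json.loads(meta_path.read_text())
    scale = CoverScale.from_json(meta["cover_scale"])
    env_attributes = [EnvAttribute(d["name"], d["kind"], d["may_have_parents"])
                      for d in meta["env_attributes"]]
    try:
        df = pd.read_csv(path, dtype={sp: str for sp in meta["species"]},
                         float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise PlotDataError(f"{path}: no records") from None
    if df.empty:
        raise PlotDataError(f"{path}: no records")
    return PlotTable(df=df, species=list(meta["species"]),
                     env_attributes=env_attributes, scale=scale)


def write_syndrome_map(syndromes: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"species": list(syndromes), "syndrome": [syndromes[s] for s in syndromes]}
    ).to_csv(path, index=False)


def read_syndrome_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    if set(df.columns) != {"species", "syndrome"}:
        raise PlotDataError("syndrome map must have columns species,syndrome")
    bad = ~df["syndrome"].isin(["T", "Q", "none"])
    if bad.any():
        raise PlotDataError(f"invalid syndrome value {df.loc[df.index[bad][0], 'syndrome']!r}")
    return dict(zip(df["species"], df["syndrome"]))


# ---------------------------------------------------------------------------
# Categorical view for the Bayesian network.

def quartile_bins(values: pd.Series, n_bins: int = 4) -> pd.Series:
    """Ordered equal-count bins ('q1'..'qk') of a continuous variable."""
    ranks = values.rank(method="first")
    binned = pd.qcut(ranks, n_bins, labels=[f"q{i + 1}" for i in range(n_bins)])
    return binned.astype(str)


def spatial_blocks(lon: pd.Series, lat: pd.Series, n_side: int = 3) -> pd.Series:
    """Unordered spatial-location classes: equal-count lon x lat blocks."""
    lon_b = pd.qcut(lon.rank(method="first"), n_side, labels=False)
    lat_b = pd.qcut(lat.rank(method="first"), n_side, labels=False)
    return pd.Series([f"b{i}{j}" for i, j in zip(lon_b, lat_b)], index=lon.index)


def to_categorical(table: PlotTable, n_bins: int = 4, n_side: int = 3) -> pd.DataFrame:
    """All-categorical view of a plot table for multinomial network learning.

    Continuous attributes become quartile classes, coordinates become one
    spatial-block variable, species stay on the cover-class scale (encoded by
    rank so the class order is preserved).
    """
    out = {}
    for a in table.env_attributes:
        col = table.df[a.name]
        out[a.name] = quartile_bins(col, n_bins) if a.kind == "continuous" else col.astype(str)
    out[SPATIAL_NODE] = spatial_blocks(table.df["lon"], table.df["lat"], n_side)
    for sp in table.species:
        out[sp] = table.df[sp].astype(str)
    return pd.DataFrame(out, index=table.df.index)


def node_order_info(table: PlotTable) -> dict[str, list[str] | None]:
    """Per BN node: its ordered level list, or None if the node is unordered.

    Species and quartile-binned continuous attributes are ordered; geology,
    land use, orientation, growth form and the spatial block are not.
    """
    info: dict[str, list[str] | None] = {}
    for a in table.env_attributes:
        if a.kind == "continuous":
            info[a.name] = [f"q{i + 1}" for i in range(4)]
        elif a.kind == "ordered-categorical":
            info[a.name] = sorted(table.df[a.name].astype(str).unique())
        else:
            info[a.name] = None
    info[SPATIAL_NODE] = None
    for sp in table.species:
        info[sp] = table.scale.labels
    return info
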
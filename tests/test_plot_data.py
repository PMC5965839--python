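"""Cover-class discretization, dominant-category rules, and table I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vegnet.plot_data import (
    DEFAULT_COVER_SCALE, PlotDataError, PlotTable, assign_dominant_category,
    classify_growth_form, discretize_cover, read_plot_table, read_syndrome_map,
    to_categorical, write_plot_table, write_syndrome_map,
)
from conftest import make_plot_table


@pytest.mark.parametrize("percent,label,midpoint", [
    (0, "0", 0.0),
    (0.3, "+", 0.5),
    (15, "2", 15.0),
    (5, "1", 3.0),       # boundary belongs to the lower class: (1, 5]
    (5.0001, "2", 15.0),
    (100, "5", 87.5),
])
def test_discretize_cover_maps_into_declared_bands(percent, label, midpoint):
    c = discretize_cover(percent)
    assert c.label == label
    assert c.midpoint_pct == midpoint


@pytest.mark.parametrize("bad", [-1, 100.5, float("nan")])
def test_discretize_cover_rejects_out_of_range(bad):
    with pytest.raises(PlotDataError):
        discretize_cover(bad)


@given(st.floats(min_value=0, max_value=100, allow_nan=False))
@settings(max_examples=200, deadline=None)
def test_discretize_cover_is_monotone(x):
    scale = DEFAULT_COVER_SCALE
    rank_x = scale.rank(discretize_cover(x).label)
    for y in (x / 2, x * 0.9, max(x - 1, 0)):
        assert scale.rank(discretize_cover(y).label) <= rank_x


@pytest.mark.parametrize("fracs,expected", [
    ({"forest": 0.80, "agri": 0.20}, "forest"),
    ({"forest": 0.50, "agri": 0.50}, "mix"),
    ({"forest": 0.70, "agri": 0.30}, "forest"),  # the >= 70% rule is inclusive
    ({"a": 0.69, "b": 0.31}, "mix"),
])
def test_dominant_category_rule(fracs, expected):
    assert assign_dominant_category(fracs) == expected


def test_dominant_category_rejects_bad_input():
    with pytest.raises(PlotDataError):
        assign_dominant_category({})
    with pytest.raises(PlotDataError):
        assign_dominant_category({"a": 0.9, "b": 0.3})


@given(st.dictionaries(st.sampled_from("abcd"), st.floats(0, 1), min_size=1),
       st.floats(0.5, 0.95))
@settings(max_examples=200, deadline=None)
def test_dominant_category_threshold_dichotomy(fracs, thr):
    total = sum(fracs.values())
    if total > 1:
        fracs = {k: v / total for k, v in fracs.items()}
    got = assign_dominant_category(fracs, thr)
    if got == "mix":
        assert all(v < thr for v in fracs.values())
    else:
        assert fracs[got] >= thr


@pytest.mark.parametrize("tree_cover,expected", [
    (60, "tree"), (10, "shrub"), (37, "mix"), (25, "mix"), (50, "mix"),
    (50.5, "tree"), (24.9, "shrub"),
])
def test_growth_form_rule(tree_cover, expected):
    assert classify_growth_form(tree_cover) == expected


def test_growth_form_rejects_out_of_range():
    with pytest.raises(PlotDataError):
        classify_growth_form(101)


@pytest.mark.parametrize("seed", range(5))
def test_plot_table_round_trip(tmp_path, seed):
    table = make_plot_table(n_plots=25, n_species=4, seed=seed)
    path = tmp_path / "t.csv"
    write_plot_table(table, path)
    back = read_plot_table(path)
    assert back.equals(table)


@given(st.integers(0, 10_000))
@settings(max_examples=100, deadline=None)
def test_plot_table_round_trip_randomized(tmp_path_factory, seed):
    table = make_plot_table(n_plots=8, n_species=2, seed=seed)
    path = tmp_path_factory.mktemp("io") / "t.csv"
    write_plot_table(table, path)
    assert read_plot_table(path).equals(table)


def test_read_rejects_bad_cover_label(tmp_path):
    table = make_plot_table(n_plots=5)
    path = tmp_path / "t.csv"
    write_plot_table(table, path)
    df = pd.read_csv(path, dtype=str)
    df.loc[2, "sp1"] = "9"
    df.to_csv(path, index=False)
    with pytest.raises(PlotDataError, match="sp1"):
        read_plot_table(path)


def test_read_rejects_duplicate_plot_ids(tmp_path):
    table = make_plot_table(n_plots=5)
    path = tmp_path / "t.csv"
    write_plot_table(table, path)
    df = pd.read_csv(path)
    df.loc[1, "plot_id"] = df.loc[0, "plot_id"]
    df.to_csv(path, index=False)
    with pytest.raises(PlotDataError, match="duplicate"):
        read_plot_table(path)


def test_read_empty_file_errors(tmp_path):
    table = make_plot_table(n_plots=5)
    path = tmp_path / "t.csv"
    write_plot_table(table, path)
    path.write_text("")
    with pytest.raises(PlotDataError, match="no records"):
        read_plot_table(path)


def test_syndrome_map_round_trip_and_validation(tmp_path):
    syn = {"sp1": "T", "sp2": "Q", "sp3": "none"}
    path = tmp_path / "syn.csv"
    write_syndrome_map(syn, path)
    assert read_syndrome_map(path) == syn
    path.write_text("species,syndrome\nsp1,X\n")
    with pytest.raises(PlotDataError):
        read_syndrome_map(path)


def test_categorical_view_bins_continuous_and_space():
    table = make_plot_table(n_plots=80, n_species=2, seed=3)
    cat = to_categorical(table)
    assert set(cat["Twarm"].unique()) <= {"q1", "q2", "q3", "q4"}
    assert cat["spac"].nunique() <= 9
    # quartile bins are balanced
    counts = cat["Twarm"].value_counts()
    assert counts.max() - counts.min() <= 1
    # species columns unchanged
    assert (cat["sp1"] == table.df["sp1"].astype(str)).all()
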
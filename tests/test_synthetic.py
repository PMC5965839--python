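"""Ground-truth sampling, ancestral simulation, and recovery metrics."""

import numpy as np
import pytest

from vegnet.network import Arc, ConsensusNetwork
from vegnet.plot_data import SPATIAL_NODE, write_plot_table
from vegnet.synthetic import (GroundTruthNetwork, SimulationConfig,
                              sample_ground_truth, simulate_plots,
                              structure_recovery_metrics)


def test_zero_density_gives_empty_arc_set():
    net = sample_ground_truth(SimulationConfig(n_species=6, n_plots=10,
                                               arc_density=0.0, seed=1))
    assert net.arc_set == set()


def test_all_positive_config_forces_plus_signs():
    net = sample_ground_truth(SimulationConfig(n_species=15, n_plots=10,
                                               fraction_positive_signs=1.0, seed=2))
    signed = [s for s in net.arcs.values() if s is not None]
    assert signed and all(s == "+" for s in signed)


def test_positive_fraction_matches_configured_rate():
    """Monte-Carlo: the '+' fraction over many sampled networks ~ 0.95."""
    plus = total = 0
    for seed in range(300):
        net = sample_ground_truth(SimulationConfig(n_species=12, n_plots=10, seed=seed))
        signs = [s for s in net.arcs.values() if s is not None]
        plus += sum(s == "+" for s in signs)
        total += len(signs)
    assert total > 1000
    assert abs(plus / total - 0.95) < 0.02


def test_ground_truth_respects_structural_constraints(small_truth):
    no_parent = {a.name for a in small_truth.env_attributes if not a.may_have_parents}
    no_parent.add(SPATIAL_NODE)
    env = {a.name for a in small_truth.env_attributes} | {SPATIAL_NODE}
    for parent, child in small_truth.arc_set:
        assert child not in no_parent
        assert not (parent in small_truth.species and child in env)


def test_cpt_rows_sum_to_one_and_plus_arcs_are_stochastically_increasing(small_truth):
    for sp in small_truth.species:
        cpt = small_truth.cpt(sp)
        assert np.allclose(cpt.sum(axis=1), 1.0, atol=1e-9)
    # single-parent "+" arcs: P(Y <= k) decreases in the parent level
    for (p, c), sign in small_truth.arcs.items():
        if sign != "+" or small_truth.parents[c] != [p]:
            continue
        k = len(small_truth.levels[p])
        probs = small_truth.conditional_probs(c, {p: np.arange(k)})
        cum = probs.cumsum(axis=1)[:, :-1]
        assert (np.diff(cum, axis=0) <= 1e-9).all()


def test_uniform_cpt_marginals_converge():
    """LLN: with a uniform root CPT, class frequencies approach 1/L."""
    cfg = SimulationConfig(n_species=1, n_env=1, n_plots=30_000,
                           arc_density=0.0, n_cover_levels=3, seed=3)
    net = sample_ground_truth(cfg)
    sp = net.species[0]
    net.cutpoints[sp] = np.log(np.array([1 / 3, 2 / 3]) / (1 - np.array([1 / 3, 2 / 3])))
    table = simulate_plots(net, 30_000, seed=4)
    freq = table.df[sp].value_counts(normalize=True)
    assert np.allclose(freq.sort_index().to_numpy(), 1 / 3, atol=0.01)


def test_plus_arc_is_stochastically_monotone_in_samples():
    """JT statistic of a strong '+' arc exceeds its null mean in >= 95% of replicates."""
    from vegnet.plot_data import to_categorical
    from vegnet.signing import jonckheere_test
    cfg = SimulationConfig(n_species=2, n_env=1, n_plots=80, arc_density=0.0,
                           effect_strength=2.0, seed=12)
    net = sample_ground_truth(cfg)
    parent, child = net.species
    net.parents[child] = [parent]
    net.arcs = {(parent, child): "+"}
    above = 0
    for rep in range(200):
        table = simulate_plots(net, 80, seed=1000 + rep)
        cat = to_categorical(table)
        g = cat[parent].map({lv: i for i, lv in enumerate(net.levels[parent])})
        v = cat[child].map({lv: i for i, lv in enumerate(net.levels[child])})
        groups = [v[g == k].to_numpy() for k in sorted(g.unique())]
        groups = [grp for grp in groups if len(grp)]
        if len(groups) < 2:
            continue
        jt, z, _ = jonckheere_test(groups)
        above += z > 0
    assert above / 200 >= 0.95


def test_simulation_is_deterministic(tmp_path, small_truth):
    t1 = simulate_plots(small_truth, 100, seed=9)
    t2 = simulate_plots(small_truth, 100, seed=9)
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_plot_table(t1, p1)
    write_plot_table(t2, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_simulated_tables_pass_plot_table_invariants(small_table):
    small_table.validate()
    assert small_table.df["plot_id"].is_unique


def test_ground_truth_json_round_trip(tmp_path, small_truth):
    path = tmp_path / "net.json"
    small_truth.to_json(path)
    back = GroundTruthNetwork.from_json(path)
    assert back.arc_set == small_truth.arc_set
    assert back.syndromes == small_truth.syndromes
    for sp in small_truth.species:
        assert np.allclose(back.cpt(sp), small_truth.cpt(sp))


def _consensus_of(nodes, arcs):
    return ConsensusNetwork(
        nodes=list(nodes),
        arcs=[Arc(p, c, 1.0, 1.0, significant=True) for p, c in arcs],
        threshold=0.5, runs=1, seed=0)


def test_recovery_metrics_identity_and_empty(small_truth):
    perfect = _consensus_of(small_truth.nodes, small_truth.arc_set)
    m = structure_recovery_metrics(small_truth, perfect)
    assert m == {"arc_precision": 1.0, "arc_recall": 1.0, "shd": 0.0}
    empty = _consensus_of(small_truth.nodes, [])
    assert structure_recovery_metrics(small_truth, empty)["arc_recall"] == 0.0


def test_recovery_metrics_hand_counted_three_nodes():
    cfg = SimulationConfig(n_species=3, n_env=1, n_plots=10, arc_density=0.0, seed=0)
    truth = sample_ground_truth(cfg)
    a, b, c = truth.species
    truth.parents[b] = [a]
    truth.parents[c] = [b]
    truth.arcs = {(a, b): "+", (b, c): "+"}
    inferred = _consensus_of(truth.nodes, [(a, b), (c, a)])
    m = structure_recovery_metrics(truth, inferred)
    assert m["arc_precision"] == 0.5
    assert m["arc_recall"] == 0.5


def test_recovery_metrics_rejects_node_mismatch(small_truth):
    other = _consensus_of(["x", "y"], [])
    with pytest.raises(ValueError):
        structure_recovery_metrics(small_truth, other)
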
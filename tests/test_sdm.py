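"""Binomial additive abundance models: fitting, prediction, baselines."""

import numpy as np
import pytest
import statsmodels.api as sm

from vegnet.network import Arc, ConsensusNetwork
from vegnet.sdm import (SdmSpec, _build_design, build_predictor_sets,
                        fit_random_baseline, fit_sdm, predict_abundance)


def test_spec_rejects_self_prediction():
    with pytest.raises(ValueError):
        SdmSpec("sp1", ("sp1",))


def test_intercept_only_fit_is_null_model(small_table):
    sp = small_table.species[0]
    fit = fit_sdm(small_table, SdmSpec(sp, ()))
    assert fit.deviance_explained_pct == pytest.approx(0.0, abs=1e-6)
    y = small_table.cover_midpoints(sp).to_numpy() / 100.0
    pred = predict_abundance(fit, small_table)
    assert np.allclose(list(pred.values()), y.mean(), atol=1e-6)


def test_nested_specs_have_monotone_deviance(small_truth, small_table):
    sp = small_truth.species[-1]
    others = [s for s in small_truth.species if s != sp]
    small = fit_sdm(small_table, SdmSpec(sp, tuple(others[:1]), smooth=False))
    big = fit_sdm(small_table, SdmSpec(sp, tuple(others[:3]), smooth=False))
    assert big.deviance <= small.deviance + 1e-6


def test_strongly_driven_species_has_high_deviance_explained(small_truth, small_table):
    focal = next(sp for sp in small_truth.species
                 if any(p in small_truth.species for p in small_truth.parents[sp]))
    fit = fit_sdm(small_table, SdmSpec(focal, tuple(small_truth.parents[focal])))
    assert fit.deviance_explained_pct >= 20.0


def test_parametric_fit_matches_statsmodels_glm(small_truth, small_table):
    """Independent oracle: unpenalized binomial GLM via statsmodels IRLS."""
    focal = next(sp for sp in small_truth.species if small_truth.parents[sp])
    spec = SdmSpec(focal, tuple(small_truth.parents[focal]), smooth=False)
    fit = fit_sdm(small_table, spec)
    X, _, _, _, _ = _build_design(small_table, spec)
    y = small_table.cover_midpoints(focal).to_numpy() / 100.0
    glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    assert fit.deviance == pytest.approx(glm.deviance, rel=1e-5)
    assert np.allclose(fit.beta, glm.params, atol=1e-4)


def test_predictions_bounded_in_unit_interval(small_truth, small_table):
    focal = small_truth.species[0]
    preds = tuple(small_truth.parents[focal]) or ("Twarm",)
    fit = fit_sdm(small_table, SdmSpec(focal, preds))
    vals = np.array(list(predict_abundance(fit, small_table).values()))
    assert ((vals >= 0) & (vals <= 1)).all()


def test_smooth_lambda_selected_from_grid(small_truth, small_table):
    focal = small_truth.species[1]
    fit = fit_sdm(small_table, SdmSpec(focal, ("Twarm",), basis_dim=15))
    assert fit.lam > 0
    assert 0 < fit.edf < len(small_table.df)


def test_random_baseline_k0_equals_intercept_only(small_table):
    sp = small_table.species[0]
    f0 = fit_sdm(small_table, SdmSpec(sp, ()))
    fr = fit_random_baseline(small_table, sp, 0, seed=3)
    assert fr.aic == pytest.approx(f0.aic)


def test_random_baseline_deterministic_draw(small_table):
    sp = small_table.species[0]
    f1 = fit_random_baseline(small_table, sp, 3, seed=11)
    f2 = fit_random_baseline(small_table, sp, 3, seed=11)
    assert f1.spec.predictors == f2.spec.predictors
    assert sp not in f1.spec.predictors


def test_noise_predictor_usually_raises_aic(small_truth, small_table):
    """BIC-style penalisation: pure-noise extra predictors worsen AIC mostly."""
    rng = np.random.default_rng(0)
    worse = total = 0
    for sp in small_truth.species:
        base_preds = tuple(p for p in small_truth.parents[sp])
        noise_candidates = [s for s in small_truth.species
                            if s != sp and s not in base_preds
                            and not _connected(small_truth, s, sp)]
        if not noise_candidates:
            continue
        noise = noise_candidates[rng.integers(len(noise_candidates))]
        f0 = fit_sdm(small_table, SdmSpec(sp, base_preds, smooth=False))
        f1 = fit_sdm(small_table, SdmSpec(sp, base_preds + (noise,), smooth=False))
        total += 1
        worse += f1.aic > f0.aic
    assert total >= 4
    assert worse / total > 0.5


def _connected(truth, a, b):
    """Crude ancestry check to pick genuinely unrelated noise predictors."""
    def ancestors(x):
        seen, stack = set(), [x]
        while stack:
            cur = stack.pop()
            for p in truth.parents.get(cur, []):
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        return seen
    return a in ancestors(b) or b in ancestors(a) or bool(ancestors(a) & ancestors(b))


def test_build_predictor_sets_reads_both_network_families():
    nodes = ["Twarm", "anualP", "spA", "spB"]
    overall = ConsensusNetwork(
        nodes=nodes,
        arcs=[Arc("spA", "spB", 1.0, 1.0, significant=True),
              Arc("Twarm", "spB", 1.0, 1.0, significant=True)],
        threshold=0.5, runs=1, seed=0)
    env_only = ConsensusNetwork(
        nodes=["Twarm", "anualP", "spB"],
        arcs=[Arc("anualP", "spB", 1.0, 1.0, significant=True)],
        threshold=0.5, runs=1, seed=0)
    sets = build_predictor_sets(overall, {"spB": env_only}, ["spA", "spB"])
    assert sets["spB"]["env_bio"] == ["Twarm", "spA"]
    assert sets["spB"]["env"] == ["anualP"]
    assert sets["spA"] == {"env_bio": [], "env": []}
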
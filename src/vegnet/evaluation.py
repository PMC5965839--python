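"""Calibration/validation split and the model-comparison battery.

One global random split assigns floor(2n/3) plots to calibration and the
rest to validation (1570 plots -> 1046 / 524).  Per species, models are
calibrated on the calibration plots where the species is present; both
model families (Env+Bio and Env) and the random baseline are then evaluated
on the full validation set with Spearman rank correlation of abundances,
the change in deviance explained and AIC, and, per validation plot, the
Bray-Curtis similarity 1 - sum|x-y|/sum(x+y) between predicted and observed
community structure.  Paired t-tests compare the families species-wise
(AIC, deviance explained, rho) and plot-wise (Bray-Curtis).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import braycurtis

from .plot_data import PlotTable
from .sdm import SdmFit, SdmSpec, fit_random_baseline, fit_sdm, predict_abundance

logger = logging.getLogger(__name__)

__all__ = ["split_plots", "spearman_eval", "bray_curtis_similarity",
           "paired_t_test", "run_evaluation", "EvaluationReport", "PairedTestResult"]


def split_plots(table: PlotTable, frac_calibration: float = 2 / 3, seed: int = 0
                ) -> tuple[list[str], list[str]]:
    """One global uniform calibration/validation split of plot ids."""
    n = table.n_plots
    if n < 3:
        raise ValueError("need at least 3 plots to split")
    ids = table.df["plot_id"].astype(str).to_numpy()
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_cal = int(np.floor(frac_calibration * n))
    return sorted(ids[perm[:n_cal]]), sorted(ids[perm[n_cal:]])


def spearman_eval(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Spearman rank correlation (mid-rank ties); NaN when either side is constant."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if len(obs) != len(pred) or len(obs) < 3:
        raise ValueError("vectors must be equal length >= 3")
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        return float("nan")
    return float(stats.spearmanr(obs, pred).statistic)


def bray_curtis_similarity(x: Sequence[float], y: Sequence[float]) -> float:
    """1 - Bray-Curtis dissimilarity between community abundance vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be nonnegative")
    if x.sum() == 0 and y.sum() == 0:
        return float("nan")
    return float(1.0 - braycurtis(x, y))


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    mean_delta: float
    se_delta: float
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {"t": self.t, "df": self.df, "p": self.p, "mean_delta": self.mean_delta,
                "se_delta": self.se_delta, "degenerate": self.degenerate}


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> PairedTestResult:
    """Two-sided paired t-test on aligned pairs (a - b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need equal-length vectors with >= 2 pairs")
    d = a - b
    n = len(d)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    se = sd / np.sqrt(n)
    if sd == 0:
        t = 0.0 if mean == 0 else float("inf") * np.sign(mean)
        p = 1.0 if mean == 0 else 0.0
        return PairedTestResult(t, n - 1, p, mean, 0.0, degenerate=True)
    res = stats.ttest_rel(a, b)
    return PairedTestResult(float(res.statistic), n - 1, float(res.pvalue), mean, se)


@dataclass
class EvaluationReport:
    per_species: pd.DataFrame   # species, n_cal, rho_env, rho_env_bio, delta_deviance_pct, delta_aic, ...
    per_plot: pd.DataFrame      # plot_id, bc_env, bc_env_bio, bc_random
    paired_tests: dict[str, PairedTestResult]
    seed: int
    skipped: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "seed": self.seed,
            "skipped": self.skipped,
            "per_species": self.per_species.round(10).to_dict(orient="records"),
            "per_plot": self.per_plot.round(10).to_dict(orient="records"),
            "paired_tests": {k: v.as_dict() for k, v in self.paired_tests.items()},
        }
        Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, allow_nan=True))


def _subset(table: PlotTable, ids: Sequence[str]) -> PlotTable:
    mask = table.df["plot_id"].astype(str).isin(set(ids))
    return PlotTable(df=table.df.loc[mask].reset_index(drop=True),
                     species=list(table.species),
                     env_attributes=list(table.env_attributes), scale=table.scale)


def run_evaluation(table: PlotTable,
                   predictor_sets: Mapping[str, Mapping[str, Sequence[str]]],
                   seed: int = 0, frac_calibration: float = 2 / 3,
                   include_random: bool = True, basis_dim: int = 30) -> EvaluationReport:
    """Fit and compare Env+Bio vs Env (and random-baseline) models end to end.

    For each species the calibration rows are the calibration plots where it
    is present; species absent from every calibration plot are skipped with
    a logged reason.  All validation metrics use the single shared
    validation set, so the per-plot Bray-Curtis comparison is well defined.
    """
    cal_ids, val_ids = split_plots(table, frac_calibration, seed)
    cal = _subset(table, cal_ids)
    val = _subset(table, val_ids)
    obs_val = val.cover_midpoints() / 100.0  # plots x species proportions

    rows = []
    skipped: list[str] = []
    pred_env = pd.DataFrame(index=val.df["plot_id"].astype(str), columns=table.species, dtype=float)
    pred_bio = pred_env.copy()
    pred_rand = pred_env.copy()
    rng = np.random.default_rng(seed)

    for sp in table.species:
        present = cal.cover_midpoints(sp) > 0
        if not present.any():
            logger.warning("species %s absent from all calibration plots; skipped", sp)
            skipped.append(sp)
            continue
        cal_sp = PlotTable(df=cal.df.loc[present.to_numpy()].reset_index(drop=True),
                           species=list(table.species),
                           env_attributes=list(table.env_attributes), scale=table.scale)
        sets = predictor_sets.get(sp, {"env_bio": [], "env": []})
        fit_bio = fit_sdm(cal_sp, SdmSpec(sp, tuple(sets["env_bio"]), basis_dim=basis_dim))
        fit_env = fit_sdm(cal_sp, SdmSpec(sp, tuple(sets["env"]), basis_dim=basis_dim))
        p_bio = predict_abundance(fit_bio, val)
        p_env = predict_abundance(fit_env, val)
        obs = obs_val[sp].to_numpy()
        row = {
            "species": sp, "n_cal": int(present.sum()),
            "n_pred_env_bio": len(sets["env_bio"]), "n_pred_env": len(sets["env"]),
            "rho_env": spearman_eval(obs, [p_env[i] for i in pred_env.index]),
            "rho_env_bio": spearman_eval(obs, [p_bio[i] for i in pred_env.index]),
            "dev_expl_env": fit_env.deviance_explained_pct,
            "dev_expl_env_bio": fit_bio.deviance_explained_pct,
            "aic_env": fit_env.aic, "aic_env_bio": fit_bio.aic,
        }
        row["delta_deviance_pct"] = row["dev_expl_env_bio"] - row["dev_expl_env"]
        row["delta_aic"] = row["aic_env_bio"] - row["aic_env"]
        pred_bio.loc[:, sp] = [p_bio[i] for i in pred_bio.index]
        pred_env.loc[:, sp] = [p_env[i] for i in pred_env.index]
        if include_random:
            k = len(sets["env_bio"])
            fit_rand = fit_random_baseline(cal_sp, sp, k,
                                           seed=int(rng.integers(0, 2**31 - 1)))
            p_rand = predict_abundance(fit_rand, val)
            row["dev_expl_random"] = fit_rand.deviance_explained_pct
            row["rho_random"] = spearman_eval(obs, [p_rand[i] for i in pred_rand.index])
            pred_rand.loc[:, sp] = [p_rand[i] for i in pred_rand.index]
        rows.append(row)

    per_species = pd.DataFrame(rows)
    fitted = [c for c in table.species if c not in skipped]
    plot_rows = []
    for pid in pred_env.index:
        obs = obs_val.loc[val.df["plot_id"].astype(str) == pid, fitted].to_numpy().ravel()
        rec = {"plot_id": pid,
               "bc_env": bray_curtis_similarity(obs, pred_env.loc[pid, fitted].to_numpy(float)),
               "bc_env_bio": bray_curtis_similarity(obs, pred_bio.loc[pid, fitted].to_numpy(float))}
        if include_random:
            rec["bc_random"] = bray_curtis_similarity(obs, pred_rand.loc[pid, fitted].to_numpy(float))
        plot_rows.append(rec)
    per_plot = pd.DataFrame(plot_rows)

    tests: dict[str, PairedTestResult] = {}
    if len(per_species) >= 2:
        tests["aic_env_bio_vs_env"] = paired_t_test(per_species["aic_env_bio"],
                                                    per_species["aic_env"])
        tests["dev_expl_env_bio_vs_env"] = paired_t_test(per_species["dev_expl_env_bio"],
                                                         per_species["dev_expl_env"])
        rho_ok = per_species[["rho_env_bio", "rho_env"]].dropna()
        if len(rho_ok) >= 2:
            tests["rho_env_bio_vs_env"] = paired_t_test(rho_ok["rho_env_bio"],
                                                        rho_ok["rho_env"])
        if include_random:
            rnd_ok = per_species[["dev_expl_env_bio", "dev_expl_random"]].dropna()
            tests["dev_expl_env_bio_vs_random"] = paired_t_test(
                rnd_ok["dev_expl_env_bio"], rnd_ok["dev_expl_random"])
    bc_ok = per_plot[["bc_env_bio", "bc_env"]].dropna()
    if len(bc_ok) >= 2:
        tests["bc_env_bio_vs_env"] = paired_t_test(bc_ok["bc_env_bio"], bc_ok["bc_env"])

    return EvaluationReport(per_species=per_species, per_plot=per_plot,
                            paired_tests=tests, seed=seed, skipped=skipped)
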
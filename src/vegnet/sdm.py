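"""Species distribution models: binomial additive models with a spatial smooth.

The response is the focal species' mean percent cover, expressed as a
proportion in [0, 1] and modelled with a logit link and binomial deviance
(unit weights — the proportion is not a count of trials, so the fit behaves
quasi-binomially).  Predictors are the parent nodes of the focal species in
the relevant consensus network: continuous environmental variables enter
linearly, unordered-categorical ones one-hot with a reference level, and
parent species as cover-class midpoints / 100.  Whenever the model has any
predictor, a penalized bivariate thin-plate-type smooth of (lon, lat)
captures broad geographic trend; its smoothing parameter λ is selected by
generalized cross-validation.  Intercept-only models (species with no
parents) have no smooth.

The smooth uses the classic thin-plate radial basis: unpenalized linear
terms in the scaled coordinates plus radial functions r^2 log r centred on
k knots spread over the observed plots, with the bending-energy matrix as
the penalty.  Model degrees of freedom are the effective degrees of freedom
tr(H) of the penalized fit, and AIC = deviance + 2 * edf.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network import ConsensusNetwork, parent_sets
from .plot_data import SPATIAL_NODE, PlotTable

logger = logging.getLogger(__name__)

__all__ = ["SdmSpec", "SdmFit", "fit_sdm", "fit_random_baseline",
           "predict_abundance", "build_predictor_sets"]

_EPS = 1e-8


@dataclass(frozen=True)
class SdmSpec:
    """What to fit for one species: predictors and the spatial smooth."""

    focal_species: str
    predictors: tuple[str, ...] = ()
    smooth: bool = True
    basis_dim: int = 30

    def __post_init__(self) -> None:
        if self.focal_species in self.predictors:
            raise ValueError("focal species cannot predict itself")


def _tps_eta(r2: np.ndarray) -> np.ndarray:
    # thin-plate radial function r^2 log r, continuous at 0
    out = np.zeros_like(r2)
    pos = r2 > 0
    out[pos] = 0.5 * r2[pos] * np.log(r2[pos])
    return out


class _SpatialSmooth:
    """Thin-plate-type basis over scaled (lon, lat) with bending-energy penalty."""

    def __init__(self, lon: np.ndarray, lat: np.ndarray, basis_dim: int):
        pts = np.column_stack([lon, lat]).astype(float)
        self.center = pts.mean(axis=0)
        self.scale = pts.std(axis=0)
        self.scale[self.scale == 0] = 1.0
        z = (pts - self.center) / self.scale
        uniq = np.unique(z, axis=0)
        k = min(max(basis_dim - 3, 3), len(uniq))
        # deterministic spread of knots: evenly spaced through the lexicographic order
        order = np.lexsort((uniq[:, 1], uniq[:, 0]))
        take = np.linspace(0, len(uniq) - 1, k).round().astype(int)
        self.knots = uniq[order[take]]
        d2 = ((self.knots[:, None, :] - self.knots[None, :, :]) ** 2).sum(axis=2)
        self.penalty_radial = _tps_eta(d2) + 1e-8 * np.eye(k)

    def design(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        z = (np.column_stack([lon, lat]) - self.center) / self.scale
        d2 = ((z[:, None, :] - self.knots[None, :, :]) ** 2).sum(axis=2)
        return np.column_stack([z, _tps_eta(d2)])  # 2 linear + k radial columns

    @property
    def n_cols(self) -> int:
        return 2 + len(self.knots)

    def penalty(self) -> np.ndarray:
        S = np.zeros((self.n_cols, self.n_cols))
        S[2:, 2:] = self.penalty_radial
        return S


@dataclass
class SdmFit:
    """A fitted penalized binomial additive model with a prediction contract."""

    spec: SdmSpec
    beta: np.ndarray
    column_names: list[str]
    aic: float
    deviance: float
    null_deviance: float
    deviance_explained_pct: float
    lam: float
    edf: float
    converged: bool
    diagnostics: str = ""
    # design metadata
    _cont_stats: dict[str, tuple[float, float]] = field(default_factory=dict)
    _cat_levels: dict[str, list[str]] = field(default_factory=dict)
    _smooth: _SpatialSmooth | None = None
    _midpoints: dict[str, float] = field(default_factory=dict)

    def report(self, mode: str = "env_bio") -> dict:
        return {"species": self.spec.focal_species, "mode": mode,
                "predictors": list(self.spec.predictors), "aic": self.aic,
                "deviance": self.deviance,
                "deviance_explained_pct": self.deviance_explained_pct,
                "lambda": self.lam, "edf": self.edf, "converged": self.converged}


def _binomial_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, _EPS, 1 - _EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
    return float(2.0 * (t1 + t2).sum())


def _pirls(X: np.ndarray, y: np.ndarray, S: np.ndarray, lam: float,
           max_iter: int = 60, tol: float = 1e-9) -> tuple[np.ndarray, float, float, bool]:
    """Penalized IRLS for the binomial-logit model; returns (beta, dev, edf, ok)."""
    n, p = X.shape
    beta = np.zeros(p)
    mu = np.clip((y + 0.5) / 2.0, 0.02, 0.98)
    eta = np.log(mu / (1 - mu))
    dev = _binomial_deviance(y, mu)
    ok = False
    for _ in range(max_iter):
        w = np.clip(mu * (1 - mu), _EPS, None)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        A = X.T @ Xw + lam * S
        try:
            beta_new = np.linalg.solve(A, X.T @ (w * z))
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(A, X.T @ (w * z), rcond=None)[0]
        eta_new = X @ beta_new
        # step-halving to keep the deviance from blowing up
        step = 1.0
        for _ in range(30):
            eta_try = eta + step * (eta_new - eta)
            mu_try = 1.0 / (1.0 + np.exp(-np.clip(eta_try, -30, 30)))
            dev_try = _binomial_deviance(y, mu_try) + lam * float(beta.T @ S @ beta)
            if np.isfinite(dev_try):
                break
            step /= 2
        beta, eta = beta + step * (beta_new - beta), eta_try
        mu = mu_try
        dev_new = _binomial_deviance(y, mu)
        if abs(dev_new - dev) < tol * (abs(dev_new) + 0.1):
            dev = dev_new
            ok = True
            break
        dev = dev_new
    w = np.clip(mu * (1 - mu), _EPS, None)
    Xw = X * w[:, None]
    A = X.T @ Xw + lam * S
    try:
        edf = float(np.trace(np.linalg.solve(A, X.T @ Xw)))
    except np.linalg.LinAlgError:
        edf = float(X.shape[1])
    return beta, dev, edf, ok


def _build_design(table: PlotTable, spec: SdmSpec, fit_meta: SdmFit | None = None,
                  smooth_obj: _SpatialSmooth | None = None
                  ) -> tuple[np.ndarray, list[str], dict, dict, dict]:
    """Design matrix for calibration (fit_meta None) or prediction."""
    df = table.df
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["(Intercept)"]
    cont_stats: dict[str, tuple[float, float]] = {} if fit_meta is None else fit_meta._cont_stats
    cat_levels: dict[str, list[str]] = {} if fit_meta is None else fit_meta._cat_levels
    midpoints = ({c.label: c.midpoint_pct for c in table.scale}
                 if fit_meta is None else fit_meta._midpoints)
    env_names = {a.name: a for a in table.env_attributes}

    for pred in spec.predictors:
        if pred in table.species:
            x = df[pred].astype(str).map(midpoints).to_numpy(float) / 100.0
            cols.append(x)
            names.append(pred)
        elif pred in env_names and env_names[pred].kind == "continuous" or pred in ("lon", "lat"):
            v = df[pred].to_numpy(float)
            if fit_meta is None:
                m, s = float(v.mean()), float(v.std()) or 1.0
                cont_stats[pred] = (m, s if s > 0 else 1.0)
            m, s = cont_stats[pred]
            cols.append((v - m) / s)
            names.append(pred)
        elif pred in env_names or pred == SPATIAL_NODE:
            col = (df[pred].astype(str) if pred in df.columns
                   else pd.Series(["?"] * n, index=df.index))
            if fit_meta is None:
                cat_levels[pred] = sorted(col.unique())
            levels = cat_levels[pred]
            ref = levels[0]
            seen = set(levels)
            vals = col.where(col.isin(seen), ref)
            if (~col.isin(seen)).any():
                logger.warning("predictor %s: unseen level mapped to reference %r", pred, ref)
            for lv in levels[1:]:
                cols.append((vals == lv).to_numpy(float))
                names.append(f"{pred}[{lv}]")
        else:
            raise ValueError(f"unknown predictor {pred!r}")

    if spec.smooth and spec.predictors:
        if smooth_obj is None:
            smooth_obj = _SpatialSmooth(df["lon"].to_numpy(float),
                                        df["lat"].to_numpy(float), spec.basis_dim)
        B = smooth_obj.design(df["lon"].to_numpy(float), df["lat"].to_numpy(float))
        cols.append(B)
        names += [f"s(lon,lat).{i}" for i in range(B.shape[1])]
    X = np.column_stack(cols)
    return X, names, cont_stats, cat_levels, {"smooth": smooth_obj, "midpoints": midpoints}


_LAMBDA_GRID = np.logspace(-3, 7, 11)


def fit_sdm(table: PlotTable, spec: SdmSpec) -> SdmFit:
    """Fit one species' additive abundance model on the given plots.

    λ for the spatial smooth is chosen by minimising the GCV score
    n * deviance / (n - edf)^2 over a log-spaced grid.  Non-convergence is
    reported on the returned fit (``converged`` flag and diagnostics), not
    raised.
    """
    y = table.cover_midpoints(spec.focal_species).to_numpy(float) / 100.0
    X, names, cont_stats, cat_levels, extra = _build_design(table, spec)
    n, p = X.shape
    if n < p and spec.predictors:
        logger.warning("sdm %s: %d rows for %d columns", spec.focal_species, n, p)
    has_smooth = spec.smooth and bool(spec.predictors)
    S = np.zeros((p, p))
    if has_smooth:
        sm: _SpatialSmooth = extra["smooth"]
        S[-sm.n_cols:, -sm.n_cols:] = sm.penalty()

    best = None
    lam_grid = _LAMBDA_GRID if has_smooth else [0.0]
    for lam in lam_grid:
        beta, dev, edf, ok = _pirls(X, y, S, lam)
        gcv = n * dev / max(n - edf, 1e-6) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, lam, beta, dev, edf, ok)
    _, lam, beta, dev, edf, ok = best

    mu0 = np.full_like(y, y.mean())
    null_dev = _binomial_deviance(y, mu0)
    dev_expl = 100.0 * (1.0 - dev / null_dev) if null_dev > 0 else 0.0
    diagnostics = "" if ok else "IRLS did not converge (possible separation)"
    if not ok:
        logger.warning("sdm %s: %s", spec.focal_species, diagnostics)
    fit = SdmFit(spec=spec, beta=beta, column_names=names,
                 aic=dev + 2.0 * edf, deviance=dev, null_deviance=null_dev,
                 deviance_explained_pct=dev_expl, lam=float(lam), edf=edf,
                 converged=ok, diagnostics=diagnostics)
    fit._cont_stats = cont_stats
    fit._cat_levels = cat_levels
    fit._smooth = extra["smooth"]
    fit._midpoints = extra["midpoints"]
    return fit


def fit_random_baseline(table: PlotTable, focal: str, k: int, seed: int = 0) -> SdmFit:
    """Fit the focal species on k predictors drawn uniformly at random.

    Candidates are every non-focal variable (species and environmental
    attributes); k typically equals the focal species' Env+Bio predictor
    count, making the baseline a like-for-like yardstick.
    """
    candidates = [a.name for a in table.env_attributes] + \
                 [s for s in table.species if s != focal]
    if k > len(candidates):
        raise ValueError("k exceeds available non-focal variables")
    rng = np.random.default_rng(seed)
    chosen = tuple(sorted(rng.choice(candidates, size=k, replace=False))) if k else ()
    return fit_sdm(table, SdmSpec(focal_species=focal, predictors=chosen))


def predict_abundance(fit: SdmFit, plots: PlotTable) -> dict[str, float]:
    """Predicted cover proportion per plot id; always within [0, 1]."""
    X, _, _, _, _ = _build_design(plots, fit.spec, fit_meta=fit, smooth_obj=fit._smooth)
    eta = X @ fit.beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    return dict(zip(plots.df["plot_id"].astype(str), mu.astype(float)))


def build_predictor_sets(overall_net: ConsensusNetwork,
                         per_species_env_nets: Mapping[str, ConsensusNetwork],
                         species: Sequence[str]) -> dict[str, dict[str, list[str]]]:
    """Env+Bio and Env predictor lists per species.

    Env+Bio: the species' significant parents in the overall network (other
    species or environmental variables).  Env: its significant parents in
    its own environment-only network.  The two environmental subsets may
    legitimately differ.
    """
    overall_parents = parent_sets(overall_net)
    out: dict[str, dict[str, list[str]]] = {}
    for sp in species:
        env_bio = sorted(overall_parents.get(sp, []))
        env: list[str] = []
        net = per_species_env_nets.get(sp)
        if net is not None:
            env = sorted(parent_sets(net).get(sp, []))
        out[sp] = {"env_bio": env_bio, "env": env}
    return out
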
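"""Fitting the Collective Investment game to investment data.

The fit is a deterministic grid search: for every combination of the
benefit rate ``b``, cost rate ``c``, perception-error SD ``e`` and its
frequency-dependence exponent ``t``, the model's expected collective
investment is computed for each observed group composition, mapped onto
the relative-spore-production scale, and scored by least squares against
the observed per-composition means.  The transdifferentiation pressure
``D`` is then fitted by a one-dimensional search on a fixed grid
(0 to 0.25 in steps of 0.01) with the other parameters held at their
three-strain best fit.  Uncertainty comes from a parametric bootstrap
(resampling composition means from Gaussian(mean, SE) and refitting);
model comparison uses a nested-model F test and paired t / Pearson /
R-squared summaries.

Internals: strategy curves are precomputed on a 2001-point perceived-
relatedness grid per (b, c); the truncated-Gaussian error weights per
(e, t) act on those curves as a single matrix product, giving expected-
investment curves on a 201-point true-relatedness grid that are linearly
interpolated at each composition's strain frequencies.  This reproduces
the per-composition quadrature to ~1e-4 while keeping the full default
grid (20 values per parameter) tractable on one core.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .empirical_scale import model_to_empirical
from .game_core import (
    ErrorModel,
    GameParams,
    GroupComposition,
    _quadrature_grid,
    expected_investment_with_error,
    optimal_initial_allocation,
    optimal_investment,
    realized_investment,
    truncated_gaussian_weights,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "BootstrapResult",
    "FTestResult",
    "grid_search_fit",
    "fit_D",
    "bootstrap_ci",
    "model_compare_F",
    "goodness_of_fit",
    "predict_for_compositions",
]

_TIE_TOL = 1e-12


def _default_b_grid() -> np.ndarray:
    return np.linspace(2.0, 15.0, 20)


def _default_c_grid() -> np.ndarray:
    # 20 values on [1, 2): step 0.05
    return 1.0 + 0.05 * np.arange(20)


def _default_e_grid() -> np.ndarray:
    return np.linspace(0.0, 1.0, 20)


def _default_t_grid() -> np.ndarray:
    # 20 values on (0, 1]
    return np.linspace(0.05, 1.0, 20)


def _default_D_grid() -> np.ndarray:
    return np.round(np.arange(0.0, 0.25 + 1e-9, 0.01), 10)


@dataclass
class FitConfig:
    """Grid bounds, D-search range, bootstrap settings and RNG seed.

    The default four-parameter grid uses 20 values per parameter with
    b in [2, 15], c in [1, 2), e in [0, 1] and t in (0, 1]; the b upper
    bound is wide enough to contain the published best fit (b = 12).
    ``prediction_scale`` selects how model investment is mapped to the
    observed S_G scale: "eq6" (linear rescaling, the default) or "exact"
    (hyperbolic inverse of the investment-inference formula).
    """

    b_grid: np.ndarray = field(default_factory=_default_b_grid)
    c_grid: np.ndarray = field(default_factory=_default_c_grid)
    e_grid: np.ndarray = field(default_factory=_default_e_grid)
    t_grid: np.ndarray = field(default_factory=_default_t_grid)
    D_grid: np.ndarray = field(default_factory=_default_D_grid)
    bootstrap_iterations: int = 100
    seed: int = 0
    prediction_scale: str = "eq6"
    f_test_delta_p: int = 2
    relatedness_grid_points: int = 201

    def __post_init__(self) -> None:
        for name in ("b_grid", "c_grid", "e_grid", "t_grid", "D_grid"):
            g = np.asarray(getattr(self, name), dtype=float)
            if g.size == 0:
                raise ValueError(f"{name} must be nonempty")
            setattr(self, name, g)
        if self.bootstrap_iterations < 1:
            raise ValueError("bootstrap_iterations must be >= 1")
        if self.prediction_scale not in ("eq6", "exact"):
            raise ValueError("prediction_scale must be 'eq6' or 'exact'")


@dataclass
class FitResult:
    """Best-fit parameters, objective value and aligned predictions."""

    params: GameParams
    error: ErrorModel
    rss: float
    predictions: pd.DataFrame  # columns: composition, observed, predicted
    ties: list[tuple] = field(default_factory=list)
    scale: str = "eq6"

    @property
    def D(self) -> float:
        return self.params.D


@dataclass
class BootstrapResult:
    """Parametric-bootstrap confidence intervals.

    ``ci`` maps parameter name to (lo, hi); ``deviations`` holds the raw
    per-iteration deviations from the point estimate; ``conservative_band``
    is the CI-corner parameter combination maximising the deviation of
    predicted investment from the point-estimate prediction.
    """

    point: FitResult
    ci: dict[str, tuple[float, float]]
    deviations: pd.DataFrame
    conservative_band: dict[str, float]
    seed: int


@dataclass
class FTestResult:
    F: float
    df: tuple[int, int]
    p: float
    perfect_fit: bool = False


# ---------------------------------------------------------------------------
# shared prediction machinery
# ---------------------------------------------------------------------------

def _validate_data(data: pd.DataFrame) -> pd.DataFrame:
    if "composition" not in data.columns or "observed_S" not in data.columns:
        raise ValueError("data needs 'composition' and 'observed_S' columns")
    data = data.dropna(subset=["observed_S"])
    if len(data) == 0:
        raise ValueError("all observations missing")
    return data.reset_index(drop=True)


def predict_for_compositions(comps, params: GameParams, err: ErrorModel,
                             with_transdiff: bool = False,
                             scale: str = "eq6") -> np.ndarray:
    """Predicted S-scale value for each composition, caching the
    per-relatedness quadrature across strains and compositions."""
    th = params.theta()
    strat = (lambda rho: optimal_initial_allocation(rho, params)) if with_transdiff \
        else (lambda rho: optimal_investment(rho, params))
    cache: dict[float, float] = {}

    def exp_inv(r: float) -> float:
        if r not in cache:
            cache[r] = expected_investment_with_error(r, params, err, strat)
        return cache[r]

    x_G = np.empty(len(comps))
    for i, comp in enumerate(comps):
        per_strain = np.array([exp_inv(r) for r in comp.frequencies])
        if with_transdiff:
            x_G[i] = realized_investment(comp, np.clip(per_strain, 0.0, 1.0),
                                         params).x_G
        else:
            x_G[i] = float(np.dot(comp.frequencies, per_strain))
    if th <= 0:
        # degenerate b <= c: no positive optimum, predictions pinned at the
        # zero-investment endpoint on either scale
        return np.ones_like(x_G) if scale == "exact" else np.ones_like(x_G)
    return model_to_empirical(x_G / th, th, exact=(scale == "exact"))


def _error_weight_matrix(e: float, t: float, r_grid: np.ndarray,
                         rho: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Rows: truncated-Gaussian quadrature weights at each true r."""
    err = ErrorModel(e=e, t=t)
    sd = np.atleast_1d(err.sd(r_grid))
    W = np.zeros((r_grid.size, rho.size))
    step_ratio = (rho.size - 1) // (r_grid.size - 1)
    for i, (r, s) in enumerate(zip(r_grid, sd)):
        if s <= 0:
            W[i, i * step_ratio] = 1.0  # exact: r_grid nests in rho grid
        else:
            W[i] = truncated_gaussian_weights(r, s, rho, w)
    return W


def _composition_matrix(comps, r_grid: np.ndarray) -> np.ndarray:
    """Sparse-ish map M (n_r x n_comp): x_G = E_curve @ M, with linear
    interpolation of the expected-investment curve at each strain's r."""
    n_r = r_grid.size
    M = np.zeros((n_r, len(comps)))
    h = r_grid[1] - r_grid[0]
    for j, comp in enumerate(comps):
        for r in comp.frequencies:
            pos = r / h
            i0 = min(int(np.floor(pos)), n_r - 2)
            frac = pos - i0
            M[i0, j] += r * (1.0 - frac)
            M[i0 + 1, j] += r * frac
    return M


def grid_search_fit(data: pd.DataFrame, config: FitConfig | None = None) -> FitResult:
    """Least-squares grid search over (b, c, e, t) with D = 0.

    ``data`` holds one row per composition with columns ``composition``
    (a :class:`~collectivegame.game_core.GroupComposition`) and
    ``observed_S`` (mean relative spore production).  Ties on the
    objective (within 1e-12) are broken by ascending (b, c, e, t) and all
    tied grid points are reported.
    """
    if config is None:
        config = FitConfig()
    data = _validate_data(data)
    comps = list(data["composition"])
    if len({tuple(np.round(c.frequencies, 12)) for c in comps}) < 2:
        raise ValueError("need at least 2 distinct compositions")
    obs = data["observed_S"].to_numpy(dtype=float)

    rho, w = _quadrature_grid()
    r_grid = np.linspace(0.0, 1.0, config.relatedness_grid_points)
    M = _composition_matrix(comps, r_grid)

    # strategy values on the perceived-relatedness grid, one row per (b, c)
    bb, cc = np.meshgrid(config.b_grid, config.c_grid, indexing="ij")
    bc_pairs = np.column_stack([bb.ravel(), cc.ravel()])
    with np.errstate(divide="ignore"):
        inv_rho = np.where(rho > 0, 1.0 / rho, np.inf)
    S = 0.5 * (1.0 / bc_pairs[:, 1:2] - inv_rho[None, :] / bc_pairs[:, 0:1])
    S = np.clip(np.where(np.isfinite(S), S, 0.0), 0.0, None)  # (n_bc, n_rho)
    th_bc = np.where(bc_pairs[:, 0] > bc_pairs[:, 1],
                     (bc_pairs[:, 0] - bc_pairs[:, 1])
                     / (2.0 * bc_pairs[:, 0] * bc_pairs[:, 1]),
                     0.0)

    best_rss = np.inf
    candidates: list[tuple[float, tuple]] = []
    for e in config.e_grid:
        for t in config.t_grid:
            W = _error_weight_matrix(e, t, r_grid, rho, w)
            E = S @ W.T  # (n_bc, n_r) expected investment curves
            x_G = E @ M  # (n_bc, n_comp)
            with np.errstate(divide="ignore", invalid="ignore"):
                if config.prediction_scale == "exact":
                    pred = (1.0 - th_bc)[:, None] / (1.0 - x_G)
                else:
                    pred = (1.0 - th_bc)[:, None] + x_G
            pred = np.where(th_bc[:, None] > 0, pred, 1.0)
            rss = ((obs[None, :] - pred) ** 2).sum(axis=1)
            lo = rss.min()
            if lo < best_rss + _TIE_TOL:
                for k in np.flatnonzero(rss <= min(lo, best_rss) + _TIE_TOL):
                    candidates.append(
                        (rss[k], (bc_pairs[k, 0], bc_pairs[k, 1], e, t)))
                best_rss = min(best_rss, lo)

    candidates = [(r, p) for r, p in candidates if r <= best_rss + _TIE_TOL]
    candidates.sort(key=lambda rp: rp[1])
    best = candidates[0][1]
    params = GameParams(b=float(best[0]), c=float(best[1]))
    err = ErrorModel(e=float(best[2]), t=float(best[3]))
    pred = predict_for_compositions(comps, params, err, with_transdiff=False,
                                    scale=config.prediction_scale)
    out = data.copy()
    out["predicted"] = pred
    return FitResult(params=params, error=err,
                     rss=float(((obs - pred) ** 2).sum()),
                     predictions=out[["composition", "observed_S", "predicted"]],
                     ties=[tuple(map(float, p)) for _, p in candidates],
                     scale=config.prediction_scale)


def fit_D(data: pd.DataFrame, fixed_params: GameParams, fixed_error: ErrorModel,
          config: FitConfig | None = None) -> FitResult:
    """One-dimensional search for the transdifferentiation pressure D.

    (b, c, e, t) are held fixed at the values fitted to the three-strain
    data; D is searched on the configured grid (default 0 to 0.25, step
    0.01).  Ties broken by ascending D.
    """
    if config is None:
        config = FitConfig()
    data = _validate_data(data)
    comps = list(data["composition"])
    obs = data["observed_S"].to_numpy(dtype=float)

    results = []
    for D in config.D_grid:
        params = GameParams(b=fixed_params.b, c=fixed_params.c, D=float(D))
        pred = predict_for_compositions(comps, params, fixed_error,
                                        with_transdiff=True,
                                        scale=config.prediction_scale)
        results.append((float(((obs - pred) ** 2).sum()), float(D), pred))
    best_rss = min(r for r, _, _ in results)
    ties = [(D,) for r, D, _ in results if r <= best_rss + _TIE_TOL]
    rss, D, pred = next(t for t in results if t[0] <= best_rss + _TIE_TOL)
    params = GameParams(b=fixed_params.b, c=fixed_params.c, D=D)
    out = data.copy()
    out["predicted"] = pred
    return FitResult(params=params, error=fixed_error, rss=rss,
                     predictions=out[["composition", "observed_S", "predicted"]],
                     ties=ties, scale=config.prediction_scale)


# ---------------------------------------------------------------------------
# uncertainty and model comparison
# ---------------------------------------------------------------------------

def bootstrap_ci(data: pd.DataFrame, config: FitConfig | None = None,
                 fixed_params: GameParams | None = None,
                 fixed_error: ErrorModel | None = None,
                 method: str = "gaussian",
                 replicate_data: pd.DataFrame | None = None) -> BootstrapResult:
    """Parametric-bootstrap confidence intervals for the fitted parameters.

    Each iteration resamples every composition mean from
    Gaussian(mean, SE) (``data`` must carry an ``se_S`` column; SE = 0
    degenerates to no resampling) and refits; the CI per parameter spans
    the 5th to 95th percentile of the deviations from the point estimate,
    widened to contain the point estimate itself.  With ``fixed_params``
    given, only D is refitted.  ``method="replicates"`` instead resamples
    replicate-level observations (``replicate_data`` with columns
    ``composition_id`` and ``observed_S``) with replacement and refits on
    the resampled means.
    """
    if config is None:
        config = FitConfig()
    data = _validate_data(data)
    if method not in ("gaussian", "replicates"):
        raise ValueError("method must be 'gaussian' or 'replicates'")
    if method == "gaussian" and "se_S" not in data.columns:
        raise ValueError("gaussian bootstrap needs an 'se_S' column")
    if config.bootstrap_iterations < 20:
        warnings.warn("fewer than 20 bootstrap iterations: percentiles unstable",
                      stacklevel=2)

    def do_fit(d: pd.DataFrame) -> FitResult:
        if fixed_params is not None:
            return fit_D(d, fixed_params, fixed_error or ErrorModel(), config)
        return grid_search_fit(d, config)

    point = do_fit(data)
    names = ["D"] if fixed_params is not None else ["b", "c", "e", "t"]

    def param_vec(fit: FitResult) -> dict[str, float]:
        full = {"b": fit.params.b, "c": fit.params.c,
                "e": fit.error.e, "t": fit.error.t, "D": fit.params.D}
        return {k: full[k] for k in names}

    rng = np.random.default_rng(config.seed)
    rows = []
    for _ in range(config.bootstrap_iterations):
        d = data.copy()
        if method == "gaussian":
            se = data["se_S"].to_numpy(dtype=float)
            d["observed_S"] = rng.normal(data["observed_S"].to_numpy(float), se)
        else:
            means = []
            for cid in data["composition_id"]:
                vals = replicate_data.loc[
                    replicate_data["composition_id"] == cid, "observed_S"
                ].to_numpy(float)
                means.append(rng.choice(vals, size=vals.size, replace=True).mean())
            d["observed_S"] = means
        d["observed_S"] = d["observed_S"].clip(lower=1e-6)  # S_G must stay > 0
        fit = do_fit(d)
        pt = param_vec(point)
        rows.append({k: v - pt[k] for k, v in param_vec(fit).items()})
    dev = pd.DataFrame(rows)

    ci = {}
    pt = param_vec(point)
    for k in names:
        q5, q95 = np.percentile(dev[k], [5, 95])
        ci[k] = (pt[k] + min(q5, 0.0), pt[k] + max(q95, 0.0))

    # conservative band: CI corner maximising prediction deviation
    comps = list(data["composition"])
    base_pred = point.predictions["predicted"].to_numpy(float)
    best_corner, best_dev = dict(pt), 0.0
    corners = [{}]
    for k in names:
        corners = [dict(cn, **{k: v}) for cn in corners for v in ci[k]]
    for corner in corners:
        full = {"b": point.params.b, "c": point.params.c,
                "e": point.error.e, "t": point.error.t, "D": point.params.D}
        full.update(corner)
        try:
            p = GameParams(b=max(full["b"], 1e-6), c=max(full["c"], 1e-6),
                           D=min(max(full["D"], 0.0), 1.0))
            er = ErrorModel(e=max(full["e"], 0.0), t=max(full["t"], 0.0))
            pred = predict_for_compositions(
                comps, p, er, with_transdiff=fixed_params is not None,
                scale=config.prediction_scale)
        except Exception:
            continue
        d = float(np.max(np.abs(pred - base_pred)))
        if d > best_dev:
            best_dev, best_corner = d, dict(full)
    return BootstrapResult(point=point, ci=ci, deviations=dev,
                           conservative_band=best_corner, seed=config.seed)


def model_compare_F(fit_restricted: FitResult, fit_full: FitResult, n: int,
                    delta_p: int = 2, p_full: int = 4) -> FTestResult:
    """Nested-model F test (perfect vs imperfect information).

    F = ((RSS0 - RSS1)/delta_p) / (RSS1/(n - p_full)).  By default the
    restricted (perfect-information) model drops both error parameters
    (e and t), so delta_p = 2 and the full model has p_full = 4.
    """
    if n <= p_full:
        raise ValueError(f"need n > {p_full} observations (got n={n})")
    rss0, rss1 = fit_restricted.rss, fit_full.rss
    df = (delta_p, n - p_full)
    if rss1 <= 0:
        return FTestResult(F=np.inf, df=df, p=0.0, perfect_fit=True)
    F = ((rss0 - rss1) / delta_p) / (rss1 / (n - p_full))
    p = float(stats.f.sf(F, *df)) if F >= 0 else 1.0
    return FTestResult(F=float(F), df=df, p=p)


def goodness_of_fit(observed, predicted) -> dict[str, float]:
    """R-squared, Pearson r and paired t comparing predictions to data.

    R² = 1 - RSS/TSS with TSS about the observed mean; the paired t test
    asks whether predictions are systematically offset from observations.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size < 3:
        raise ValueError("need equal-length 1-d vectors with n >= 3")
    tss = float(((obs - obs.mean()) ** 2).sum())
    if tss <= 0:
        raise ValueError("observations have zero variance: R^2 undefined")
    rss = float(((obs - pred) ** 2).sum())
    if np.allclose(obs, pred):
        r, r_p, t, t_p = 1.0, 0.0, 0.0, 1.0
    else:
        r, r_p = stats.pearsonr(obs, pred)
        t, t_p = stats.ttest_rel(obs, pred)
    return {"r_squared": 1.0 - rss / tss, "pearson_r": float(r),
            "pearson_p": float(r_p), "paired_t": float(t),
            "paired_t_p": float(t_p), "n": int(obs.size)}
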
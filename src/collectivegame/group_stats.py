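"""Fruiting-body collapse statistics and the two- vs twenty-strain test.

Three analyses live here:

* regression of the proportion of spontaneously collapsed fruiting
  bodies on group relatedness (1/N) — an OLS with F(1, n-2) as the
  headline statistic, with a maximum-likelihood mixed model (composition
  random intercept) computed alongside, plus a relatedness-cubed
  polynomial trend used for visualisation;
* the Pearson correlation between per-group-size mean collapse and mean
  collective investment;
* the enforcement contrast: strains at 5% frequency invest less in
  two-strain groups (partner at 95%, little transdifferentiation
  pressure) than in 20-strain groups (everyone at 5%, strong pressure).
  Pair compositions are first adjusted for systematic representation
  bias observed in 50:50 mixes (odds scaling), then compared by a mixed
  model with group type fixed and replicate group random, with degrees
  of freedom hard-limited to (number of replicate groups - 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "CollapseRegressionResult",
    "collapse_regression",
    "collapse_trend_cubic",
    "correlate_collapse_investment",
    "adjust_pair_frequencies",
    "compare_two_vs_twenty",
]


@dataclass
class CollapseRegressionResult:
    slope: float
    intercept: float
    F: float
    df: tuple[int, int]
    p: float
    r_squared: float
    perfect_fit: bool
    mixed_fixed_effect: float | None
    mixed_p: float | None


def _check_collapse_frame(records: pd.DataFrame) -> pd.DataFrame:
    need = {"relatedness", "proportion_collapsed"}
    missing = need - set(records.columns)
    if missing:
        raise ValueError(f"collapse table missing columns: {sorted(missing)}")
    if len(records) < 3:
        raise ValueError("need at least 3 collapse records")
    if records["relatedness"].nunique() < 2:
        raise ValueError("need at least 2 distinct relatedness values")
    p = records["proportion_collapsed"]
    if ((p < 0) | (p > 1)).any():
        raise ValueError("collapse proportions must lie in [0, 1]")
    return records.reset_index(drop=True)


def collapse_regression(records: pd.DataFrame) -> CollapseRegressionResult:
    """OLS of collapse proportion on relatedness, plus an ML mixed model.

    The OLS F(1, n-2) is the headline statistic; when a ``composition_id``
    column is present a mixed model with composition random intercept is
    fitted by maximum likelihood and its fixed-effect slope reported
    alongside.  A perfect linear fit (zero residual) is flagged with
    F = inf.
    """
    records = _check_collapse_frame(records)
    y = records["proportion_collapsed"].to_numpy(float)
    X = sm.add_constant(records["relatedness"].to_numpy(float))
    ols = sm.OLS(y, X).fit()
    perfect = ols.ssr <= 1e-14 * max(ols.centered_tss, 1.0)
    if perfect:
        F, p = np.inf, 0.0
    else:
        F, p = float(ols.fvalue), float(ols.f_pvalue)
    mix_est = mix_p = None
    if "composition_id" in records.columns and records["composition_id"].nunique() > 1:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = sm.MixedLM(y, X, groups=records["composition_id"])
            mfit = md.fit(reml=False)
        mix_est = float(mfit.fe_params[1])
        mix_p = float(np.asarray(mfit.pvalues)[1])
    return CollapseRegressionResult(
        slope=float(ols.params[1]), intercept=float(ols.params[0]),
        F=F, df=(1, int(ols.df_resid)), p=p,
        r_squared=float(ols.rsquared), perfect_fit=bool(perfect),
        mixed_fixed_effect=mix_est, mixed_p=mix_p)


def collapse_trend_cubic(records: pd.DataFrame) -> dict[str, float]:
    """OLS of collapse proportion on relatedness cubed (plotting aid)."""
    records = _check_collapse_frame(records)
    y = records["proportion_collapsed"].to_numpy(float)
    X = sm.add_constant(records["relatedness"].to_numpy(float) ** 3)
    fit = sm.OLS(y, X).fit()
    return {"intercept": float(fit.params[0]), "slope_r_cubed": float(fit.params[1]),
            "r_squared": float(fit.rsquared)}


def correlate_collapse_investment(collapse_means: pd.DataFrame,
                                  investment_means: pd.DataFrame) -> dict[str, float]:
    """Pearson correlation of per-group-size mean collapse vs investment.

    Both tables need a ``group_size`` key column plus ``proportion_collapsed``
    / ``investment`` value columns; group sizes must match one-to-one.
    """
    a = set(collapse_means["group_size"])
    b = set(investment_means["group_size"])
    if a != b:
        raise ValueError(
            f"group sizes do not match: only-in-collapse={sorted(a - b)}, "
            f"only-in-investment={sorted(b - a)}")
    merged = collapse_means.merge(investment_means, on="group_size")
    if len(merged) < 3:
        raise ValueError("need at least 3 matched group sizes")
    r, p = stats.pearsonr(merged["proportion_collapsed"], merged["investment"])
    return {"pearson_r": float(r), "p": float(p), "n": int(len(merged))}


def adjust_pair_frequencies(focal_frequency: float, fifty_fifty_share: float) -> float:
    """Bias-correct a nominal pair frequency using the 50:50 mix share.

    A strain observed at share ``s`` in nominally 50:50 mixes is over- or
    under-represented by the odds factor ``beta = s/(1-s)``; its adjusted
    frequency in a pair mixed at nominal frequency ``f`` is
    ``f' = f*beta / (f*beta + (1-f))``.  ``s = 0.5`` leaves ``f`` unchanged
    and the two-strain frequencies still sum to 1.
    """
    s = float(fifty_fifty_share)
    f = float(focal_frequency)
    if not 0 < s < 1:
        raise ValueError(f"50:50 share must lie strictly in (0, 1) (got {s})")
    if not 0 < f < 1:
        raise ValueError(f"focal frequency must lie in (0, 1) (got {f})")
    beta = s / (1.0 - s)
    return f * beta / (f * beta + (1.0 - f))


def compare_two_vs_twenty(records: pd.DataFrame) -> dict[str, float]:
    """Mixed-model contrast of low-relatedness investment by group type.

    ``records`` has one row per measurement with columns ``group_type``
    ("two-strain" or "twenty-strain"), ``replicate_group`` (strain ID for
    pairs, N for 20-strain groups) and ``investment``.  Group type is the
    fixed effect, replicate group the random intercept; the t test for
    the fixed effect is evaluated at the minimal degrees of freedom,
    (number of replicate groups - 1).
    """
    need = {"group_type", "replicate_group", "investment"}
    missing = need - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    types = set(records["group_type"])
    if types != {"two-strain", "twenty-strain"}:
        raise ValueError(
            f"need both group types 'two-strain' and 'twenty-strain' (got {sorted(types)})")
    n_groups = records["replicate_group"].nunique()
    if n_groups < 2:
        raise ValueError("need at least 2 replicate groups for the t test df")
    y = records["investment"].to_numpy(float)
    x = (records["group_type"] == "twenty-strain").astype(float).to_numpy()
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.MixedLM(y, X, groups=records["replicate_group"]).fit(reml=False)
    est = float(fit.fe_params[1])
    se = float(np.asarray(fit.bse_fe)[1])
    t = est / se
    df = n_groups - 1
    p = float(2.0 * stats.t.sf(abs(t), df))
    return {"estimate": est, "se": se, "t": float(t), "df": int(df), "p": p,
            "n_replicate_groups": int(n_groups)}
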
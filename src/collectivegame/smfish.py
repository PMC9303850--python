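"""Cell-fate classification from smFISH dot counts.

Per-cell transcript dot counts of the prestalk marker *ecmA* and the
prespore marker *pspA* are turned into a cell-fate call in four steps:

1. **Censoring** — cells whose signal is too weak to call (fewer than 17
   dots) are excluded.  By default a cell is dropped only when *both*
   genes are below 17 dots: a committed prespore cell legitimately shows
   ~0 ecmA, so requiring both genes to pass would censor most committed
   cells.  The strict reading (drop if *either* gene is below 17) is
   available via ``mode="either"``.
2. **Normalisation** — pspA counts are rescaled per replicate by
   mean(ecmA)/mean(pspA) over the retained cells, so both genes share a
   mean and hybridisation-efficiency differences between replicates
   cancel.
3. **Index** — pspA_index = pspA_norm / (ecmA + pspA_norm), the fraction
   of (normalised) signal attributable to the prespore programme.
4. **Classification** — index <= 0.3 → prestalk, >= 0.7 → prespore,
   in between → transdifferentiated (both programmes active at once).

Chi-square contingency tests (no continuity correction) compare category
proportions between clonal and chimeric aggregations and check
replicate homogeneity.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CENSOR_THRESHOLD",
    "INDEX_PRESTALK_MAX",
    "INDEX_PRESPORE_MIN",
    "FATES",
    "censor_cells",
    "normalize_pspA",
    "compute_index",
    "classify_fate",
    "classify_cells",
    "category_proportions",
    "compare_conditions",
    "replicate_homogeneity",
]

CENSOR_THRESHOLD = 17  # minimum dot count for a usable signal
INDEX_PRESTALK_MAX = 0.3
INDEX_PRESPORE_MIN = 0.7
FATES = ("prestalk", "prespore", "transdifferentiated")

_REQUIRED = ("cell_id", "replicate", "condition", "ecmA", "pspA")


def _check_cells(cells: pd.DataFrame) -> pd.DataFrame:
    missing = set(_REQUIRED) - set(cells.columns)
    if missing:
        raise ValueError(f"cell table missing columns: {sorted(missing)}")
    if ((cells["ecmA"] < 0) | (cells["pspA"] < 0)).any():
        raise ValueError("dot counts must be nonnegative")
    return cells.reset_index(drop=True)


def censor_cells(cells: pd.DataFrame, mode: str = "both") -> pd.DataFrame:
    """Flag low-signal cells; adds a boolean ``censored`` column.

    ``mode="both"`` (default) censors a cell only when both genes have
    fewer than 17 dots; ``mode="either"`` censors when either does.
    """
    cells = _check_cells(cells).copy()
    below_e = cells["ecmA"] < CENSOR_THRESHOLD
    below_p = cells["pspA"] < CENSOR_THRESHOLD
    if mode == "both":
        cells["censored"] = below_e & below_p
    elif mode == "either":
        cells["censored"] = below_e | below_p
    else:
        raise ValueError("mode must be 'both' or 'either'")
    return cells


def normalize_pspA(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate pspA normalisation: pspA * mean(ecmA)/mean(pspA).

    Means are taken over the retained (non-censored) cells of each
    replicate, each replicate normalised independently; afterwards
    mean(pspA_norm) equals mean(ecmA) within every replicate.  Requires
    :func:`censor_cells` to have run first.
    """
    if "censored" not in cells.columns:
        raise ValueError("run censor_cells before normalize_pspA")
    cells = cells.copy()
    cells["pspA_norm"] = np.nan
    for rep, grp in cells.groupby("replicate"):
        kept = grp[~grp["censored"]]
        if len(kept) == 0:
            raise ValueError(f"replicate {rep!r} has no retained cells")
        mean_p = kept["pspA"].mean()
        if mean_p <= 0:
            raise ValueError(f"replicate {rep!r} has zero mean pspA: cannot normalise")
        factor = kept["ecmA"].mean() / mean_p
        cells.loc[grp.index, "pspA_norm"] = grp["pspA"] * factor
    return cells


def compute_index(cells: pd.DataFrame) -> pd.DataFrame:
    """pspA index = pspA_norm / (ecmA + pspA_norm) per retained cell."""
    if "pspA_norm" not in cells.columns:
        raise ValueError("run normalize_pspA before compute_index")
    cells = cells.copy()
    denom = cells["ecmA"] + cells["pspA_norm"]
    cells["pspA_index"] = np.where(denom > 0, cells["pspA_norm"] / denom, np.nan)
    cells.loc[cells["censored"], "pspA_index"] = np.nan
    return cells


def classify_fate(index):
    """Fate call from the pspA index (inclusive 0.3 / 0.7 thresholds)."""
    idx = np.asarray(index, dtype=float)
    out = np.where(idx <= INDEX_PRESTALK_MAX, "prestalk",
                   np.where(idx >= INDEX_PRESPORE_MIN, "prespore",
                            "transdifferentiated"))
    out = np.where(np.isnan(idx), "censored", out)
    return out if out.ndim else str(out)


def classify_cells(cells: pd.DataFrame, mode: str = "both") -> pd.DataFrame:
    """Full chain: censor, normalise, index, classify.  Adds columns
    ``censored``, ``pspA_norm``, ``pspA_index``, ``fate``."""
    cells = compute_index(normalize_pspA(censor_cells(cells, mode=mode)))
    cells["fate"] = classify_fate(cells["pspA_index"])
    return cells


def category_proportions(cells: pd.DataFrame, by: str = "condition") -> pd.DataFrame:
    """Fraction of retained cells per fate within each group of ``by``."""
    kept = cells[cells["fate"].isin(FATES)]
    counts = kept.groupby([by, "fate"]).size().unstack(fill_value=0)
    counts = counts.reindex(columns=list(FATES), fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)


def compare_conditions(cells: pd.DataFrame, category: str,
                       correction: bool = False) -> dict[str, float]:
    """2x2 chi-square (1 df): (category vs not) by (clonal vs chimeric).

    No Yates continuity correction by default (counts are large).
    """
    if category not in FATES:
        raise ValueError(f"category must be one of {FATES}")
    kept = cells[cells["fate"].isin(FATES)]
    conditions = sorted(kept["condition"].unique())
    if len(conditions) != 2:
        raise ValueError(f"need exactly 2 conditions (got {conditions})")
    table = np.array([
        [(kept.loc[kept["condition"] == cond, "fate"] == category).sum(),
         (kept.loc[kept["condition"] == cond, "fate"] != category).sum()]
        for cond in conditions
    ])
    if table.sum(axis=1).min() == 0:
        raise ValueError("one condition has no retained cells")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=correction)
    return {"chi2": float(chi2), "df": int(dof), "p": float(p),
            "table": table.tolist(), "conditions": conditions}


def replicate_homogeneity(cells: pd.DataFrame, condition: str) -> dict[str, float]:
    """Replicates x 3-fate contingency chi-square within one condition.

    With R replicates and all three fates present the test has
    2(R-1) df; fates absent from every replicate are dropped with a
    warning (df reduced accordingly).
    """
    kept = cells[(cells["fate"].isin(FATES)) & (cells["condition"] == condition)]
    if kept["replicate"].nunique() < 2:
        raise ValueError(f"need >= 2 replicates in condition {condition!r}")
    table = kept.groupby(["replicate", "fate"]).size().unstack(fill_value=0)
    table = table.reindex(columns=list(FATES), fill_value=0)
    empty = [c for c in table.columns if table[c].sum() == 0]
    if empty:
        warnings.warn(f"fate categories absent everywhere: {empty}; df reduced",
                      stacklevel=2)
        table = table.drop(columns=empty)
    chi2, p, dof, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return {"chi2": float(chi2), "df": int(dof), "p": float(p),
            "table": table.to_numpy().tolist()}
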
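"""CSV schemas, result serialisation and run configuration.

Assay tables are long-format CSV with one row per strain per chimeric
measurement:

    strain_set_id, composition_id, replicate_id, strain_id, frequency,
    clonal_spores, chimeric_spores

(``chimeric_spores`` is the group total repeated on each strain row;
``composition_id`` identifies the frequency combination within a strain
set).  Cell tables are one row per cell: ``cell_id, replicate,
condition, ecmA, pspA``.  Collapse tables are one row per well:
``group_size, composition_id, replicate_id, proportion_collapsed``.

All CSVs are comma-separated UTF-8 with a header row and '.' decimals.
Unknown columns are preserved on read and logged; structural problems
raise errors naming the offending row or group.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .empirical_scale import SporeAssayRecord
from .game_core import GroupComposition

logger = logging.getLogger("collectivegame")

__all__ = [
    "RunConfig",
    "read_assay_table",
    "write_assay_table",
    "read_cell_table",
    "write_cell_table",
    "read_collapse_table",
    "write_collapse_table",
    "investment_summary",
    "write_json",
]

ASSAY_COLUMNS = ("strain_set_id", "composition_id", "replicate_id", "strain_id",
                 "frequency", "clonal_spores", "chimeric_spores")
CELL_COLUMNS = ("cell_id", "replicate", "condition", "ecmA", "pspA")
COLLAPSE_COLUMNS = ("group_size", "composition_id", "replicate_id",
                    "proportion_collapsed")
CONDITIONS = ("clonal", "chimeric")

_FREQ_SUM_TOL = 1e-6  # CSV round-trip tolerance, looser than in-memory


class TableFormatError(ValueError):
    """Raised for malformed input tables, naming the row or group."""


@dataclass
class RunConfig:
    """Resolved settings of one CLI run, written next to its outputs so
    every analysis records its seed and design-decision flags."""

    command: str
    seed: int = 0
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    options: dict = field(default_factory=dict)

    def write(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{what} missing columns: {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        logger.warning("%s: ignoring extra columns %s", what, extra)


# ---------------------------------------------------------------------------
# assay tables
# ---------------------------------------------------------------------------

def write_assay_table(records: list[SporeAssayRecord], path) -> None:
    """Write assay records in the long-format CSV schema."""
    comp_ids: dict[tuple, str] = {}
    rows = []
    for rec in records:
        key = (rec.strain_set_id, rec.composition.strain_ids,
               tuple(np.round(rec.composition.frequencies, 12)))
        if key not in comp_ids:
            comp_ids[key] = f"comp{len(comp_ids) + 1:03d}"
        for sid, freq in rec.composition.entries:
            rows.append({
                "strain_set_id": rec.strain_set_id,
                "composition_id": comp_ids[key],
                "replicate_id": rec.replicate_id,
                "strain_id": sid,
                "frequency": freq,
                "clonal_spores": rec.clonal_totals[sid],
                "chimeric_spores": rec.total_spores,
            })
    pd.DataFrame(rows, columns=list(ASSAY_COLUMNS)).to_csv(path, index=False)


def read_assay_table(path) -> list[SporeAssayRecord]:
    """Read and validate an assay CSV into :class:`SporeAssayRecord`\\ s."""
    df = pd.read_csv(path)
    _require_columns(df, ASSAY_COLUMNS, f"assay table {path}")
    for col in ("frequency", "clonal_spores", "chimeric_spores"):
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            raise TableFormatError(
                f"assay table {path}: non-numeric {col} at rows {list(bad[:5])}")
    neg = df.index[(df["clonal_spores"] < 0) | (df["chimeric_spores"] < 0)]
    if len(neg):
        raise TableFormatError(
            f"assay table {path}: negative spore counts at rows {list(neg[:5])}")
    records = []
    for key, grp in df.groupby(["strain_set_id", "composition_id", "replicate_id"],
                               sort=False):
        fsum = grp["frequency"].sum()
        if abs(fsum - 1.0) > _FREQ_SUM_TOL:
            raise TableFormatError(
                f"assay table {path}: frequencies sum to {fsum:.6g} (not 1) in "
                f"group {key}")
        totals = grp["chimeric_spores"].unique()
        if len(totals) != 1:
            raise TableFormatError(
                f"assay table {path}: inconsistent chimeric totals in group {key}")
        comp = GroupComposition(list(zip(grp["strain_id"], grp["frequency"])))
        records.append(SporeAssayRecord(
            composition=comp,
            total_spores=float(totals[0]),
            clonal_totals=dict(zip(grp["strain_id"],
                                   grp["clonal_spores"].astype(float))),
            replicate_id=str(key[2]),
            strain_set_id=str(key[0]),
        ))
    return records


def investment_summary(records: list[SporeAssayRecord]) -> pd.DataFrame:
    """Per-composition mean and SE of relative spore production S_G.

    Returns one row per unique composition with columns ``composition``,
    ``composition_id``, ``observed_S``, ``se_S`` and ``n`` — the table
    the fitting routines consume.
    """
    from .empirical_scale import expected_clonal_production, relative_production

    groups: dict[tuple, dict] = {}
    for rec in records:
        key = (rec.strain_set_id, rec.composition.strain_ids,
               tuple(np.round(rec.composition.frequencies, 12)))
        s = relative_production(expected_clonal_production(rec), rec.total_spores)
        groups.setdefault(key, {"composition": rec.composition, "S": []})
        groups[key]["S"].append(s)
    rows = []
    for i, (key, g) in enumerate(groups.items(), start=1):
        s = np.array(g["S"])
        rows.append({
            "composition": g["composition"],
            "composition_id": f"comp{i:03d}",
            "observed_S": float(s.mean()),
            "se_S": float(s.std(ddof=1) / np.sqrt(s.size)) if s.size > 1 else 0.0,
            "n": int(s.size),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cell and collapse tables
# ---------------------------------------------------------------------------

def write_cell_table(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, index=False)


def read_cell_table(path) -> pd.DataFrame:
    """Read and validate a per-cell smFISH dot-count CSV."""
    df = pd.read_csv(path)
    _require_columns(df, CELL_COLUMNS, f"cell table {path}")
    for col in ("ecmA", "pspA"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.index[vals.isna()]
            raise TableFormatError(
                f"cell table {path}: non-numeric {col} at rows {list(bad[:5])}")
        if not np.allclose(vals, vals.round()):
            bad = df.index[~np.isclose(vals, vals.round())]
            raise TableFormatError(
                f"cell table {path}: non-integer dot counts in {col} at rows "
                f"{list(bad[:5])}")
        if (vals < 0).any():
            raise TableFormatError(f"cell table {path}: negative counts in {col}")
        df[col] = vals.astype(int)
    unknown = sorted(set(df["condition"]) - set(CONDITIONS))
    if unknown:
        raise TableFormatError(
            f"cell table {path}: unknown condition labels {unknown}; "
            f"allowed: {list(CONDITIONS)}")
    return df


def write_collapse_table(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def read_collapse_table(path) -> pd.DataFrame:
    """Read and validate a fruiting-body collapse CSV; derives the
    ``relatedness`` column (1/group_size) if absent."""
    df = pd.read_csv(path)
    _require_columns(df, COLLAPSE_COLUMNS, f"collapse table {path}")
    p = pd.to_numeric(df["proportion_collapsed"], errors="coerce")
    if p.isna().any() or ((p < 0) | (p > 1)).any():
        bad = df.index[p.isna() | (p < 0) | (p > 1)]
        raise TableFormatError(
            f"collapse table {path}: invalid proportions at rows {list(bad[:5])}")
    if (df["group_size"] < 2).any():
        raise TableFormatError(f"collapse table {path}: group_size must be >= 2")
    if "relatedness" not in df.columns:
        df = df.assign(relatedness=1.0 / df["group_size"])
    return df


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, GroupComposition):
        return {s: f for s, f in obj.entries}
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable) + "\n")
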
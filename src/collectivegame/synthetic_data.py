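"""Synthetic assay generators mirroring the study designs.

These generators produce data with the shape and statistical structure
of the real assays so that every pipeline stage is testable end to end:

* three-strain "transect" designs (one strain fixed at 0.2 or 0.8, the
  other two varied over 10 splits of the remainder → 60 labelled
  compositions per triplet) and equal-frequency N-strain designs
  (N in {4..10, 15, 20});
* chimeric spore totals generated from the game model by inverting the
  investment-inference chain (T_G = E_G*(1 - x_G)/(1 - theta)) with
  multiplicative log-normal measurement noise;
* per-cell smFISH dot counts for prestalk / prespore / transdifferentiated
  populations (negative-binomial counts with class-dependent means);
* fruiting-body collapse proportions that decrease with collective
  investment through a logistic link.

All generators are pure functions of their spec and seed.

Default condition choices (documented in the methods note): clonal spore
mean 5e6 (1e7 cells plated, near-theta allocated to stalk), strain-level
clonal CV 0.3, measurement CV 0.15, ~20 replicates per three-strain
composition and 22 per N-strain composition, matching the reported
replication and the scale of the published per-composition SEs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .empirical_scale import SporeAssayRecord
from .game_core import ErrorModel, GameParams, GroupComposition, predict_collective

__all__ = [
    "SimulationSpec",
    "design_three_strain",
    "design_nstrain",
    "simulate_assay",
    "simulate_smfish",
    "simulate_collapse",
    "DEFAULT_NSTRAIN_SIZES",
]

DEFAULT_NSTRAIN_SIZES = (4, 5, 6, 7, 8, 9, 10, 15, 20)


@dataclass
class SimulationSpec:
    """True parameters and noise structure of a simulated spore assay."""

    params: GameParams = field(default_factory=lambda: GameParams(b=12.0, c=1.0))
    error: ErrorModel = field(default_factory=ErrorModel)
    with_transdiff: bool = False
    n_strains: int = 24
    clonal_mean: float = 5e6
    clonal_strain_cv: float = 0.3  # among-strain variation in clonal totals
    replicates_per_composition: int = 20
    noise_cv: float = 0.15  # multiplicative measurement noise on chimeric totals
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.clonal_strain_cv, self.noise_cv) < 0:
            raise ValueError("coefficients of variation must be >= 0")
        if self.replicates_per_composition < 1:
            raise ValueError("replicate counts must be >= 1")


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# experimental designs
# ---------------------------------------------------------------------------

def design_three_strain(strain_ids) -> list[GroupComposition]:
    """Transect design through three-strain frequency space.

    Each of the three strains is in turn held at frequency 0.2 or 0.8
    while the remaining mass is split between the other two at k/11 and
    1 - k/11 for k = 1..10 (a split grid whose values never collide with
    0.2 or 0.8, so every labelled composition is unique): 3 focals x 2
    levels x 10 splits = 60 compositions.
    """
    ids = list(strain_ids)
    if len(ids) != 3 or len(set(ids)) != 3:
        raise ValueError("need exactly 3 distinct strain ids")
    comps = []
    for focal in range(3):
        others = [i for i in range(3) if i != focal]
        for q in (0.2, 0.8):
            for k in range(1, 11):
                f = [0.0, 0.0, 0.0]
                f[focal] = q
                f[others[0]] = (1.0 - q) * k / 11.0
                f[others[1]] = (1.0 - q) * (11.0 - k) / 11.0
                comps.append(GroupComposition(list(zip(ids, f))))
    return comps


def design_nstrain(sizes=DEFAULT_NSTRAIN_SIZES, strain_pool=None) -> list[GroupComposition]:
    """Equal-frequency N-strain designs: every strain at 1/N."""
    comps = []
    for n in sizes:
        if n < 2:
            raise ValueError(f"N must be >= 2 (got {n})")
        if strain_pool is not None:
            ids = list(strain_pool)[:n]
            if len(ids) < n:
                raise ValueError("strain pool smaller than N")
        else:
            ids = [f"strain{i + 1}" for i in range(n)]
        comps.append(GroupComposition([(s, 1.0 / n) for s in ids]))
    return comps


# ---------------------------------------------------------------------------
# spore-count assay
# ---------------------------------------------------------------------------

def simulate_assay(designs, spec: SimulationSpec,
                   strain_set_id: str = "set1") -> list[SporeAssayRecord]:
    """Simulate chimeric and clonal spore totals for a list of designs.

    Per-strain clonal totals T_i are drawn log-normally around the panel
    mean (among-strain variation).  Each chimeric total inverts the
    investment-inference chain at the model-predicted collective
    investment, T_G = E_G*(1 - x_G)/(1 - theta), then applies
    multiplicative log-normal measurement noise.
    """
    rng = np.random.default_rng(spec.seed)
    th = spec.params.theta()
    if not 0 < th < 1:
        raise ValueError("simulation requires b > c so that theta is in (0, 1)")

    strain_ids = sorted({s for comp in designs for s in comp.strain_ids})
    clonal = dict(zip(strain_ids, spec.clonal_mean * _lognormal_factor(
        rng, spec.clonal_strain_cv, len(strain_ids))))

    records = []
    x_cache: dict[tuple, float] = {}
    for comp in designs:
        key = tuple(np.round(comp.frequencies, 12))
        if key not in x_cache:
            x_cache[key] = predict_collective(comp, spec.params, spec.error,
                                              with_transdiff=spec.with_transdiff)
        x_G = x_cache[key]
        E_G = float(np.dot(comp.frequencies,
                           [clonal[s] for s in comp.strain_ids]))
        T_true = E_G * (1.0 - x_G) / (1.0 - th)
        noise = _lognormal_factor(rng, spec.noise_cv,
                                  spec.replicates_per_composition)
        for rep, f in enumerate(noise, start=1):
            records.append(SporeAssayRecord(
                composition=comp,
                total_spores=float(T_true * f),
                clonal_totals=clonal,
                replicate_id=f"rep{rep}",
                strain_set_id=strain_set_id,
            ))
    return records


# ---------------------------------------------------------------------------
# smFISH dot counts
# ---------------------------------------------------------------------------

#: class-dependent negative-binomial mean dot counts (ecmA, pspA); the
#: classes are well separated on the pspA index so classification error is
#: negligible relative to binomial sampling noise
_CLASS_MEANS = {
    "prestalk": (200.0, 5.0),
    "prespore": (2.0, 200.0),
    "transdifferentiated": (90.0, 115.0),
}


def _nb_draw(rng, mean, size, dispersion):
    """Negative binomial with the given mean and size (dispersion) param."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_smfish(n_cells: int, proportions, seed: int = 0,
                    condition: str = "clonal", replicate: str = "rep1",
                    dispersion: float = 15.0,
                    low_signal_fraction: float = 0.05) -> pd.DataFrame:
    """Simulate per-cell ecmA/pspA dot counts for one condition.

    ``proportions`` are the generating (prestalk, prespore,
    transdifferentiated) class fractions among cells with usable signal.
    A ``low_signal_fraction`` of extra cells with both counts below the
    censoring threshold is appended to exercise the censoring step.
    """
    props = np.asarray(proportions, dtype=float)
    if props.size != 3 or abs(props.sum() - 1.0) > 1e-9 or np.any(props < 0):
        raise ValueError("proportions must be 3 nonnegative values summing to 1")
    rng = np.random.default_rng(seed)
    classes = list(_CLASS_MEANS)
    labels = rng.choice(3, size=n_cells, p=props)
    ecma = np.empty(n_cells, dtype=int)
    pspa = np.empty(n_cells, dtype=int)
    for k, cls in enumerate(classes):
        idx = labels == k
        mu_e, mu_p = _CLASS_MEANS[cls]
        ecma[idx] = _nb_draw(rng, mu_e, int(idx.sum()), dispersion)
        pspa[idx] = _nb_draw(rng, mu_p, int(idx.sum()), dispersion)
    df = pd.DataFrame({
        "cell_id": [f"{replicate}_{condition}_c{i + 1}" for i in range(n_cells)],
        "replicate": replicate,
        "condition": condition,
        "ecmA": ecma,
        "pspA": pspa,
        "true_class": [classes[k] for k in labels],
    })
    n_low = int(round(low_signal_fraction * n_cells))
    if n_low:
        low = pd.DataFrame({
            "cell_id": [f"{replicate}_{condition}_low{i + 1}" for i in range(n_low)],
            "replicate": replicate,
            "condition": condition,
            "ecmA": rng.integers(0, 17, size=n_low),
            "pspA": rng.integers(0, 17, size=n_low),
            "true_class": "low_signal",
        })
        df = pd.concat([df, low], ignore_index=True)
    return df


# ---------------------------------------------------------------------------
# fruiting-body collapse
# ---------------------------------------------------------------------------

def simulate_collapse(x_G_values, group_sizes, n_bodies: int = 100,
                      replicates: int = 11, seed: int = 0,
                      p_floor: float = 0.02, p_ceiling: float = 0.8,
                      midpoint: float = 0.5, steepness: float = 8.0,
                      theta: float | None = None) -> pd.DataFrame:
    """Simulate collapse proportions that fall with collective investment.

    Collapse probability follows a decreasing logistic link in the
    investment expressed as a proportion of theta (or used raw when
    ``theta`` is None); each well scores ``n_bodies`` fruiting bodies as
    a binomial draw.
    """
    x = np.asarray(x_G_values, dtype=float)
    sizes = list(group_sizes)
    if x.size != len(sizes):
        raise ValueError("need one x_G per group size")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("x_G must lie in [0, 1]")
    y = x / theta if theta else x
    p = p_floor + (p_ceiling - p_floor) / (1.0 + np.exp(steepness * (y - midpoint)))
    rng = np.random.default_rng(seed)
    rows = []
    for (n_strains, pi) in zip(sizes, p):
        for rep in range(1, replicates + 1):
            collapsed = rng.binomial(n_bodies, pi)
            rows.append({
                "group_size": n_strains,
                "relatedness": 1.0 / n_strains,
                "composition_id": f"N{n_strains}",
                "replicate_id": f"rep{rep}",
                "proportion_collapsed": collapsed / n_bodies,
            })
    return pd.DataFrame(rows)
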
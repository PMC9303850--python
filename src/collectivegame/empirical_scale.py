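"""Mapping between spore-count assays and stalk investment.

Direct counting of stalk cells is not feasible, so collective stalk
investment is inferred from spore production.  If a chimeric group
invested exactly like clones, it would produce the frequency-weighted
mean of the constituent strains' clonal spore totals,

    E_G = sum_i r_i * T_i.

Relative spore production is S_G = E_G / T_G, so S_G = 1 means
clone-equivalent production (investment at the group optimum theta) and
S_G < 1 means the chimera over-produced spores, i.e. under-invested in
stalk.  The inferred investment on the model scale is

    I_G = (theta - 1 + S_G) / S_G = 1 - (1 - theta) / S_G,

and model predictions x_hat_G (expressed as a proportion of theta) map
back onto the relative-production scale through the paper-style linear
rescaling

    X_G = 1 - theta * (1 - x_hat_G).

The linear map and the exact hyperbolic inverse of the I_G formula,
S = (1 - theta) / (1 - I), agree at both endpoints but differ by up to
~0.07 in between for theta ~ 0.46; both are provided (``exact=True``
selects the hyperbolic form) and the default follows the linear form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .game_core import GroupComposition

__all__ = [
    "SporeAssayRecord",
    "InvestmentEstimate",
    "expected_clonal_production",
    "relative_production",
    "infer_investment",
    "model_to_empirical",
    "estimate_investment",
]


class AssayDataError(ValueError):
    """Raised for structurally invalid assay records."""


@dataclass(frozen=True)
class SporeAssayRecord:
    """One chimeric spore-count measurement plus its clonal references.

    ``clonal_totals`` maps every strain in the composition to its clonal
    spore total T_i; ``total_spores`` is the chimera's measured total T_G.
    """

    composition: GroupComposition
    total_spores: float
    clonal_totals: dict[str, float]
    replicate_id: str = "rep1"
    strain_set_id: str = "set1"

    def __post_init__(self) -> None:
        if self.total_spores < 0:
            raise AssayDataError(f"negative chimeric spore count {self.total_spores}")
        for sid in self.composition.strain_ids:
            if sid not in self.clonal_totals:
                raise AssayDataError(f"missing clonal total for strain {sid!r}")
            if self.clonal_totals[sid] < 0:
                raise AssayDataError(f"negative clonal spore count for strain {sid!r}")


@dataclass(frozen=True)
class InvestmentEstimate:
    """Derived quantities for one record: E_G, S_G, I_G and y = I_G/theta."""

    E_G: float
    S_G: float
    I_G: float
    y: float


def expected_clonal_production(record: SporeAssayRecord) -> float:
    """Clonal expectation E_G = sum_i r_i * T_i for the record's group."""
    comp = record.composition
    totals = np.array([record.clonal_totals[s] for s in comp.strain_ids])
    return float(np.dot(comp.frequencies, totals))


def relative_production(E_G: float, T_G: float) -> float:
    """Relative spore production S_G = E_G / T_G (chimera vs clonal)."""
    if T_G <= 0:
        raise AssayDataError(f"chimeric total T_G must be > 0 (got {T_G})")
    return E_G / T_G


def infer_investment(S_G: float, theta: float) -> float:
    """Inferred collective investment I_G = 1 - (1 - theta)/S_G.

    S_G = 1 maps to theta (clone-equivalent production = optimal
    investment); S_G = 1 - theta maps to 0.  Values of S_G below
    1 - theta give negative inferred investment, which is reported as-is
    with a warning: it flags measurement noise or model misfit and
    clipping it would bias least-squares fits.
    """
    if S_G <= 0:
        raise AssayDataError(f"S_G must be > 0 (got {S_G})")
    if not 0 < theta < 1:
        raise ValueError(f"theta must lie in (0, 1) (got {theta})")
    I_G = 1.0 - (1.0 - theta) / S_G
    if I_G < 0:
        warnings.warn(
            f"inferred investment {I_G:.4g} < 0 (S_G={S_G:.4g} below 1-theta); "
            "reported unclipped",
            stacklevel=2,
        )
    return I_G


def model_to_empirical(x_hat_scaled, theta: float, exact: bool = False):
    """Map model investment (proportion of theta) to the S_G scale.

    Default is the linear rescaling ``X_G = 1 - theta*(1 - x_hat)``;
    ``exact=True`` uses the hyperbolic inverse of :func:`infer_investment`,
    ``S = (1 - theta) / (1 - theta*x_hat)``.
    """
    x = np.asarray(x_hat_scaled, dtype=float)
    if not 0 < theta < 1:
        raise ValueError(f"theta must lie in (0, 1) (got {theta})")
    if exact:
        out = (1.0 - theta) / (1.0 - theta * x)
    else:
        out = 1.0 - theta * (1.0 - x)
    return out if out.ndim else float(out)


def estimate_investment(record: SporeAssayRecord, theta: float) -> InvestmentEstimate:
    """Full chain E_G -> S_G -> I_G -> y for one assay record."""
    E_G = expected_clonal_production(record)
    S_G = relative_production(E_G, record.total_spores)
    I_G = infer_investment(S_G, theta)
    return InvestmentEstimate(E_G=E_G, S_G=S_G, I_G=I_G, y=I_G / theta)
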
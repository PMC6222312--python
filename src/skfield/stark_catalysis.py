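"""Vibrational-Stark and rate-theory analytics.

Links the computed bond fields to observables:

* the linear vibrational Stark effect,  h c Δν̃ = −Δμ·ΔF, converting a field
  change along the probe's difference-dipole axis (MV/cm) into a frequency
  shift (cm⁻¹) and back.  The tuning rate |Δμ|/(hc) is a user-supplied
  calibration constant in cm⁻¹ per (MV/cm); higher-order (quadratic) Stark
  terms are not modeled.
* the Eyring/transition-state relation  ΔG‡ = −RT ln[k_cat/(k_B T/h)],
  converting a unimolecular rate constant into an activation free energy
  (kcal/mol, T = 293 K by default).
* ordinary least-squares fits with R² (squared Pearson correlation) for
  field-vs-experiment and field-vs-ΔG‡ correlations.
* the per-group contribution report: each source group's field, the sum over
  a designated set of key groups, and that sum as an integer percentage of
  the total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classical_field import FieldRecord
from .constants import BOLTZMANN_KB, GAS_CONSTANT_KCAL, PLANCK_H

__all__ = [
    "StarkModel",
    "EyringParams",
    "stark_shift",
    "field_from_shift",
    "eyring_dg",
    "linear_fit",
    "LinearFit",
    "contribution_report",
    "ContributionReport",
]


@dataclass(frozen=True)
class StarkModel:
    """Linear Stark response of the probe.

    ``tuning_rate`` is |Δμ|/(hc) in cm⁻¹ per (MV/cm); ``axis`` is the unit
    direction of the difference dipole (by convention the C→O bond
    direction).
    """

    tuning_rate: float
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.tuning_rate <= 0:
            raise ValueError("tuning_rate must be positive")
        norm = math.sqrt(sum(c * c for c in self.axis))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("axis must be a unit vector")


@dataclass(frozen=True)
class EyringParams:
    """Constants of the Eyring relation (CODATA k_B and h)."""

    temperature: float = 293.0
    gas_constant: float = GAS_CONSTANT_KCAL  # kcal mol^-1 K^-1
    k_b: float = BOLTZMANN_KB
    h: float = PLANCK_H

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def stark_shift(delta_field: float, model: StarkModel) -> float:
    """Frequency shift (cm⁻¹) for a field change projected on the probe axis.

    A more negative field along C→O gives a blue shift (positive Δν̃): the
    shift is ``-tuning_rate * delta_field``.
    """
    return -model.tuning_rate * delta_field


def field_from_shift(shift: float, model: StarkModel) -> float:
    """Invert the linear Stark relation: field change (MV/cm) from a shift."""
    return -shift / model.tuning_rate


def eyring_dg(k_cat: float, params: EyringParams = EyringParams()) -> float:
    """Activation free energy (kcal/mol) from a unimolecular rate constant.

    ΔG‡ = −RT ln[k_cat/(k_B T/h)].  Zero when k_cat equals the attempt
    frequency k_B T/h (≈6.1e12 s⁻¹ at 293 K); positive for any slower rate.
    """
    if k_cat <= 0:
        raise ValueError("k_cat must be positive")
    attempt = params.k_b * params.temperature / params.h
    return -params.gas_constant * params.temperature * math.log(k_cat / attempt)


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    stderr_slope: float

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def linear_fit(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    """Ordinary least squares y = slope·x + intercept with R².

    R² is the squared Pearson correlation of x and y, which for simple
    regression equals the coefficient of determination.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct x values")
    res = stats.linregress(x, y)
    return LinearFit(slope=float(res.slope), intercept=float(res.intercept),
                     r_squared=float(res.rvalue) ** 2,
                     stderr_slope=float(res.stderr))


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


@dataclass
class ContributionReport:
    table: pd.DataFrame
    key_groups: list[str]
    key_sum: float
    total: float
    joint_percent: int

    def to_markdown(self) -> str:
        lines = ["| group | field (MV/cm) |", "| --- | --- |"]
        for label, row in self.table.iterrows():
            lines.append(f"| {label} | {row['field']:+.1f} |")
        lines.append(f"| sum({' + '.join(self.key_groups)}) "
                     f"| {self.key_sum:+.1f} |")
        lines.append(f"\nJoint contribution of {', '.join(self.key_groups)}: "
                     f"{self.joint_percent}% of the total field.")
        return "\n".join(lines)


def contribution_report(decomposition: Mapping[str, "FieldRecord | float"],
                        key_groups: Sequence[str],
                        total_key: str = "total") -> ContributionReport:
    """Per-group fields and the key groups' joint share of the total.

    ``decomposition`` maps group labels to FieldRecords or bare field values
    (MV/cm) and must contain a ``total_key`` entry.  The joint percentage,
    100 × Σ(key groups)/total, is rounded half-away-from-zero to an integer
    and is invariant under uniform rescaling of all fields.
    """
    def _val(v) -> float:
        return float(v.field) if isinstance(v, FieldRecord) else float(v)

    if total_key not in decomposition:
        raise KeyError(f"decomposition lacks the total entry {total_key!r}")
    total = _val(decomposition[total_key])
    if total == 0:
        raise ValueError("total field is zero; percentages undefined")
    missing = [g for g in key_groups if g not in decomposition]
    if missing:
        raise KeyError(f"key groups missing from decomposition: {missing}")
    rows = {label: _val(v) for label, v in decomposition.items()}
    table = pd.DataFrame.from_dict(rows, orient="index", columns=["field"])
    key_sum = float(sum(rows[g] for g in key_groups))
    pct = _round_half_away(100.0 * key_sum / total)
    return ContributionReport(table=table, key_groups=list(key_groups),
                              key_sum=key_sum, total=total,
                              joint_percent=pct)
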
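"""Tumor control probability (TCP) under fractionated irradiation.

The Poisson TCP model: a tumor is controlled when no clonogenic cell
survives, so with ``N`` clonogens and per-fraction survival ``S(d)`` after
``n`` fractions,

    TCP = exp(-N * S(d)**n)

More generally the tumor is voxelised, ``TCP = exp(-sum_i N_i prod_j S_ij)``;
for uniform dose and uniformly distributed cells the voxelised sum reduces
exactly to the single-compartment form, and the default tumor uses one
voxel.  The default tumor is a 1 cm^3 sphere (radius 0.6203 cm) holding
1e8 clonogens, fully oxygenated, with LET effects folded into the fitted
survival parameters rather than modelled explicitly.

Dose axes come in two flavours: physical dose (Gy) and photon-equivalent
dose (GyE) = physical dose x RBE.  Carbon-ion schedules are usually
prescribed in GyE with a generic RBE of 3; `underdose_report` quantifies the
GyE shortfall when that generic value replaces the RBE measured for a
specific cell line.

The number of fractions ``n`` is treated as continuous for dose finding
(iso-effect totals rarely land on integer fraction counts); an integer mode
is available via `numpy.ceil` on the caller's side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import RCRParameters, evaluate_survival

__all__ = [
    "TumorSpec",
    "FractionSchedule",
    "TCPCurve",
    "UnderdoseReport",
    "survival_after_fractions",
    "tcp",
    "tcp_curve",
    "dose_for_tcp",
    "underdose_report",
    "schedule_comparison",
]


@dataclass(frozen=True)
class TumorSpec:
    """In-silico tumor: clonogen count, geometry, voxelisation."""

    n_cells: float = 1e8
    radius: float = 0.6203  # cm; (4/3) pi r^3 = 1.000 cm^3
    n_vox: int = 1

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.n_vox < 1:
            raise ValueError("n_vox must be >= 1")

    @property
    def volume(self) -> float:
        """Sphere volume in cm^3."""
        return 4.0 / 3.0 * math.pi * self.radius**3

    @property
    def cells_per_voxel(self) -> float:
        """Uniform allocation of clonogens across voxels."""
        return self.n_cells / self.n_vox


@dataclass(frozen=True)
class FractionSchedule:
    """Constant dose per fraction, prescribed in Gy or GyE.

    For a GyE prescription the physical dose per fraction is GyE / RBE.
    """

    dose_per_fraction: float
    unit: str = "Gy"  # "Gy" | "GyE"
    rbe: float = 1.0
    name: str = ""

    def __post_init__(self):
        if self.dose_per_fraction <= 0:
            raise ValueError("dose_per_fraction must be positive")
        if self.unit not in ("Gy", "GyE"):
            raise ValueError("unit must be 'Gy' or 'GyE'")
        if self.rbe <= 0:
            raise ValueError("rbe must be positive")

    @property
    def physical_dose_per_fraction(self) -> float:
        return self.dose_per_fraction / self.rbe if self.unit == "GyE" else self.dose_per_fraction


@dataclass(frozen=True)
class TCPCurve:
    """TCP as a function of total dose for one schedule."""

    total_dose: np.ndarray
    tcp: np.ndarray
    dose_axis_kind: str  # "physical" | "GyE"
    schedule: FractionSchedule


def survival_after_fractions(params: RCRParameters, d: float, n: float) -> float:
    """Overall survival S(d)**n after n fractions of d Gy each.

    ``n`` may be non-integer (continuous fractionation for dose finding).
    """
    if d <= 0:
        raise ValueError("dose per fraction must be positive")
    if n < 0:
        raise ValueError("number of fractions must be non-negative")
    return evaluate_survival(params, d) ** n


def tcp(params: RCRParameters, tumor: TumorSpec, d: float, n: float) -> float:
    """Poisson TCP = exp(-sum_i N_i S(d)**n) for uniform dose.

    The voxelised sum is computed explicitly; for uniform dose it equals the
    single-compartment exp(-n_cells * S(d)**n) for any voxel count.
    """
    s_total = survival_after_fractions(params, d, n)
    expected_survivors = tumor.n_vox * tumor.cells_per_voxel * s_total
    return math.exp(-expected_survivors)


def tcp_curve(
    params: RCRParameters,
    tumor: TumorSpec,
    schedule: FractionSchedule,
    n_grid,
    dose_axis_kind: str = "physical",
) -> TCPCurve:
    """Evaluate TCP across a grid of fraction numbers.

    The dose axis is n*d physical Gy, or n*d*RBE GyE when
    ``dose_axis_kind='GyE'``.
    """
    n_grid = np.asarray(n_grid, dtype=float)
    if n_grid.size == 0:
        raise ValueError("n_grid must not be empty")
    if np.any(n_grid < 0) or np.any(np.diff(n_grid) < 0):
        raise ValueError("n_grid must be non-negative and increasing")
    if dose_axis_kind not in ("physical", "GyE"):
        raise ValueError("dose_axis_kind must be 'physical' or 'GyE'")
    d_phys = schedule.physical_dose_per_fraction
    probs = np.array([tcp(params, tumor, d_phys, n) for n in n_grid])
    axis = n_grid * d_phys * (schedule.rbe if dose_axis_kind == "GyE" else 1.0)
    return TCPCurve(total_dose=axis, tcp=probs, dose_axis_kind=dose_axis_kind, schedule=schedule)


def dose_for_tcp(
    params: RCRParameters,
    tumor: TumorSpec,
    schedule: FractionSchedule,
    target: float,
    dose_axis_kind: str = "physical",
) -> float:
    """Total dose achieving the target TCP, for continuous fraction number.

    Solves exp(-N * S(d)**n) = target:
    n* = ln(-ln(target)/N) / ln S(d); total = n* d (physical), times RBE for
    a GyE axis.
    """
    if not 0 < target < 1:
        raise ValueError("target TCP must lie strictly between 0 and 1")
    d_phys = schedule.physical_dose_per_fraction
    s = evaluate_survival(params, d_phys)
    if s >= 1:
        raise ValueError("per-fraction survival >= 1: dose has no effect, no solution")
    n_star = math.log(-math.log(target) / tumor.n_cells) / math.log(s)
    total = n_star * d_phys
    if dose_axis_kind == "GyE":
        total *= schedule.rbe
    elif dose_axis_kind != "physical":
        raise ValueError("dose_axis_kind must be 'physical' or 'GyE'")
    return total


@dataclass(frozen=True)
class UnderdoseReport:
    """GyE shortfall when a generic RBE replaces the cell line's own.

    Identities (held at full precision):
    physical_dose = gye_fixed / rbe_fixed;
    gye_actual = physical_dose * rbe_actual;
    difference = gye_fixed - gye_actual.
    """

    cell_line: str
    gye_fixed: float
    rbe_fixed: float
    physical_dose: float
    rbe_actual: float
    gye_actual: float
    difference: float

    def display_row(self) -> dict[str, float]:
        """One-decimal display row.

        The physical-dose column is truncated to one decimal (the reporting
        convention for delivered physical dose); the GyE columns are rounded.
        """
        return {
            "cell_line": self.cell_line,
            "gye_fixed": round(self.gye_fixed, 1),
            "physical_dose": math.floor(self.physical_dose * 10) / 10,
            "gye_actual": round(self.gye_actual, 1),
            "rbe_actual": round(self.rbe_actual, 2),
            "difference": round(self.difference, 1),
        }


def underdose_report(
    cell_line: str,
    gye_fixed: float,
    rbe_actual: float,
    rbe_fixed: float = 3.0,
) -> UnderdoseReport:
    """Quantify underdosing at a fixed prescription ``gye_fixed`` (GyE).

    A prescription in GyE with the generic ``rbe_fixed`` fixes the physical
    dose; re-expressing that physical dose with the cell line's measured
    ``rbe_actual`` gives the biologically delivered GyE, and the difference
    is the underdose.
    """
    if gye_fixed <= 0 or rbe_fixed <= 0 or rbe_actual <= 0:
        raise ValueError("doses and RBEs must be positive")
    physical = gye_fixed / rbe_fixed
    gye_actual = physical * rbe_actual
    return UnderdoseReport(
        cell_line=cell_line,
        gye_fixed=gye_fixed,
        rbe_fixed=rbe_fixed,
        physical_dose=physical,
        rbe_actual=rbe_actual,
        gye_actual=gye_actual,
        difference=gye_fixed - gye_actual,
    )


def schedule_comparison(
    params_by_line: dict[str, RCRParameters],
    tumor: TumorSpec,
    schedules: list[FractionSchedule],
    target: float,
) -> pd.DataFrame:
    """Required total dose at the target TCP per cell line x schedule.

    GyE-prescribed schedules report a GyE axis; Gy schedules a physical axis.
    """
    rows = []
    for line, params in params_by_line.items():
        for sched in schedules:
            kind = "GyE" if sched.unit == "GyE" else "physical"
            rows.append(
                {
                    "cell_line": line,
                    "schedule": sched.name or f"{sched.dose_per_fraction:g}{sched.unit}",
                    "dose_axis": kind,
                    "total_dose": dose_for_tcp(params, tumor, sched, target, kind),
                }
            )
    return pd.DataFrame(rows)
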
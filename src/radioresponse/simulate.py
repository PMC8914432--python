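"""Synthetic data generators for the radioresponse pipeline.

Two generators:

* `simulate_clonogenic` — colony-count tables with the structure of a real
  clonogenic assay.  Expected colonies at dose d are
  ``cells_seeded * PE * S(d)`` with S from the RCR model; observed counts are
  Poisson draws around that mean (colony formation is a count process, so
  Poisson is the standard radiobiology noise assumption).  Dose grids default
  to the photon (1, 2, 4, 6, 8 Gy) and carbon-ion (0.5, 1, 2, 4, 6 Gy)
  designs, always with a dose-0 control per replicate so plating efficiency
  is recoverable.

* `simulate_expression` — a genes x samples log-intensity matrix for four
  radiosensitivity cohorts (S/MS/MR/R).  A chosen number of informative genes
  receive per-group mean offsets; all genes carry i.i.d. Gaussian noise.
  BeadChip probe-level artefacts (bead summarisation, background) are not
  emulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .survival import RCRParameters, evaluate_survival

__all__ = [
    "GAMMA_DOSES",
    "CARBON_DOSES",
    "ClonogenicDesign",
    "ExpressionDesign",
    "simulate_clonogenic",
    "simulate_expression",
    "GROUP_LABELS",
]

GAMMA_DOSES = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0)
CARBON_DOSES = (0.0, 0.5, 1.0, 2.0, 4.0, 6.0)
GROUP_LABELS = ("S", "MS", "MR", "R")

#: default cells seeded per flask, escalating with dose so expected colonies
#: stay countable as survival falls
_DEFAULT_SEEDING = {0.0: 100, 0.5: 200, 1.0: 200, 2.0: 500, 4.0: 2000, 6.0: 5000, 8.0: 10000}


def _default_seeding(doses: Sequence[float]) -> tuple[int, ...]:
    return tuple(_DEFAULT_SEEDING.get(d, int(100 * 2 ** min(d, 10))) for d in doses)


@dataclass(frozen=True)
class ClonogenicDesign:
    """Design of one simulated clonogenic experiment."""

    doses: tuple[float, ...] = GAMMA_DOSES
    cells_seeded_per_dose: tuple[int, ...] | None = None
    plating_efficiency: float = 0.4
    replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if len(self.doses) == 0:
            raise ValueError("dose list must not be empty")
        d = np.asarray(self.doses, dtype=float)
        if np.any(d < 0):
            raise ValueError("doses must be non-negative")
        if np.any(np.diff(d) <= 0):
            raise ValueError("doses must be sorted and unique")
        if not 0 < self.plating_efficiency <= 1:
            raise ValueError("plating_efficiency must be in (0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.cells_seeded_per_dose is not None:
            if len(self.cells_seeded_per_dose) != len(self.doses):
                raise ValueError("cells_seeded_per_dose must match doses in length")
            if any(n < 1 for n in self.cells_seeded_per_dose):
                raise ValueError("cells seeded must be positive")

    @property
    def seeding(self) -> tuple[int, ...]:
        if self.cells_seeded_per_dose is not None:
            return self.cells_seeded_per_dose
        return _default_seeding(self.doses)


def simulate_clonogenic(
    true_params: RCRParameters,
    design: ClonogenicDesign,
    cell_line: str = "SIM",
    quality: str = "reference",
) -> pd.DataFrame:
    """Poisson-noised colony counts for one cell line / radiation quality.

    Returns a DataFrame in the clonogenic CSV dialect:
    ``cell_line, quality, dose_Gy, cells_seeded, colonies, replicate``.
    Dose-0 rows use S = 1 (they measure plating efficiency).  Reproducible
    for a fixed ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    for rep in range(1, design.replicates + 1):
        for dose, seeded in zip(design.doses, design.seeding):
            s = 1.0 if dose == 0 else evaluate_survival(true_params, dose)
            mean = seeded * design.plating_efficiency * s
            rows.append(
                {
                    "cell_line": cell_line,
                    "quality": quality,
                    "dose_Gy": dose,
                    "cells_seeded": seeded,
                    "colonies": int(rng.poisson(mean)),
                    "replicate": rep,
                }
            )
    df = pd.DataFrame(rows)
    if 0.0 not in design.doses:
        raise ValueError("design must include a dose-0 control")
    return df


@dataclass(frozen=True)
class ExpressionDesign:
    """Design of one simulated 4-cohort expression matrix."""

    n_genes: int = 1000
    n_informative: int = 40
    samples_per_group: tuple[int, int, int, int] = (8, 16, 11, 3)
    group_shift: tuple[float, float, float, float] = (0.0, 0.5, 1.0, 1.5)
    noise_sd: float = 1.0
    baseline: float = 7.0
    seed: int = 0

    def __post_init__(self):
        if self.n_informative > self.n_genes:
            raise ValueError("n_informative must not exceed n_genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if len(self.samples_per_group) != 4 or any(n < 1 for n in self.samples_per_group):
            raise ValueError("samples_per_group must be four positive integers")
        if len(self.group_shift) != 4:
            raise ValueError("group_shift must give one offset per group")


def simulate_expression(design: ExpressionDesign) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a genes x samples log-intensity matrix with group structure.

    The first ``n_informative`` gene ids ("ginfo0001", ...) are informative:
    each receives its own random permutation (and sign) of the group_shift
    vector, so informative genes carry diverse, non-collinear group
    patterns of the designed magnitude.  Remaining genes ("gnull...") are
    pure noise.  Returns (matrix, labels) with labels in S/MS/MR/R.
    """
    rng = np.random.default_rng(design.seed)
    n_samples = sum(design.samples_per_group)
    labels = np.repeat(GROUP_LABELS, design.samples_per_group)
    group_idx = np.repeat(np.arange(4), design.samples_per_group)

    x = rng.normal(design.baseline, design.noise_sd, size=(design.n_genes, n_samples))
    shift = np.asarray(design.group_shift, dtype=float)
    for g in range(design.n_informative):
        pattern = rng.permutation(shift) * rng.choice([-1.0, 1.0])
        x[g] += pattern[group_idx]

    width = len(str(design.n_genes))
    gene_ids = [
        (f"ginfo{i + 1:0{width}d}" if i < design.n_informative else f"gnull{i + 1:0{width}d}")
        for i in range(design.n_genes)
    ]
    sample_ids = [f"{lab}{j + 1:02d}" for j, lab in enumerate(labels)]
    expr = pd.DataFrame(x, index=pd.Index(gene_ids, name="gene"), columns=sample_ids)
    groups = pd.Series(labels, index=sample_ids, name="group")
    return expr, groups
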
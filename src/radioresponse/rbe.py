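"""Relative biological effectiveness (RBE) from paired survival fits.

RBE = (reference dose) / (test dose) producing equal biological effect.
Four iso-effect endpoints are supported, each a dose-like metric of the
fitted RCR curve:

* ``SF10``       — dose at 10% survival (D10),
* ``DBAR_PARAM`` — mean inactivation dose, closed form 1/a + b/c^2,
* ``DBAR_AUC``   — mean inactivation dose, trapezoidal area under the curve,
* ``D0``         — limiting slope of the distal log-survival tail.

`rbe_table` mirrors the conventional summary layout: one row per cell line
with the four endpoint RBEs, followed by Average / Std dev / CV rows (sample
standard deviation, n-1; CV computed from the unrounded mean and SD —
rounding is display-only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .survival import RCRSurvivalResults

__all__ = ["ENDPOINTS", "RBERecord", "RBESummary", "rbe", "rbe_table", "summarize_rbe"]

ENDPOINTS = ("SF10", "DBAR_PARAM", "DBAR_AUC", "D0")


@dataclass(frozen=True)
class RBERecord:
    cell_line: str
    endpoint: str
    reference_metric: float
    test_metric: float
    rbe: float


@dataclass(frozen=True)
class RBESummary:
    endpoint: str
    mean: float
    sd: float | None  # None when n = 1 (sample SD undefined)
    cv: float | None


def rbe(reference_metric: float, test_metric: float) -> float:
    """Ratio of reference to test dose metric at equal effect."""
    if reference_metric <= 0 or test_metric <= 0:
        raise ValueError("dose metrics must be positive")
    return reference_metric / test_metric


def summarize_rbe(values: list[float], endpoint: str) -> RBESummary:
    """Mean, sample SD (n-1) and CV of one endpoint's RBEs."""
    n = len(values)
    if n == 0:
        raise ValueError("no RBE values to summarize")
    mean = sum(values) / n
    if n == 1:
        return RBESummary(endpoint=endpoint, mean=mean, sd=None, cv=None)
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    return RBESummary(endpoint=endpoint, mean=mean, sd=sd, cv=sd / mean)


def rbe_table(
    fits_reference: dict[str, RCRSurvivalResults],
    fits_test: dict[str, RCRSurvivalResults],
) -> tuple[list[RBERecord], list[RBESummary]]:
    """Endpoint-wise RBEs for every cell line plus per-endpoint summaries.

    The two fit maps must share identical cell-line keys; a mismatch is
    rejected naming the offending lines.
    """
    ref_keys, test_keys = set(fits_reference), set(fits_test)
    if ref_keys != test_keys:
        only_ref = sorted(ref_keys - test_keys)
        only_test = sorted(test_keys - ref_keys)
        raise ValueError(
            f"cell-line mismatch: only in reference {only_ref}, only in test {only_test}"
        )
    records: list[RBERecord] = []
    for line in fits_reference:  # preserves insertion order
        for ep in ENDPOINTS:
            ref_m = fits_reference[line].metric(ep)
            test_m = fits_test[line].metric(ep)
            records.append(
                RBERecord(
                    cell_line=line,
                    endpoint=ep,
                    reference_metric=ref_m,
                    test_metric=test_m,
                    rbe=rbe(ref_m, test_m),
                )
            )
    summaries = [
        summarize_rbe([r.rbe for r in records if r.endpoint == ep], ep) for ep in ENDPOINTS
    ]
    return records, summaries


def rbe_frame(records: list[RBERecord], summaries: list[RBESummary]) -> pd.DataFrame:
    """Wide layout: one row per cell line, one column per endpoint, then
    Average / Std dev / CV rows.  Values are unrounded; round at display."""
    lines = list(dict.fromkeys(r.cell_line for r in records))
    wide = pd.DataFrame(index=lines + ["Average", "Std dev", "CV"], columns=list(ENDPOINTS), dtype=float)
    for r in records:
        wide.loc[r.cell_line, r.endpoint] = r.rbe
    for s in summaries:
        wide.loc["Average", s.endpoint] = s.mean
        wide.loc["Std dev", s.endpoint] = s.sd if s.sd is not None else float("nan")
        wide.loc["CV", s.endpoint] = s.cv if s.cv is not None else float("nan")
    wide.index.name = "cell_line"
    return wide
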
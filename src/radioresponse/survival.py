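"""Repairable Conditionally Repairable (RCR) cell-survival model.

The RCR model describes clonogenic survival after a single acute dose ``d``
(Gy) as

    S(d) = exp(-a*d) + b*d*exp(-c*d)

where the first term is the fraction of cells escaping damage and the second
the fraction damaged but conditionally repaired.  ``a`` and ``c`` are per-Gy
rates, ``b`` a per-Gy amplitude; S(0) = 1 for any parameter triple.

The model yields closed forms for the standard radiosensitivity metrics:

* SF2 / SF3.5 — surviving fraction at 2 / 3.5 Gy,
* D10 — dose at 10% survival (numeric inversion),
* mean inactivation dose  D-bar = integral of S over [0, inf) = 1/a + b/c**2,
* limiting slope D0 = -1/slope of ln S in the distal (high-dose) tail,
  which tends to 1/min(a, c).

`RCRSurvivalModel` fits the triple to (dose, surviving-fraction) data by
least squares on ln SF — the radiobiology convention, equalising relative
error across decades of survival — with non-negativity constraints and a
multi-start grid, returning an `RCRSurvivalResults` carrying the estimates
and all derived metrics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
import numpy as np
from scipy import optimize

__all__ = [
    "RCRParameters",
    "evaluate_survival",
    "compute_sf",
    "sf_at",
    "dose_at_survival",
    "mean_inactivation_dose_param",
    "mean_inactivation_dose_auc",
    "limiting_slope_d0",
    "derived_metrics",
    "RCRSurvivalModel",
    "RCRSurvivalResults",
]


@dataclass(frozen=True)
class RCRParameters:
    """Parameter triple (a, b, c) of one RCR survival curve.

    a : per-Gy rate of the undamaged-survival term, >= 0
    b : per-Gy amplitude of the repaired term, >= 0
    c : per-Gy rate of the repaired term, > 0
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ValueError(f"a and b must be non-negative, got a={self.a}, b={self.b}")
        if self.c <= 0:
            raise ValueError(f"c must be positive, got c={self.c}")


def evaluate_survival(params: RCRParameters, dose):
    """Surviving fraction S(d) = exp(-a d) + b d exp(-c d).

    ``dose`` may be a scalar or array; negative doses are rejected.
    """
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    s = np.exp(-params.a * d) + params.b * d * np.exp(-params.c * d)
    return float(s) if np.isscalar(dose) or d.ndim == 0 else s


def sf_at(params: RCRParameters, dose: float) -> float:
    """Surviving fraction at a conventional dose (2 or 3.5 Gy typically)."""
    return evaluate_survival(params, dose)


def compute_sf(colonies: int, cells_seeded: int, plating_efficiency: float) -> float:
    """Per-flask surviving fraction: colonies / (PE * cells seeded).

    Not clipped: noisy data may exceed 1.
    """
    if cells_seeded < 1:
        raise ValueError("cells_seeded must be >= 1")
    if not 0 < plating_efficiency <= 1:
        raise ValueError("plating_efficiency must be in (0, 1]")
    if colonies < 0:
        raise ValueError("colonies must be non-negative")
    return colonies / (plating_efficiency * cells_seeded)


def dose_at_survival(params: RCRParameters, s_target: float, tol: float = 1e-10) -> float:
    """Smallest dose d > 0 with S(d) = s_target.

    Brackets by geometric growth of the upper bound until S < s_target, then
    bisects (Brent) to |S - s_target| < ``tol``.
    """
    if not 0 < s_target < 1:
        raise ValueError("s_target must lie strictly between 0 and 1")
    if params.a == 0:
        # exp term tends to 1; S(d) >= 1 - cannot reach s_target < 1
        raise ValueError("a = 0: survival never falls below 1, no solution")

    f = lambda d: evaluate_survival(params, d) - s_target
    hi = 1.0
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover - unreachable for a > 0
            raise RuntimeError("failed to bracket the target survival level")
    root = optimize.brentq(f, 0.0, hi, xtol=1e-14, rtol=8.9e-16)
    # polish to the survival-space tolerance
    assert abs(f(root)) < tol
    return float(root)


def mean_inactivation_dose_param(params: RCRParameters) -> float:
    """Closed-form mean inactivation dose: integral of S = 1/a + b/c**2."""
    if params.a <= 0:
        raise ValueError("a must be positive: the integral of S diverges for a = 0")
    return 1.0 / params.a + params.b / params.c**2


def _default_dmax(params: RCRParameters, s_floor: float = 1e-8) -> float:
    return dose_at_survival(params, s_floor)


def mean_inactivation_dose_auc(
    params: RCRParameters,
    d_max: float | None = None,
    step: float = 0.01,
) -> float:
    """Mean inactivation dose by trapezoidal area under the fitted curve.

    Defaults: uniform grid of ``step`` = 0.01 Gy out to the dose where
    S < 1e-8.  Converges to `mean_inactivation_dose_param` as step -> 0 and
    d_max -> inf.
    """
    if d_max is None:
        d_max = _default_dmax(params)
    if d_max <= 0 or step <= 0:
        raise ValueError("d_max and step must be positive")
    if step > d_max:
        raise ValueError("step must not exceed d_max")
    grid = np.arange(0.0, d_max + step / 2, step)
    return float(np.trapezoid(evaluate_survival(params, grid), grid))


def _log_survival(params: RCRParameters, d: np.ndarray) -> np.ndarray:
    """ln S(d) evaluated in the log domain (no underflow at distal doses)."""
    from scipy.special import logsumexp

    d = np.asarray(d, dtype=float)
    term1 = -params.a * d
    if params.b == 0:
        return term1
    with np.errstate(divide="ignore"):
        term2 = math.log(params.b) + np.log(d) - params.c * d
    return logsumexp(np.stack([term1, term2]), axis=0)


def limiting_slope_d0(
    params: RCRParameters,
    window: tuple[float, float],
    n_points: int = 200,
) -> float:
    """Limiting slope D0 = -1/slope of ln S(d) over a distal dose window.

    The slope is the ordinary least-squares slope of ln S sampled densely on
    ``window``.  As the window moves distally, D0 -> 1/min(a, c).
    """
    d_lo, d_hi = window
    if not (d_hi > d_lo >= 0):
        raise ValueError("window must satisfy d_hi > d_lo >= 0")
    d = np.linspace(d_lo, d_hi, n_points)
    ln_s = _log_survival(params, d)
    slope = np.polyfit(d, ln_s, 1)[0]
    if slope >= 0:
        raise ValueError("non-physical: log-survival slope is non-negative on the window")
    return -1.0 / slope


def derived_metrics(
    params: RCRParameters,
    d_max_data: float = 8.0,
    d0_window: tuple[float, float] | None = None,
) -> dict[str, float]:
    """All per-curve radiosensitivity metrics as a dict.

    ``d0_window`` defaults to the distal 40% of the data's dose range.
    """
    if d0_window is None:
        d0_window = (0.6 * d_max_data, d_max_data)
    return {
        "sf2": sf_at(params, 2.0),
        "sf35": sf_at(params, 3.5),
        "d10": dose_at_survival(params, 0.1),
        "dbar_param": mean_inactivation_dose_param(params),
        "dbar_auc": mean_inactivation_dose_auc(params),
        "d0": limiting_slope_d0(params, d0_window),
    }


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class RCRSurvivalModel:
    """RCR survival model for one cell line under one radiation quality.

    Parameters
    ----------
    doses, sfs : array-like
        Paired dose (Gy) and surviving-fraction observations.  Replicate
        points at the same dose are fitted jointly, not averaged.
    quality : str
        Radiation-quality tag carried through to the results ("reference",
        "test", "gamma", "carbon", ...).
    cell_line : str, optional
        Identifier carried through to the results.
    """

    def __init__(self, doses, sfs, quality: str = "reference", cell_line: str = ""):
        doses = np.asarray(doses, dtype=float)
        sfs = np.asarray(sfs, dtype=float)
        if doses.shape != sfs.shape or doses.ndim != 1:
            raise ValueError("doses and sfs must be 1-D arrays of equal length")
        if np.any(doses < 0):
            raise ValueError("doses must be non-negative")
        if len(np.unique(doses)) < 4:
            raise ValueError(
                "at least 4 distinct dose levels are required to fit 3 parameters"
            )
        self.doses = doses
        self.sfs = sfs
        self.quality = quality
        self.cell_line = cell_line

    @classmethod
    def from_dataframe(cls, df, quality: str | None = None, cell_line: str | None = None):
        """Build from a clonogenic-record frame.

        Expects columns ``dose_Gy``, ``cells_seeded``, ``colonies`` (and
        optionally ``cell_line``/``quality``); plating efficiency is taken
        from the dose-0 rows and per-flask SF computed via `compute_sf`.
        """
        df = df.copy()
        if cell_line is not None:
            df = df[df["cell_line"] == cell_line]
        if quality is not None:
            df = df[df["quality"] == quality]
        if df.empty:
            raise ValueError("no records after cell_line/quality selection")
        controls = df[df["dose_Gy"] == 0]
        if controls.empty:
            raise ValueError("no dose-0 control records: plating efficiency unknown")
        pe = float(controls["colonies"].sum() / controls["cells_seeded"].sum())
        if pe <= 0:
            raise ValueError("estimated plating efficiency is zero")
        irradiated = df[df["dose_Gy"] > 0]
        sfs = [
            compute_sf(int(r.colonies), int(r.cells_seeded), min(pe, 1.0))
            for r in irradiated.itertuples()
        ]
        doses = np.concatenate([[0.0] * len(controls), irradiated["dose_Gy"].to_numpy()])
        sfs = np.concatenate(
            [
                controls["colonies"].to_numpy() / (pe * controls["cells_seeded"].to_numpy()),
                sfs,
            ]
        )
        return cls(
            doses,
            sfs,
            quality=quality or str(df["quality"].iloc[0]),
            cell_line=cell_line or str(df["cell_line"].iloc[0]),
        )

    # -- fitting ------------------------------------------------------------

    def _starts(self) -> list[tuple[float, float, float]]:
        """Multi-start grid: a0 from the initial log-slope, b0/c0 on a lattice."""
        order = np.argsort(self.doses)
        d, s = self.doses[order], self.sfs[order]
        pos = s > 0
        d, s = d[pos], s[pos]
        lo = np.unique(d)[:2]
        if len(lo) == 2 and lo[1] > lo[0]:
            s0 = np.exp(np.mean(np.log(s[d == lo[0]])))
            s1 = np.exp(np.mean(np.log(s[d == lo[1]])))
            a0 = max((math.log(s0) - math.log(s1)) / (lo[1] - lo[0]), 1e-3)
        else:  # pragma: no cover - guarded by >= 4 distinct doses
            a0 = 0.5
        starts = []
        for b0 in (0.0, 0.5, 1.0, 2.0):
            for c0 in (0.5 * a0, a0, 2 * a0, 4 * a0):
                starts.append((a0, b0, max(c0, 1e-3)))
        return starts

    def fit(self, objective: str = "log") -> "RCRSurvivalResults":
        """Fit (a, b, c) by bounded least squares with multi-start.

        objective : {"log", "linear"}
            "log" (default) minimises sum (ln SF - ln S)^2; SF <= 0 points
            are excluded with a warning.  "linear" minimises raw residuals
            and tolerates SF = 0.
        """
        if objective not in ("log", "linear"):
            raise ValueError("objective must be 'log' or 'linear'")
        d, s = self.doses, self.sfs
        if objective == "log":
            if np.any(s <= 0):
                n_bad = int(np.sum(s <= 0))
                warnings.warn(
                    f"excluding {n_bad} non-positive SF value(s) from log-space fit",
                    stacklevel=2,
                )
                keep = s > 0
                d, s = d[keep], s[keep]
                if len(np.unique(d)) < 4:
                    raise ValueError(
                        "fewer than 4 distinct dose levels remain after excluding "
                        "non-positive SF; use objective='linear'"
                    )
            target = np.log(s)

            def resid(p):
                return np.log(np.exp(-p[0] * d) + p[1] * d * np.exp(-p[2] * d)) - target

        else:
            def resid(p):
                return np.exp(-p[0] * d) + p[1] * d * np.exp(-p[2] * d) - s

        lb = [0.0, 0.0, 1e-9]
        ub = [np.inf] * 3
        best = None
        for start in self._starts():
            try:
                sol = optimize.least_squares(
                    resid, start, bounds=(lb, ub), method="trf", xtol=1e-14, ftol=1e-14
                )
            except Exception:
                continue
            if not sol.success:
                continue
            rss = 2 * sol.cost
            # tie-break toward smaller b (simpler, closer to pure-exponential)
            key = (round(rss, 12), sol.x[1])
            if best is None or key < best[0]:
                best = (key, sol)
        if best is None:
            raise RuntimeError("RCR fit failed to converge from every start")
        sol = best[1]
        params = RCRParameters(a=float(sol.x[0]), b=float(sol.x[1]), c=float(max(sol.x[2], 1e-9)))
        # report RSS on the log scale regardless of objective, where defined
        with np.errstate(divide="ignore", invalid="ignore"):
            pos = s > 0
            lr = np.log(evaluate_survival(params, d[pos])) - np.log(s[pos])
        rss_log = float(np.sum(lr**2))
        return RCRSurvivalResults(
            model=self,
            params=params,
            rss_log=rss_log,
            converged=True,
            n_points=len(d),
            dose_max=float(np.max(self.doses)),
        )


class RCRSurvivalResults:
    """Fitted RCR curve: estimates, fit diagnostics and derived metrics."""

    def __init__(self, model, params, rss_log, converged, n_points, dose_max):
        self.model = model
        self.params = params
        self.rss_log = rss_log
        self.converged = converged
        self.n_points = n_points
        self.dose_max = dose_max

    # metric accessors -------------------------------------------------------

    @property
    def sf2(self) -> float:
        return sf_at(self.params, 2.0)

    @property
    def sf35(self) -> float:
        return sf_at(self.params, 3.5)

    @property
    def d10(self) -> float:
        return dose_at_survival(self.params, 0.1)

    @property
    def dbar_param(self) -> float:
        return mean_inactivation_dose_param(self.params)

    @property
    def dbar_auc(self) -> float:
        return mean_inactivation_dose_auc(self.params)

    @property
    def d0(self) -> float:
        return limiting_slope_d0(self.params, (0.6 * self.dose_max, self.dose_max))

    def predict(self, doses):
        """Model survival at the given doses."""
        return evaluate_survival(self.params, doses)

    def metric(self, endpoint: str) -> float:
        """Endpoint metric by name: 'SF10' (=D10), 'DBAR_PARAM', 'DBAR_AUC', 'D0'."""
        table = {
            "SF10": lambda: self.d10,
            "DBAR_PARAM": lambda: self.dbar_param,
            "DBAR_AUC": lambda: self.dbar_auc,
            "D0": lambda: self.d0,
        }
        try:
            return table[endpoint]()
        except KeyError:
            raise ValueError(f"unknown endpoint {endpoint!r}") from None

    def to_row(self) -> dict:
        """Flat record for the fits CSV dialect."""
        return {
            "cell_line": self.model.cell_line,
            "quality": self.model.quality,
            "a": self.params.a,
            "b": self.params.b,
            "c": self.params.c,
            "rss_log": self.rss_log,
            "sf2": self.sf2,
            "sf35": self.sf35,
            "d10": self.d10,
            "dbar_param": self.dbar_param,
            "dbar_auc": self.dbar_auc,
            "d0": self.d0,
        }

    def summary(self) -> str:
        p = self.params
        lines = [
            "RCR survival fit",
            "================",
            f"cell line : {self.model.cell_line or '-'}",
            f"quality   : {self.model.quality}",
            f"n points  : {self.n_points}   dose range: [0, {self.dose_max:g}] Gy",
            f"a = {p.a:.4f} /Gy   b = {p.b:.4f} /Gy   c = {p.c:.4f} /Gy",
            f"RSS(ln SF) = {self.rss_log:.4g}",
            "-" * 40,
            f"SF2   = {self.sf2:.3f}    SF3.5 = {self.sf35:.3f}",
            f"D10   = {self.d10:.3f} Gy",
            f"D-bar = {self.dbar_param:.3f} Gy (closed form) / "
            f"{self.dbar_auc:.3f} Gy (trapezoidal)",
            f"D0    = {self.d0:.3f} Gy (window [{0.6 * self.dose_max:g}, {self.dose_max:g}])",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        p = self.params
        return (
            f"<RCRSurvivalResults {self.model.cell_line or '?'}/{self.model.quality}: "
            f"a={p.a:.3g} b={p.b:.3g} c={p.c:.3g}>"
        )
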
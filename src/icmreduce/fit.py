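"""Zero-intercept calibration of CNR against iodine concentration.

Per stratum (scanner, mode, energy, size, reconstruction) the model is

    CNR_i = alpha * c_i + eps_i,

a line through the origin: zero concentration adds zero contrast, so the
model carries no intercept term.  The least-squares slope is

    alpha = sum(c_i * CNR_i) / sum(c_i^2),

with standard error  SE(alpha)^2 = s^2 / sum(c_i^2),  s^2 = RSS / (n - 1),
and a coefficient of determination defined about the origin (uncentred),

    R^2 = 1 - RSS / sum(CNR_i^2),

which is the correct R^2 for a no-intercept model (note it is not
comparable to the centred R^2 of an intercept fit; output headers say so).

A diagnostic ordinary fit *with* intercept is also reported when n >= 3,
flagged when its intercept differs from zero by more than two standard
errors — a drift alarm, never used by the planner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, InsufficientDesignError
from .measure import STRATUM_COLUMNS


@dataclass(frozen=True)
class SlopeFit:
    """Fitted CNR-per-(mg/mL) slope for one stratum."""

    stratum: tuple
    alpha: float
    alpha_se: float
    r2: float
    n_points: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_flagged: bool = False

    @property
    def size_label(self) -> str:
        return self.stratum[3] if len(self.stratum) >= 4 else ""


def fit_slope(concentrations, cnr_values, stratum: tuple = ()) -> SlopeFit:
    """Least-squares slope through the origin for one stratum.

    Replicate measurements at the same concentration all enter
    individually.  Requires at least two distinct positive concentrations.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(cnr_values, dtype=float)
    if c.shape != y.shape or c.ndim != 1:
        raise ConfigError("concentrations and CNR values must be 1-D and matched")
    distinct = np.unique(c[c > 0])
    if distinct.size < 2:
        raise InsufficientDesignError(
            f"need >=2 distinct positive concentrations to fit a slope, got {distinct.tolist()}"
        )
    n = c.size
    sxx = float(np.sum(c * c))
    alpha = float(np.sum(c * y)) / sxx
    resid = y - alpha * c
    rss = float(np.sum(resid * resid))
    s2 = rss / (n - 1) if n > 1 else 0.0
    alpha_se = float(np.sqrt(s2 / sxx))
    syy = float(np.sum(y * y))
    r2 = 1.0 - rss / syy if syy > 0 else float("nan")

    intercept = intercept_se = None
    flagged = False
    if n >= 3 and distinct.size >= 2:
        # diagnostic intercept-allowed OLS; never consumed by the planner
        A = np.column_stack([c, np.ones(n)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid2 = y - A @ coef
        dof = n - 2
        s2_2 = float(resid2 @ resid2) / dof if dof > 0 else 0.0
        cov = s2_2 * np.linalg.inv(A.T @ A)
        intercept = float(coef[1])
        intercept_se = float(np.sqrt(cov[1, 1]))
        flagged = intercept_se > 0 and abs(intercept) > 2.0 * intercept_se
    return SlopeFit(tuple(stratum), alpha, alpha_se, r2, n, intercept, intercept_se, flagged)


def fit_slope_measurements(measurements) -> SlopeFit:
    """Fit from a list of :class:`~icmreduce.measure.CNRMeasurement` sharing one stratum."""
    strata = {m.stratum for m in measurements}
    if len(strata) > 1:
        raise ConfigError(f"measurements mix strata: {sorted(strata)}")
    if not measurements:
        raise ConfigError("no measurements given")
    stratum = next(iter(strata))
    return fit_slope(
        [m.concentration for m in measurements],
        [m.cnr for m in measurements],
        stratum=stratum,
    )


@dataclass
class FitResult:
    """All per-stratum fits plus the strata that could not be fitted."""

    fits: pd.DataFrame
    failures: pd.DataFrame


FIT_COLUMNS = STRATUM_COLUMNS + [
    "alpha", "alpha_se", "r2", "n_points",
    "intercept", "intercept_se", "intercept_flagged",
]


def fit_all(measurement_table: pd.DataFrame) -> FitResult:
    """One zero-intercept fit per stratum of a tidy measurement table.

    Strata failing the design preconditions are reported in ``failures``
    (with the reason), never silently dropped.
    """
    if measurement_table is None or len(measurement_table) == 0:
        raise ConfigError("measurement table is empty")
    missing = [col for col in STRATUM_COLUMNS + ["concentration_mg_ml", "cnr"]
               if col not in measurement_table.columns]
    if missing:
        raise ConfigError(f"measurement table missing columns: {missing}")

    fit_rows, fail_rows = [], []
    for key, group in measurement_table.groupby(STRATUM_COLUMNS, sort=True):
        try:
            fit = fit_slope(
                group["concentration_mg_ml"].to_numpy(),
                group["cnr"].to_numpy(),
                stratum=key,
            )
        except InsufficientDesignError as err:
            fail_rows.append(dict(zip(STRATUM_COLUMNS, key)) | {"reason": str(err)})
            continue
        fit_rows.append(
            dict(zip(STRATUM_COLUMNS, key))
            | {
                "alpha": fit.alpha,
                "alpha_se": fit.alpha_se,
                "r2": fit.r2,
                "n_points": fit.n_points,
                "intercept": fit.intercept,
                "intercept_se": fit.intercept_se,
                "intercept_flagged": fit.intercept_flagged,
            }
        )
    fits = pd.DataFrame(fit_rows, columns=FIT_COLUMNS)
    failures = pd.DataFrame(fail_rows, columns=STRATUM_COLUMNS + ["reason"])
    return FitResult(fits, failures)


def slope_fit_from_row(row) -> SlopeFit:
    """Rehydrate a :class:`SlopeFit` from one row of a fits table."""
    return SlopeFit(
        stratum=tuple(row[col] for col in STRATUM_COLUMNS),
        alpha=float(row["alpha"]),
        alpha_se=float(row["alpha_se"]),
        r2=float(row["r2"]),
        n_points=int(row["n_points"]),
    )
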
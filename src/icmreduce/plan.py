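"""Slope-ratio equivalence and iodine-reduction planning.

If stratum fits give CNR = alpha_b * c at the baseline technique and
CNR = alpha_t * c at a target technique, the target concentration matching
the baseline CNR at concentration c_b is

    c_t = (alpha_b / alpha_t) * c_b,

and the achievable contrast-media reduction is

    reduction% = 100 * (1 - alpha_b / alpha_t),

positive when the target technique yields more CNR per unit iodine
(alpha_t > alpha_b); a negative value means the target technique *requires*
100 * (alpha_b/alpha_t - 1) percent more contrast.  Comparisons are only
meaningful within one phantom size (noise and beam path match); cross-size
plans are refused unless explicitly overridden.

Uncertainty is first-order propagation treating the two slopes as
independent:  Var(ratio) = ratio^2 * [(SE_b/alpha_b)^2 + (SE_t/alpha_t)^2].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateInputError
from .fit import SlopeFit, slope_fit_from_row
from .measure import STRATUM_COLUMNS


@dataclass(frozen=True)
class ReductionPlan:
    """Baseline -> target concentration ratio and percent ICM reduction."""

    baseline_stratum: tuple
    target_stratum: tuple
    conc_ratio: float  # target/baseline concentration at matched CNR
    reduction_pct: float  # 100 * (1 - conc_ratio); negative = required increase
    uncertainty_pct: float  # propagated SE of reduction_pct


def _check_pair(baseline: SlopeFit, target: SlopeFit, allow_cross_size: bool):
    if baseline.alpha <= 0:
        raise DegenerateInputError(f"baseline slope must be positive, got {baseline.alpha}")
    if target.alpha <= 0:
        raise DegenerateInputError(f"target slope must be positive, got {target.alpha}")
    if baseline.size_label != target.size_label:
        if not allow_cross_size:
            raise ConfigError(
                f"refusing cross-size plan ({baseline.size_label!r} vs "
                f"{target.size_label!r}); pass allow_cross_size=True to override"
            )
        warnings.warn(
            "comparing slopes across phantom sizes; noise conditions differ",
            stacklevel=3,
        )


def equivalent_concentration(
    conc_baseline: float,
    baseline: SlopeFit,
    target: SlopeFit,
    allow_cross_size: bool = False,
) -> float:
    """Target-technique concentration giving the baseline technique's CNR."""
    _check_pair(baseline, target, allow_cross_size)
    if conc_baseline <= 0:
        raise ConfigError(f"baseline concentration must be positive, got {conc_baseline}")
    return (baseline.alpha / target.alpha) * conc_baseline


def iodine_reduction(
    baseline: SlopeFit,
    target: SlopeFit,
    allow_cross_size: bool = False,
) -> ReductionPlan:
    """Percent ICM reduction achievable by switching baseline -> target."""
    _check_pair(baseline, target, allow_cross_size)
    ratio = baseline.alpha / target.alpha
    rel_var = 0.0
    if baseline.alpha_se > 0:
        rel_var += (baseline.alpha_se / baseline.alpha) ** 2
    if target.alpha_se > 0:
        rel_var += (target.alpha_se / target.alpha) ** 2
    se_ratio = ratio * np.sqrt(rel_var)
    return ReductionPlan(
        baseline_stratum=baseline.stratum,
        target_stratum=target.stratum,
        conc_ratio=ratio,
        reduction_pct=100.0 * (1.0 - ratio),
        uncertainty_pct=100.0 * se_ratio,
    )


@dataclass
class PlanResult:
    """Reduction matrix, per-energy averages across sizes, unavailable strata."""

    plans: pd.DataFrame
    averages: pd.DataFrame
    unavailable: pd.DataFrame


PLAN_COLUMNS = [
    "scanner_label", "size_label", "mode", "energy", "recon_label",
    "baseline_mode", "baseline_energy", "baseline_recon",
    "conc_ratio", "reduction_pct", "uncertainty_pct",
]


def reduction_matrix(
    fits: pd.DataFrame,
    baseline_energy: float = 120,
    baseline_mode: str = "SECT",
    mode_filter: str | None = None,
) -> PlanResult:
    """Reductions for every target stratum relative to a per-size baseline.

    The baseline for each (scanner, size) is the fit at
    (baseline_mode, baseline_energy), matched on reconstruction label when
    several baselines exist.  Sizes lacking a baseline are reported under
    ``unavailable``, never fabricated.  ``averages`` holds the per-energy
    mean reduction across sizes (computed on unrounded values).
    """
    if fits is None or len(fits) == 0:
        raise ConfigError("fits table is empty")
    missing = [c for c in STRATUM_COLUMNS + ["alpha", "alpha_se"] if c not in fits.columns]
    if missing:
        raise ConfigError(f"fits table missing columns: {missing}")
    baseline_mode = baseline_mode.upper()

    is_base = (fits["mode"].str.upper() == baseline_mode) & (
        fits["energy"].astype(float) == float(baseline_energy)
    )
    plan_rows, unavailable = [], []
    for (scanner, size), group in fits.groupby(["scanner_label", "size_label"], sort=True):
        bases = group[is_base.loc[group.index]]
        targets = group[~is_base.loc[group.index]]
        if mode_filter is not None:
            targets = targets[targets["mode"].str.upper() == mode_filter.upper()]
        if bases.empty:
            unavailable.append(
                {
                    "scanner_label": scanner,
                    "size_label": size,
                    "reason": f"no {baseline_mode} {baseline_energy:g} baseline fit",
                }
            )
            continue
        for _, trow in targets.iterrows():
            match = bases[bases["recon_label"] == trow["recon_label"]]
            if len(match) == 1:
                brow = match.iloc[0]
            elif len(bases) == 1:
                brow = bases.iloc[0]
            else:
                unavailable.append(
                    {
                        "scanner_label": scanner,
                        "size_label": size,
                        "reason": (
                            f"ambiguous baseline for target recon {trow['recon_label']!r}"
                        ),
                    }
                )
                continue
            plan = iodine_reduction(slope_fit_from_row(brow), slope_fit_from_row(trow))
            plan_rows.append(
                {
                    "scanner_label": scanner,
                    "size_label": size,
                    "mode": trow["mode"],
                    "energy": trow["energy"],
                    "recon_label": trow["recon_label"],
                    "baseline_mode": brow["mode"],
                    "baseline_energy": brow["energy"],
                    "baseline_recon": brow["recon_label"],
                    "conc_ratio": plan.conc_ratio,
                    "reduction_pct": plan.reduction_pct,
                    "uncertainty_pct": plan.uncertainty_pct,
                }
            )
    plans = pd.DataFrame(plan_rows, columns=PLAN_COLUMNS)
    if len(plans):
        averages = (
            plans.groupby(["scanner_label", "mode", "energy", "recon_label"], sort=True)
            .agg(
                mean_reduction_pct=("reduction_pct", "mean"),
                n_sizes=("size_label", "nunique"),
            )
            .reset_index()
        )
    else:
        averages = pd.DataFrame(
            columns=["scanner_label", "mode", "energy", "recon_label",
                     "mean_reduction_pct", "n_sizes"]
        )
    unavailable_df = pd.DataFrame(unavailable, columns=["scanner_label", "size_label", "reason"])
    return PlanResult(plans, averages, unavailable_df)
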
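"""Weighted group summaries, bootstrap uncertainty, ICER/dominance, CEAC.

Point estimates are propensity-weighted arm means.  Uncertainty comes from a
nonparametric bootstrap that resamples patients with replacement within each
arm (original arm sizes, patients carrying their matching weights), recomputes
the weighted means, and stores the incremental QALY and cost draws
(baseline-PCT arm minus no-baseline-PCT arm) for the 1-year horizon and the
lifetime horizon.  The draws yield percentile confidence intervals, the
cost-effectiveness plane, and cost-effectiveness acceptability curves
(probability that threshold x dQALY - dCost > 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SUMMARY_COLUMNS",
    "BootstrapDraws",
    "CEAResult",
    "weighted_mean",
    "weighted_summary",
    "bootstrap",
    "icer",
    "ceac",
    "run_cea",
    "remove_ward_outliers",
]

ARM_TEST = "baseline_pct"
ARM_CONTROL = "no_baseline_pct"

#: Outcome columns summarized per arm (Tables 4-5 structure).
SUMMARY_COLUMNS = (
    "ward_days",
    "icu_days",
    "pct_tests",
    "abx_days",
    "qaly_loss_ward",
    "qaly_loss_icu",
    "qaly_loss_abx",
    "cost_ward",
    "cost_icu",
    "cost_pct",
    "cost_drugs",
    "cost_amr",
    "survival_capped",
    "alive_at_1y",
    "baseline_utility",
    "qalys_dt",
    "qalys_total",
    "cost_total",
)


def weighted_mean(values, weights) -> float:
    """Propensity-weighted mean sum(w x) / sum(w); rejects all-zero weights."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("weights sum to zero")
    if (w < 0).any():
        raise ValueError("weights must be positive")
    return float(np.average(np.asarray(values, dtype=float), weights=w))


@dataclass
class BootstrapDraws:
    """Bootstrap draws of per-arm weighted means and incremental quantities."""

    columns: tuple
    arm_means: dict  # arm -> (B, n_columns) array
    seed: int
    B: int

    def col(self, arm: str, column: str) -> np.ndarray:
        return self.arm_means[arm][:, self.columns.index(column)]

    def delta(self, column: str) -> np.ndarray:
        """Test-minus-control draws of a weighted mean."""
        return self.col(ARM_TEST, column) - self.col(ARM_CONTROL, column)


def bootstrap(
    outcomes: pd.DataFrame,
    B: int,
    seed: int,
    columns: Sequence[str] = SUMMARY_COLUMNS,
    chunk: int = 2048,
) -> BootstrapDraws:
    """Within-arm bootstrap of weighted means.

    Each iteration resamples every arm with replacement at its original size;
    resampling is realized as multinomial resampling counts, which is
    distribution-identical and lets the weighted means be computed as matrix
    products in chunks.  Reproducible given ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    columns = tuple(columns)
    rng = np.random.default_rng(seed)
    arm_means = {}
    for arm, g in outcomes.groupby("arm"):
        n = len(g)
        if n < 1:
            raise ValueError(f"arm {arm!r} is empty")
        w = g["weight"].to_numpy(dtype=float)
        if (w <= 0).any():
            raise ValueError("weights must be positive")
        X = g[list(columns)].to_numpy(dtype=float)
        wX = X * w[:, None]
        out = np.empty((B, len(columns)))
        p = np.full(n, 1.0 / n)
        done = 0
        while done < B:
            m = min(chunk, B - done)
            counts = rng.multinomial(n, p, size=m).astype(float)
            num = counts @ wX
            den = counts @ w
            out[done : done + m] = num / den[:, None]
            done += m
        arm_means[arm] = out
    if not arm_means:
        raise ValueError("outcomes contain no arms to resample")
    return BootstrapDraws(columns=columns, arm_means=arm_means, seed=seed, B=B)


def weighted_summary(
    outcomes: pd.DataFrame,
    arm: str,
    draws: Optional[BootstrapDraws] = None,
    columns: Sequence[str] = SUMMARY_COLUMNS,
) -> pd.DataFrame:
    """One arm's weighted means with percentile 95% CIs from bootstrap draws.

    Returns a frame indexed by outcome column with ``mean``, ``ci_low`` and
    ``ci_high`` (CIs NaN when no draws are supplied).
    """
    g = outcomes[outcomes["arm"] == arm]
    if len(g) == 0:
        raise ValueError(f"arm {arm!r} is empty")
    w = g["weight"].to_numpy(dtype=float)
    rows = {}
    for col in columns:
        mean = weighted_mean(g[col].to_numpy(dtype=float), w)
        lo = hi = np.nan
        if draws is not None:
            d = draws.col(arm, col)
            lo, hi = np.percentile(d, [2.5, 97.5])
        rows[col] = {"mean": mean, "ci_low": lo, "ci_high": hi}
    return pd.DataFrame.from_dict(rows, orient="index")


def icer(dE: float, dC: float) -> tuple[float, str]:
    """Incremental cost-effectiveness ratio dC/dE with a quadrant label.

    Labels: ``dominant`` (more QALYs, lower cost), ``dominated`` (fewer
    QALYs, higher cost), ``trade-off`` otherwise; a zero QALY difference
    yields ``undefined`` with a NaN ratio.
    """
    if dE == 0:
        return float("nan"), "undefined"
    if dE > 0 and dC < 0:
        label = "dominant"
    elif dE < 0 and dC > 0:
        label = "dominated"
    else:
        label = "trade-off"
    return dC / dE, label


def ceac(de: np.ndarray, dc: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Probability of cost-effectiveness at each willingness-to-pay threshold.

    For each threshold lambda, the fraction of bootstrap draws with positive
    net monetary benefit lambda x dE - dC (ties count as not cost-effective).
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if (thresholds < 0).any() or (np.diff(thresholds) < 0).any():
        raise ValueError("thresholds must be non-negative and ascending")
    nmb = thresholds[:, None] * de[None, :] - dc[None, :]
    return (nmb > 0).mean(axis=1)


@dataclass
class CEAResult:
    """Cost-effectiveness results for both horizons.

    Costs accrue only in the first year, so the incremental cost is shared by
    the 1-year and lifetime horizons.
    """

    de_dt: float
    de_lifetime: float
    dc: float
    icer_dt: float
    icer_dt_label: str
    icer_lifetime: float
    icer_lifetime_label: str
    icer_dt_ci: tuple
    icer_lifetime_ci: tuple
    thresholds: np.ndarray
    ceac_dt: np.ndarray
    ceac_lifetime: np.ndarray
    draws: BootstrapDraws = field(repr=False, default=None)

    def p_cost_effective(self, threshold: float, horizon: str = "lifetime") -> float:
        curve = self.ceac_lifetime if horizon == "lifetime" else self.ceac_dt
        idx = int(np.argmin(np.abs(self.thresholds - threshold)))
        return float(curve[idx])


def run_cea(
    outcomes: pd.DataFrame,
    B: int,
    seed: int,
    thresholds: np.ndarray,
) -> CEAResult:
    """Point estimates plus bootstrap CEA over the threshold grid."""
    point = {
        arm: weighted_summary(outcomes, arm, columns=("qalys_dt", "qalys_total", "cost_total"))
        for arm in (ARM_TEST, ARM_CONTROL)
    }
    de_dt = point[ARM_TEST].loc["qalys_dt", "mean"] - point[ARM_CONTROL].loc["qalys_dt", "mean"]
    de_lt = (
        point[ARM_TEST].loc["qalys_total", "mean"] - point[ARM_CONTROL].loc["qalys_total", "mean"]
    )
    dc = point[ARM_TEST].loc["cost_total", "mean"] - point[ARM_CONTROL].loc["cost_total", "mean"]
    cols = tuple(c for c in SUMMARY_COLUMNS if c in outcomes.columns)
    draws = bootstrap(outcomes, B=B, seed=seed, columns=cols)
    d_qdt = draws.delta("qalys_dt")
    d_qlt = draws.delta("qalys_total")
    d_c = draws.delta("cost_total")
    icer_dt, label_dt = icer(de_dt, dc)
    icer_lt, label_lt = icer(de_lt, dc)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_dt = d_c / d_qdt
        ratio_lt = d_c / d_qlt
    thresholds = np.asarray(thresholds, dtype=float)
    return CEAResult(
        de_dt=float(de_dt),
        de_lifetime=float(de_lt),
        dc=float(dc),
        icer_dt=icer_dt,
        icer_dt_label=label_dt,
        icer_lifetime=icer_lt,
        icer_lifetime_label=label_lt,
        icer_dt_ci=tuple(np.percentile(ratio_dt[np.isfinite(ratio_dt)], [2.5, 97.5])),
        icer_lifetime_ci=tuple(np.percentile(ratio_lt[np.isfinite(ratio_lt)], [2.5, 97.5])),
        thresholds=thresholds,
        ceac_dt=ceac(d_qdt, d_c, thresholds),
        ceac_lifetime=ceac(d_qlt, d_c, thresholds),
        draws=draws,
    )


def remove_ward_outliers(
    outcomes: pd.DataFrame,
    horizon_days: float = 365.25,
) -> tuple[pd.DataFrame, dict]:
    """Drop patients who spent the full decision-tree year in a general ward.

    Returns the filtered frame and the count removed per arm (robustness
    analysis against extreme length-of-stay outliers).
    """
    mask = outcomes["ward_days"] >= horizon_days
    removed = outcomes[mask].groupby("arm").size().to_dict()
    removed = {arm: int(removed.get(arm, 0)) for arm in outcomes["arm"].unique()}
    return outcomes[~mask].copy(), removed
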
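"""Trend statistics for variant counts across disease stages.

Two per-patient statistics summarize how mitochondrial variant numbers
change through a patient's disease course:

* the **paired difference** of tumor-specific variant counts, relapse
  minus primary (R − P);
* the **trend coefficient** for germline variants: the ordinary
  least-squares slope of the counts over the three stages normal →
  primary → relapse, coded at times 0, 1, 2.  With three equally spaced
  points the slope has the closed form (R − N) / 2.

The cohort-level statistic is the mean of the per-patient values.  Its
null distribution is simulated by Monte Carlo: in each iteration every
per-sample count is replaced by a continuous uniform draw over the range
of the observed counts, the per-patient statistics are rebuilt and their
mean recorded.  The p-value uses the add-one estimator
``(1 + #{|null| >= |observed|}) / (1 + iterations)``, which is never
exactly zero for a finite simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "TrendTestResult",
    "paired_differences",
    "fit_trend",
    "monte_carlo_test",
    "difference_statistic",
    "slope_statistic",
]

Sidedness = Literal["two_sided", "greater", "less"]


@dataclass
class TrendTestResult:
    """Outcome of a Monte Carlo trend test."""

    observed_mean: float
    null_draws: np.ndarray
    p_value: float
    iterations: int
    seed: int | None
    sidedness: Sidedness

    def to_dict(self) -> dict:
        return {
            "observed_mean": self.observed_mean,
            "p_value": self.p_value,
            "iterations": self.iterations,
            "seed": self.seed,
            "sidedness": self.sidedness,
        }


def paired_differences(
    counts: pd.DataFrame, relapse: str = "first"
) -> pd.DataFrame:
    """Per-patient paired difference of tumor-specific counts (R − P).

    ``counts`` needs columns ``patient_id, ts_p, ts_r`` (as produced by
    :func:`mitodyn.variants.count_table`, whose R column already reflects
    the configured relapse collapse).  Returns a frame with columns
    ``patient_id, p_count, r_count, difference``.
    """
    for col in ("patient_id", "ts_p", "ts_r"):
        if col not in counts.columns:
            raise ValueError(f"counts table lacks column {col!r}")
    out = pd.DataFrame({
        "patient_id": counts["patient_id"],
        "p_count": counts["ts_p"].astype(int),
        "r_count": counts["ts_r"].astype(int),
    })
    out["difference"] = out["r_count"] - out["p_count"]
    return out


def fit_trend(n_count: float, p_count: float, r_count: float) -> float:
    """OLS slope of three stage counts at time codes 0, 1, 2.

    Equals ``(r_count - n_count) / 2`` — the middle point does not move
    the slope of three equally spaced observations.
    """
    return (r_count - n_count) / 2.0


def difference_statistic(counts: np.ndarray) -> np.ndarray:
    """Per-patient R − P from an (..., n_patients, 2) count array."""
    return counts[..., 1] - counts[..., 0]


def slope_statistic(counts: np.ndarray) -> np.ndarray:
    """Per-patient OLS slope from an (..., n_patients, 3) count array."""
    return (counts[..., 2] - counts[..., 0]) / 2.0


def monte_carlo_test(
    counts: np.ndarray | pd.DataFrame,
    statistic: Callable[[np.ndarray], np.ndarray],
    iterations: int = 10_000,
    seed: int | None = None,
    sidedness: Sidedness = "two_sided",
    range_mode: Literal["pooled", "per_role"] = "pooled",
) -> TrendTestResult:
    """Monte Carlo test of ``mean(per-patient statistic) == 0``.

    Parameters
    ----------
    counts:
        Observed per-patient, per-stage counts, shape ``(n_patients,
        n_stages)`` — (P, R) columns for the difference test, (N, P, R)
        for the slope test.
    statistic:
        Maps a count array to per-patient statistics along the last axis;
        must broadcast over leading axes (see
        :func:`difference_statistic`, :func:`slope_statistic`).
    range_mode:
        ``pooled`` (default) draws every surrogate count uniformly on the
        [min, max] of all observed counts pooled across stages;
        ``per_role`` bounds each stage's surrogates by that stage's own
        observed range.
    """
    arr = np.asarray(
        counts.drop(columns="patient_id") if isinstance(counts, pd.DataFrame)
        and "patient_id" in counts.columns else counts,
        dtype=float,
    )
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need a 2-D count array with >= 2 patients")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")

    n_patients, n_stages = arr.shape
    observed_mean = float(np.mean(statistic(arr)))

    rng = np.random.default_rng(seed)
    if range_mode == "pooled":
        lo = np.full(n_stages, arr.min())
        hi = np.full(n_stages, arr.max())
    elif range_mode == "per_role":
        lo = arr.min(axis=0)
        hi = arr.max(axis=0)
    else:
        raise ValueError(f"unknown range_mode {range_mode!r}")
    draws = rng.uniform(lo, hi, size=(iterations, n_patients, n_stages))
    null_means = statistic(draws).mean(axis=1)

    if sidedness == "two_sided":
        extreme = np.abs(null_means) >= abs(observed_mean)
    elif sidedness == "greater":
        extreme = null_means >= observed_mean
    elif sidedness == "less":
        extreme = null_means <= observed_mean
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    p_value = (1 + int(extreme.sum())) / (1 + iterations)

    return TrendTestResult(
        observed_mean=observed_mean,
        null_draws=null_means,
        p_value=p_value,
        iterations=iterations,
        seed=seed,
        sidedness=sidedness,
    )
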
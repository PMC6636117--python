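"""Interim analysis: matching-rate estimation and sample-size recalculation.

Two strategies are implemented.

*Resampling CI method* (the proposed design).  The treated arm at interim
holds ``n_treated_interim`` patients.  b times (default 200): draw
``n_treated_interim`` controls without replacement, fit the propensity model
on the sampled controls plus all interim treated, match 1:1 within the
caliper, and record the matching rate (denominator = the common arm size;
the arms are equal by construction, which deliberately biases the rate
*downward* relative to matching against the full control pool).  The mean
resampling rate mr_bar is then converted into a one-sided lower confidence
limit

    l_mr = mr_bar - z_{1-alpha_CI} * sqrt(mr_bar * (1 - mr_bar) / n_control)

and the recalculated treated-arm requirement is

    n_treated_final = ceil(n_control / l_mr).

*Naive method*.  A single match of all interim treated against all controls;
its rate (denominator = the treated arm, the limiting arm at interim)
directly rescales the sample size.  The naive rate systematically
overestimates the final matching rate because each treated patient can draw
on the full diversity of the control pool.

Degenerate inputs: covariates constant in the sample at hand are dropped
before the fit (with a warning); if none remain, an intercept-only model is
used, all logits coincide, every distance is 0, and the rate is 1.  A
configurable floor (default 0.05) clamps l_mr before the division so a tiny
interim sample cannot request an unbounded cohort.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .matching import (
    DEFAULT_CALIPER_MULTIPLIER,
    PropensityFitError,
    _eta_or_fallback,
    _match_count,
    compute_caliper,
)

logger = logging.getLogger("adaptmatch")

DEFAULT_B = 200
DEFAULT_ALPHA_CI = 0.01
DEFAULT_RATE_FLOOR = 0.05


@dataclass
class InterimResult:
    """Result of one interim analysis (either method)."""

    method: str  # 'resampling_ci' | 'naive'
    resample_rates: list[float]
    mean_rate: float
    lower_limit: float
    n_control: int
    n_treated_interim: int
    n_treated_final: int
    alpha_ci: Optional[float] = None
    rate_floor_applied: bool = False

    def __post_init__(self) -> None:
        if self.method not in ("resampling_ci", "naive"):
            raise ValueError(f"unknown interim method {self.method!r}")
        finite = [r for r in self.resample_rates if not math.isnan(r)]
        if not finite:
            raise ValueError("no valid resampling rates")
        if not all(0.0 <= r <= 1.0 for r in finite):
            raise ValueError("resampling rates must lie in [0, 1]")
        if not math.isclose(self.mean_rate, float(np.mean(finite)),
                            rel_tol=0, abs_tol=1e-12):
            raise ValueError("mean_rate must equal the mean of resample_rates")
        if self.lower_limit > self.mean_rate + 1e-12 and not self.rate_floor_applied:
            raise ValueError("lower_limit cannot exceed mean_rate")
        if self.lower_limit <= 1.0 and self.n_treated_final < self.n_control:
            raise ValueError("n_treated_final below n_control despite lower_limit <= 1")

    def to_record(self) -> dict:
        """Flat key-value report row."""
        return {
            "method": self.method,
            "b": len(self.resample_rates),
            "alpha_ci": self.alpha_ci,
            "mean_rate": self.mean_rate,
            "lower_limit": self.lower_limit,
            "n_control": self.n_control,
            "n_treated_interim": self.n_treated_interim,
            "n_treated_final": self.n_treated_final,
        }


def _design_matrix(subjects: pd.DataFrame, covariate_names: Sequence[str]) -> np.ndarray:
    return np.column_stack(
        [np.ones(len(subjects))]
        + [subjects[c].to_numpy(dtype=float) for c in covariate_names]
    )


def _fit_scores_with_fallback(
    subjects: pd.DataFrame, covariate_names: Sequence[str]
) -> np.ndarray:
    """Logit propensity scores, tolerating sample-constant covariates.

    Constant covariates are dropped (warning logged) down to an
    intercept-only fit; raises :class:`PropensityFitError` on
    non-convergence/separation.
    """
    z = subjects["z"].to_numpy(dtype=float)
    X = _design_matrix(subjects, covariate_names)
    return _eta_or_fallback(X, z)


def _match_rate_once(
    controls: pd.DataFrame,
    treated: pd.DataFrame,
    covariate_names: Sequence[str],
    caliper_multiplier: float,
    rng: np.random.Generator,
    denominator: int,
) -> float:
    """Fit + caliper + greedy match on the given arms; one matching rate."""
    combined = pd.concat([controls, treated], axis=0)
    eta = _fit_scores_with_fallback(combined, covariate_names)
    n_c = len(controls)
    c_logits = eta[:n_c]
    t_logits = eta[n_c:]
    caliper = compute_caliper(eta, caliper_multiplier)
    n_pairs = _match_count(t_logits, c_logits, caliper, rng)
    return n_pairs / denominator


def resampling_interim(
    controls: pd.DataFrame,
    treated: pd.DataFrame,
    b: int,
    covariate_names: Sequence[str],
    caliper_multiplier: float = DEFAULT_CALIPER_MULTIPLIER,
    rng: Optional[np.random.Generator] = None,
) -> list[float]:
    """The b resampling matching rates of the proposed interim procedure.

    Each resample draws ``len(treated)`` controls without replacement,
    re-fits the propensity model on the equal-sized arms, re-derives the
    caliper from that sample's pooled logits, matches 1:1 and records
    pairs / n_treated_interim.  A resample whose fit fails is redrawn once;
    two consecutive failures leave NaN in that slot (the mean later uses the
    available rates).
    """
    if rng is None:
        rng = np.random.default_rng()
    n_t = len(treated)
    n_c = len(controls)
    if n_t > n_c:
        raise ValueError("treated arm larger than control arm at interim")
    if n_t < 2:
        raise ValueError("need at least 2 treated subjects at interim")
    if b < 1:
        raise ValueError("b must be >= 1")

    # precompute design matrices once; each resample only indexes rows
    names = list(covariate_names)
    Xc = _design_matrix(controls, names)
    Xt = _design_matrix(treated, names)
    y = np.concatenate([np.zeros(n_t), np.ones(n_t)])

    rates: list[float] = []
    n_failed = 0
    for _ in range(b):
        rate = math.nan
        for _attempt in range(2):
            idx = rng.choice(n_c, size=n_t, replace=False)
            X = np.concatenate((Xc[idx], Xt))
            try:
                eta = _eta_or_fallback(X, y)
            except PropensityFitError:
                continue
            caliper = compute_caliper(eta, caliper_multiplier)
            n_pairs = _match_count(eta[n_t:], eta[:n_t], caliper, rng)
            rate = n_pairs / n_t
            break
        if math.isnan(rate):
            n_failed += 1
        rates.append(rate)
    if n_failed:
        logger.warning("%d of %d resamples failed the propensity fit twice; "
                       "their rates are missing", n_failed, b)
    if n_failed == b:
        raise PropensityFitError("every resample failed the propensity fit")
    return rates


def mean_resampling_rate(rates: Sequence[float]) -> float:
    """Arithmetic mean of the (available) resampling matching rates."""
    arr = np.asarray(list(rates), dtype=float)
    if arr.size == 0:
        raise ValueError("rates must be non-empty")
    finite = arr[~np.isnan(arr)]
    if finite.size == 0:
        raise ValueError("all rates are missing")
    return float(finite.mean())


def lower_ci_limit(mean_rate: float, alpha_ci: float, n_control: int) -> float:
    """One-sided lower limit of the 100(1-alpha_CI)% CI for the matching rate.

    Normal approximation with the binomial standard error evaluated at
    ``n_control``; may be <= 0 for small rates (callers guard via the floor).
    """
    if not 0.0 <= mean_rate <= 1.0:
        raise ValueError("mean_rate must lie in [0, 1]")
    if not 0.0 < alpha_ci < 1.0:
        raise ValueError("alpha_ci must lie in (0, 1)")
    if n_control < 1:
        raise ValueError("n_control must be >= 1")
    z = norm.ppf(1.0 - alpha_ci)
    return float(mean_rate - z * math.sqrt(mean_rate * (1.0 - mean_rate) / n_control))


def recalc_sample_size(n_control: int, lower_limit: float) -> int:
    """Recalculated treated-arm requirement: ceil(n_control / lower_limit)."""
    if lower_limit <= 0:
        raise ValueError(
            "lower_limit must be > 0; apply the rate floor guard before "
            "recalculating the sample size"
        )
    if n_control < 1:
        raise ValueError("n_control must be >= 1")
    return math.ceil(n_control / lower_limit)


def naive_interim(
    controls: pd.DataFrame,
    treated: pd.DataFrame,
    covariate_names: Sequence[str],
    caliper_multiplier: float = DEFAULT_CALIPER_MULTIPLIER,
    rng: Optional[np.random.Generator] = None,
    rate_floor: float = DEFAULT_RATE_FLOOR,
) -> InterimResult:
    """Single interim match of all treated against all controls.

    The rate (denominator = the treated arm) rescales the sample size
    directly: ``n_treated_final = ceil(n_control / rate)``.  A zero rate
    leaves the sample size undefined and raises.
    """
    if rng is None:
        rng = np.random.default_rng()
    if len(controls) == 0 or len(treated) == 0:
        raise ValueError("both arms must be non-empty at interim")
    n_t = len(treated)
    n_c = len(controls)
    rate = _match_rate_once(controls.reset_index(drop=True),
                            treated.reset_index(drop=True),
                            list(covariate_names), caliper_multiplier, rng,
                            denominator=n_t)
    if rate == 0.0:
        raise ValueError("naive interim matching rate is 0; sample size undefined")
    floored = max(rate, rate_floor)
    return InterimResult(
        method="naive",
        resample_rates=[rate],
        mean_rate=rate,
        lower_limit=rate,
        n_control=n_c,
        n_treated_interim=n_t,
        n_treated_final=recalc_sample_size(n_c, floored),
        alpha_ci=None,
        rate_floor_applied=floored != rate,
    )


def run_interim(
    method: str,
    controls: pd.DataFrame,
    treated: pd.DataFrame,
    b: int = DEFAULT_B,
    alpha_ci: float = DEFAULT_ALPHA_CI,
    covariate_names: Sequence[str] = ("x2", "x3", "x5"),
    caliper_multiplier: float = DEFAULT_CALIPER_MULTIPLIER,
    rng: Optional[np.random.Generator] = None,
    rate_floor: float = DEFAULT_RATE_FLOOR,
) -> InterimResult:
    """Dispatch to the resampling CI method or the naive comparator.

    For the resampling method: b resampling rates -> mean -> one-sided lower
    CI limit -> recalculated n_treated_final, with the floor guard applied
    to the lower limit before the division.
    """
    if rng is None:
        rng = np.random.default_rng()
    if method == "naive":
        return naive_interim(controls, treated, covariate_names,
                             caliper_multiplier, rng, rate_floor)
    if method != "resampling_ci":
        raise ValueError(f"unknown interim method {method!r}")
    rates = resampling_interim(controls, treated, b, covariate_names,
                               caliper_multiplier, rng)
    mean_rate = mean_resampling_rate(rates)
    n_c = len(controls)
    lower = lower_ci_limit(mean_rate, alpha_ci, n_c)
    floored = max(lower, rate_floor)
    if floored != lower:
        logger.warning("lower CI limit %.4f clamped to floor %.2f before the "
                       "sample-size recalculation", lower, rate_floor)
    return InterimResult(
        method="resampling_ci",
        resample_rates=rates,
        mean_rate=mean_rate,
        lower_limit=lower,
        n_control=n_c,
        n_treated_interim=len(treated),
        n_treated_final=recalc_sample_size(n_c, floored),
        alpha_ci=alpha_ci,
        rate_floor_applied=floored != lower,
    )
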
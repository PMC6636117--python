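"""Monte-Carlo simulation study of the adaptive matched-trial design.

One replication runs the full design once under a scenario configuration:

1. recruit ``n_control`` controls and ``round(interim_fraction * n_control)``
   treated subjects by sequential accrual;
2. run the configured interim method (resampling CI or naive), yielding the
   recalculated treated-arm requirement ``n_treated_final``;
3. recruit further treated subjects up to that requirement;
4. perform the final match on the complete cohort (rate denominator:
   controls);
5. test the matched outcomes with the one-sided McNemar test.

Replications use independent, reproducible RNG streams derived from
``(master_seed, replication index)``.  Aggregation over replications yields
the operating characteristics: mean interim/final matching rates, mean
recruited treated-arm size, and the rejection rate (type I error under H0,
power under H1), each with its Monte-Carlo standard error.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .analysis import final_match, mcnemar_one_sided, paired_outcomes
from .cohort import Cohort, OutcomeModel, extend_treated, recruit_cohort
from .interim import DEFAULT_B, DEFAULT_RATE_FLOOR, run_interim
from .matching import DEFAULT_CALIPER_MULTIPLIER, PropensityFitError

logger = logging.getLogger("adaptmatch")

#: below this many subjects in the interim matching step, matching partners
#: become hard to find and the resampling estimate is unreliable
MIN_INTERIM_TREATED = 15

DEFAULT_COVARIATES = ("x2", "x3", "x5")


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario (a single grid point)."""

    n_control: int = 150
    interim_fraction: float = 0.5
    method: str = "resampling_ci"  # or 'naive'
    hypothesis: str = "H1"
    beta_z: float = 1.0
    alpha_ci: Optional[float] = 0.01
    b: int = DEFAULT_B
    caliper_multiplier: float = DEFAULT_CALIPER_MULTIPLIER
    n_reps: int = 1000
    master_seed: int = 0
    covariate_names: tuple = DEFAULT_COVARIATES
    test_alpha: float = 0.05
    rate_floor: float = DEFAULT_RATE_FLOOR
    allow_small_interim: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.interim_fraction <= 1.0:
            raise ValueError("interim_fraction must lie in (0, 1]")
        if self.method not in ("resampling_ci", "naive"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.n_treated_interim < 2:
            raise ValueError("interim treated arm must hold at least 2 subjects")
        if (self.n_treated_interim < MIN_INTERIM_TREATED
                and not self.allow_small_interim):
            raise ValueError(
                f"n_treated_interim={self.n_treated_interim} < "
                f"{MIN_INTERIM_TREATED}: matching partners become hard to find "
                "in so small an interim sample; set allow_small_interim=True "
                "to override"
            )

    @property
    def n_treated_interim(self) -> int:
        return int(round(self.interim_fraction * self.n_control))

    def outcome_model(self) -> OutcomeModel:
        return OutcomeModel(hypothesis=self.hypothesis, beta_z=self.beta_z)


@dataclass
class ReplicationRecord:
    interim_rate: float
    lower_limit: float
    n_treated_final: int
    final_rate: float
    n_pairs: int
    reject: bool
    fit_failures: int = 0


@dataclass
class StudyMetrics:
    """Monte-Carlo aggregates for one scenario, with standard errors."""

    config: ScenarioConfig
    n_reps_done: int
    n_reps_failed: int
    mean_interim_rate: float
    mean_lower_limit: float
    mean_final_rate: float
    mean_n_treated_final: float
    rejection_rate: float
    se_interim_rate: float
    se_lower_limit: float
    se_final_rate: float
    se_n_treated_final: float
    se_rejection_rate: float

    def to_record(self) -> dict:
        c = self.config
        return {
            "method": c.method, "n_control": c.n_control,
            "interim_fraction": c.interim_fraction, "alpha_ci": c.alpha_ci,
            "hypothesis": c.hypothesis, "beta_z": c.beta_z,
            "n_reps": self.n_reps_done, "n_failed": self.n_reps_failed,
            "mean_interim_rate": self.mean_interim_rate,
            "mean_lower_limit": self.mean_lower_limit,
            "mean_final_rate": self.mean_final_rate,
            "mean_n_treated_final": self.mean_n_treated_final,
            "rejection_rate": self.rejection_rate,
            "se_interim_rate": self.se_interim_rate,
            "se_lower_limit": self.se_lower_limit,
            "se_final_rate": self.se_final_rate,
            "se_n_treated_final": self.se_n_treated_final,
            "se_rejection_rate": self.se_rejection_rate,
        }


def _replication_rng(master_seed: int, rep_index: int) -> np.random.Generator:
    return np.random.default_rng([int(master_seed), int(rep_index)])


def run_replication(config: ScenarioConfig, rep_index: int) -> ReplicationRecord:
    """Run the full adaptive design once; deterministic in (seed, index)."""
    rng = _replication_rng(config.master_seed, rep_index)
    model = config.outcome_model()
    cohort = recruit_cohort(config.n_control, config.n_treated_interim,
                            model, rng)
    interim = run_interim(
        config.method, cohort.controls, cohort.treated,
        b=config.b, alpha_ci=config.alpha_ci or 0.01,
        covariate_names=config.covariate_names,
        caliper_multiplier=config.caliper_multiplier,
        rng=rng, rate_floor=config.rate_floor,
    )
    additional = interim.n_treated_final - cohort.n_treated
    if additional > 0:
        cohort = extend_treated(cohort, additional, model, rng)
    result = final_match(cohort, config.covariate_names,
                         config.caliper_multiplier, rng)
    table = paired_outcomes(result.pairs, cohort)
    test = mcnemar_one_sided(table, alpha=config.test_alpha)
    return ReplicationRecord(
        interim_rate=interim.mean_rate,
        lower_limit=interim.lower_limit,
        n_treated_final=interim.n_treated_final,
        final_rate=result.matching_rate,
        n_pairs=result.n_pairs,
        reject=test.reject,
        fit_failures=sum(1 for r in interim.resample_rates if np.isnan(r)),
    )


def run_study(config: ScenarioConfig, progress: bool = False) -> StudyMetrics:
    """Run ``config.n_reps`` replications and aggregate the metrics.

    Replications whose propensity fit fails irrecoverably (naive interim or
    final match) are dropped and counted; more than 5% such failures aborts
    the study as a broken configuration.
    """
    if config.n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    records: list[ReplicationRecord] = []
    n_failed = 0
    for r in range(config.n_reps):
        try:
            records.append(run_replication(config, r))
        except (PropensityFitError, ValueError) as exc:
            n_failed += 1
            logger.warning("replication %d failed: %s", r, exc)
        if progress and (r + 1) % 200 == 0:
            logger.info("scenario %s n=%d: %d/%d replications",
                        config.method, config.n_control, r + 1, config.n_reps)
    if n_failed > 0.05 * config.n_reps:
        raise RuntimeError(
            f"{n_failed}/{config.n_reps} replications failed; "
            "the scenario configuration looks broken"
        )

    def mom(values: np.ndarray) -> tuple[float, float]:
        m = float(np.mean(values))
        se = float(np.std(values, ddof=1) / np.sqrt(len(values))) if len(values) > 1 else 0.0
        return m, se

    ir = np.array([rec.interim_rate for rec in records])
    ll = np.array([rec.lower_limit for rec in records])
    fr = np.array([rec.final_rate for rec in records])
    nf = np.array([rec.n_treated_final for rec in records], dtype=float)
    rj = np.array([rec.reject for rec in records], dtype=float)
    m_ir, s_ir = mom(ir)
    m_ll, s_ll = mom(ll)
    m_fr, s_fr = mom(fr)
    m_nf, s_nf = mom(nf)
    p_rej = float(rj.mean())
    se_rej = float(np.sqrt(p_rej * (1 - p_rej) / len(rj)))
    return StudyMetrics(
        config=config, n_reps_done=len(records), n_reps_failed=n_failed,
        mean_interim_rate=m_ir, mean_lower_limit=m_ll, mean_final_rate=m_fr,
        mean_n_treated_final=m_nf, rejection_rate=p_rej,
        se_interim_rate=s_ir, se_lower_limit=s_ll, se_final_rate=s_fr,
        se_n_treated_final=s_nf, se_rejection_rate=se_rej,
    )


def run_grid(
    base_config: ScenarioConfig,
    vary: dict[str, Sequence],
    progress: bool = False,
) -> pd.DataFrame:
    """Run one scenario per point of the cartesian grid ``vary``.

    Returns a tidy frame with one row per grid point; scenarios that fail
    are reported (``error`` column) and the rest of the grid continues.
    """
    if not vary:
        raise ValueError("vary must name at least one parameter")
    keys = list(vary.keys())
    rows = []
    for values in itertools.product(*(vary[k] for k in keys)):
        overrides = dict(zip(keys, values))
        try:
            cfg = replace(base_config, **overrides)
            metrics = run_study(cfg, progress=progress)
            row = metrics.to_record()
            row["error"] = ""
        except Exception as exc:
            row = {"error": str(exc), **overrides}
            logger.error("grid point %s failed: %s", overrides, exc)
        rows.append(row)
    return pd.DataFrame(rows)
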
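"""Synthetic cohort generation for a prospective matched case-control trial.

The generator emulates a two-arm observational setting in acute ischemic
stroke: an external control arm (e.g. the conscious-sedation arm of an
earlier randomized trial) and a prospectively recruited treated arm.  Arms
are *not* randomized — group membership follows a logistic model in baseline
covariates, and two clinical severity scores are drawn from arm-specific
distributions, so the arms differ systematically in ways a propensity-score
matching step must correct.

Covariates (independent given the arm):

==========  =======================  ========================================
variable    interpretation           distribution
==========  =======================  ========================================
``x1``      binary (e.g. sex)        Bernoulli(0.5), both arms
``x2``      binary (e.g. diabetes)   Bernoulli(0.2), both arms
``x3``      continuous (age-like)    Normal(mean 70, sd 15), both arms
``z``       arm indicator            logit P(z=1) = -0.6 + 0.35 x1 - 0.01 x3
``x4``      ordinal 0..10 (ASPECTS)  Binomial(10, 0.80) control /
                                     Binomial(10, 0.75) treated
``x5``      continuous (NIHSS-like)  Normal(17, 5) control / Normal(16, 4)
``y``       binary outcome           H0: Bernoulli(0.5) both arms;
                                     H1: logit P(y=1) = -0.5 + beta_z z
                                     + 0.2 x4
==========  =======================  ========================================

Recruitment is sequential: candidate subjects arrive one at a time, the arm
is drawn from the assignment model, and a candidate is kept only while its
arm's quota is unfilled.  Accepted subjects are therefore i.i.d. draws from
the covariate distribution *conditional on arm*, which is exactly the
covariate–arm dependence the assignment model is meant to induce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Literal, Optional, Union

import numpy as np
import pandas as pd
from scipy.special import expit

logger = logging.getLogger("adaptmatch")

ARM_CONTROL = 0
ARM_TREATED = 1

#: canonical column order for simulated subject tables
SUBJECT_COLUMNS = ["x1", "x2", "x3", "x4", "x5", "z", "y"]


class RecruitmentError(RuntimeError):
    """Quotas could not be filled within the candidate cap.

    Signals degenerate assignment probabilities (one arm essentially never
    drawn) rather than bad luck: the cap is generous relative to the quotas.
    """


@dataclass(frozen=True)
class OutcomeModel:
    """Binary-outcome model for simulated subjects.

    Under ``H0`` the outcome is Bernoulli(``h0_rate``) in both arms (no
    treatment effect); under ``H1`` it follows a logistic model in the arm
    indicator and the ordinal severity score x4.  ``beta_z`` is the log
    odds-ratio of the treatment effect: 2 / 1 / 0.55 are the values that give
    roughly 80% power at control-arm sizes 50 / 150 / 500.
    """

    hypothesis: Literal["H0", "H1"] = "H1"
    beta_intercept: float = -0.5
    beta_z: float = 1.0
    beta_x4: float = 0.2
    h0_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.hypothesis not in ("H0", "H1"):
            raise ValueError(f"hypothesis must be 'H0' or 'H1', got {self.hypothesis!r}")
        if not 0.0 < self.h0_rate < 1.0:
            raise ValueError(f"h0_rate must lie in (0, 1), got {self.h0_rate}")

    def success_probability(self, z: np.ndarray, x4: np.ndarray) -> np.ndarray:
        """P(y=1) for subjects with arm ``z`` and severity score ``x4``."""
        if self.hypothesis == "H0":
            return np.full(np.shape(z), self.h0_rate, dtype=float)
        return expit(self.beta_intercept + self.beta_z * np.asarray(z, dtype=float)
                     + self.beta_x4 * np.asarray(x4, dtype=float))


@dataclass
class Subject:
    """One trial participant."""

    x1: int
    x2: int
    x3: float
    x4: int
    x5: float
    z: int
    y: Optional[int] = None

    def __post_init__(self) -> None:
        if self.z not in (ARM_CONTROL, ARM_TREATED):
            raise ValueError(f"z must be 0 or 1, got {self.z}")
        if not (isinstance(self.x4, (int, np.integer)) and 0 <= self.x4 <= 10):
            raise ValueError(f"x4 must be an integer in [0, 10], got {self.x4}")
        if self.y is not None and self.y not in (0, 1):
            raise ValueError(f"y must be 0, 1 or None, got {self.y}")


def group_assignment_probability(
    x1: Union[float, np.ndarray], x3: Union[float, np.ndarray]
) -> Union[float, np.ndarray]:
    """Probability of assignment to the treated arm given x1 and x3.

    The assignment model is logistic: logit P(z=1) = -0.6 + 0.35*x1 - 0.01*x3.
    Strictly inside (0, 1) for finite inputs.
    """
    return expit(-0.6 + 0.35 * np.asarray(x1, dtype=float) - 0.01 * np.asarray(x3, dtype=float))


# arm-specific clinical-score parameters: (x4 binomial p, x5 mean, x5 sd)
_ARM_PARAMS = {
    ARM_CONTROL: (0.80, 17.0, 5.0),
    ARM_TREATED: (0.75, 16.0, 4.0),
}


def simulate_subject(
    arm: Union[int, Literal["random"]],
    outcome_model: OutcomeModel,
    rng: np.random.Generator,
) -> Subject:
    """Draw a single subject; ``arm`` is 0, 1, or ``"random"``.

    With ``arm="random"`` the arm indicator is Bernoulli with probability
    from :func:`group_assignment_probability`; otherwise it is fixed and the
    assignment model is bypassed.
    """
    x1 = int(rng.binomial(1, 0.5))
    x2 = int(rng.binomial(1, 0.2))
    x3 = float(rng.normal(70.0, 15.0))
    if arm == "random":
        z = int(rng.random() < group_assignment_probability(x1, x3))
    else:
        z = int(arm)
        if z not in (ARM_CONTROL, ARM_TREATED):
            raise ValueError(f"arm must be 0, 1 or 'random', got {arm!r}")
    p4, mu5, sd5 = _ARM_PARAMS[z]
    x4 = int(rng.binomial(10, p4))
    x5 = float(rng.normal(mu5, sd5))
    p_y = float(outcome_model.success_probability(np.array(z), np.array(x4)))
    y = int(rng.random() < p_y)
    return Subject(x1=x1, x2=x2, x3=x3, x4=x4, x5=x5, z=z, y=y)


def _simulate_candidates(
    n: int,
    outcome_model: OutcomeModel,
    rng: np.random.Generator,
    assignment_prob: Optional[float] = None,
) -> pd.DataFrame:
    """Vectorized draw of ``n`` candidate subjects with random arm.

    ``assignment_prob`` overrides the logistic assignment model with a
    constant (a test hook: 0.5 makes the baseline covariates independent of
    the arm).
    """
    x1 = rng.binomial(1, 0.5, size=n)
    x2 = rng.binomial(1, 0.2, size=n)
    x3 = rng.normal(70.0, 15.0, size=n)
    if assignment_prob is None:
        p_z = group_assignment_probability(x1, x3)
    else:
        p_z = np.full(n, float(assignment_prob))
    z = (rng.random(n) < p_z).astype(np.int64)
    p4 = np.where(z == ARM_TREATED, 0.75, 0.80)
    mu5 = np.where(z == ARM_TREATED, 16.0, 17.0)
    sd5 = np.where(z == ARM_TREATED, 4.0, 5.0)
    x4 = rng.binomial(10, p4)
    x5 = rng.normal(mu5, sd5)
    y = rng.binomial(1, outcome_model.success_probability(z, x4))
    return pd.DataFrame(
        {"x1": x1, "x2": x2, "x3": x3, "x4": x4, "x5": x5, "z": z, "y": y}
    )


@dataclass
class Cohort:
    """Two-arm cohort: ``controls`` (z=0) and ``treated`` (z=1) DataFrames.

    Subject ids are the DataFrame index (unique across arms).  Columns hold
    the covariates, the arm indicator ``z``, and (optionally) the outcome
    ``y``; trial-mode cohorts loaded from file may carry arbitrary covariate
    columns.
    """

    controls: pd.DataFrame
    treated: pd.DataFrame
    rng_seed: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for df, arm, name in ((self.controls, ARM_CONTROL, "controls"),
                              (self.treated, ARM_TREATED, "treated")):
            if "z" not in df.columns:
                raise ValueError(f"{name} frame lacks an arm column 'z'")
            if len(df) and not (df["z"] == arm).all():
                raise ValueError(f"every subject in {name} must have z={arm}")
        ids = self.controls.index.append(self.treated.index)
        if ids.has_duplicates:
            raise ValueError("subject ids must be unique across arms")

    @property
    def n_control(self) -> int:
        return len(self.controls)

    @property
    def n_treated(self) -> int:
        return len(self.treated)

    def all_subjects(self) -> pd.DataFrame:
        """Both arms stacked, controls first, original ids preserved."""
        return pd.concat([self.controls, self.treated], axis=0)

    def subjects(self) -> Iterator[Subject]:
        for _, row in self.all_subjects().iterrows():
            y = row.get("y")
            yield Subject(
                x1=int(row["x1"]), x2=int(row["x2"]), x3=float(row["x3"]),
                x4=int(row["x4"]), x5=float(row["x5"]), z=int(row["z"]),
                y=None if pd.isna(y) else int(y),
            )


def _sequential_accept(
    quota_control: int,
    quota_treated: int,
    outcome_model: OutcomeModel,
    rng: np.random.Generator,
    assignment_prob: Optional[float],
    max_candidates: Optional[int],
) -> pd.DataFrame:
    """Generate candidates and keep them sequentially until quotas are met."""
    if max_candidates is None:
        # generous: both arm probabilities are bounded well away from 0 under
        # the default assignment model (~0.26-0.38 treated)
        max_candidates = 200 * (quota_control + quota_treated) + 10_000
    need_c, need_t = quota_control, quota_treated
    chunks: list[pd.DataFrame] = []
    drawn = 0
    while need_c > 0 or need_t > 0:
        m = min(max(64, 3 * (need_c + need_t)), max_candidates - drawn)
        if m <= 0:
            raise RecruitmentError(
                f"quotas ({quota_control} control, {quota_treated} treated) not met "
                f"after {drawn} candidates; assignment probabilities look degenerate"
            )
        batch = _simulate_candidates(m, outcome_model, rng, assignment_prob)
        drawn += m
        is_c = batch["z"].to_numpy() == ARM_CONTROL
        rank_c = np.cumsum(is_c)
        rank_t = np.cumsum(~is_c)
        keep = (is_c & (rank_c <= need_c)) | (~is_c & (rank_t <= need_t))
        kept = batch.loc[keep]
        need_c -= int((kept["z"] == ARM_CONTROL).sum())
        need_t -= int((kept["z"] == ARM_TREATED).sum())
        chunks.append(kept)
    out = pd.concat(chunks, axis=0, ignore_index=True)
    return out


def recruit_cohort(
    n_control: int,
    n_treated: int,
    outcome_model: OutcomeModel,
    rng: np.random.Generator,
    assignment_prob: Optional[float] = None,
    max_candidates: Optional[int] = None,
) -> Cohort:
    """Recruit a cohort with exactly ``n_control`` controls and ``n_treated`` treated.

    Sequential accrual: each candidate's arm is drawn from the assignment
    model and the candidate is discarded if that arm's quota is already
    full.  Raises :class:`RecruitmentError` if the quotas cannot be met
    within a generous candidate cap.
    """
    if n_control < 1:
        raise ValueError("n_control must be >= 1")
    if n_treated < 0:
        raise ValueError("n_treated must be >= 0")
    accepted = _sequential_accept(
        n_control, n_treated, outcome_model, rng, assignment_prob, max_candidates
    )
    controls = accepted[accepted["z"] == ARM_CONTROL].reset_index(drop=True)
    treated = accepted[accepted["z"] == ARM_TREATED].reset_index(drop=True)
    treated.index = pd.RangeIndex(n_control, n_control + len(treated))
    return Cohort(controls=controls, treated=treated)


def extend_treated(
    cohort: Cohort,
    additional: int,
    outcome_model: OutcomeModel,
    rng: np.random.Generator,
    assignment_prob: Optional[float] = None,
    max_candidates: Optional[int] = None,
) -> Cohort:
    """Recruit ``additional`` further treated subjects into a copy of ``cohort``.

    Post-interim accrual uses the same sequential mechanism; candidates
    assigned to the control arm are discarded (that quota is closed).
    Controls are unchanged; new treated subjects get fresh ids.
    """
    if additional < 0:
        raise ValueError("additional must be >= 0")
    if additional == 0:
        return Cohort(controls=cohort.controls, treated=cohort.treated,
                      rng_seed=cohort.rng_seed, meta=dict(cohort.meta))
    new = _sequential_accept(0, additional, outcome_model, rng,
                             assignment_prob, max_candidates)
    start = int(max(cohort.controls.index.max() if len(cohort.controls) else -1,
                    cohort.treated.index.max() if len(cohort.treated) else -1)) + 1
    new.index = pd.RangeIndex(start, start + len(new))
    treated = pd.concat([cohort.treated, new], axis=0)
    return Cohort(controls=cohort.controls, treated=treated,
                  rng_seed=cohort.rng_seed, meta=dict(cohort.meta))
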
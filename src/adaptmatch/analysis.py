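"""Final analysis: full-cohort matching and the one-sided McNemar test.

At the final analysis the propensity model is re-fitted on the complete
cohort, the caliper is re-derived from the pooled logit scores, and all
treated subjects are matched 1:1 against all controls.  The final matching
rate uses the *control* arm as denominator — the design goal is to find a
partner for every control patient.

The matched binary outcomes are tested with a McNemar-type test on the
discordant pair counts, one-sided for superiority of the treated arm
(H0: p_control >= p_treated vs H1: p_control < p_treated):

    z = (n10 - n01) / sqrt(n10 + n01),    p = 1 - Phi(z),

where n10 counts pairs with treated success / control failure and n01 the
reverse.  The asymptotic z-form without continuity correction is the
default; an exact binomial(n10+n01, 1/2) tail test is available behind a
flag.  With no discordant pairs the p-value is 1 and H0 is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom, norm

from .cohort import Cohort
from .interim import _fit_scores_with_fallback
from .matching import (
    DEFAULT_CALIPER_MULTIPLIER,
    MatchPair,
    MatchResult,
    _greedy_match_core,
    compute_caliper,
)

logger = logging.getLogger("adaptmatch")

DEFAULT_TEST_ALPHA = 0.05


@dataclass
class PairedOutcomeTable:
    """2x2 cross-tabulation of (treated outcome, control outcome) over pairs."""

    n11: int = 0
    n10: int = 0
    n01: int = 0
    n00: int = 0

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n_pairs(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def n_discordant(self) -> int:
        return self.n10 + self.n01

    def to_record(self) -> dict:
        return {"n11": self.n11, "n10": self.n10, "n01": self.n01,
                "n00": self.n00, "n_pairs": self.n_pairs}


@dataclass
class TestResult:
    __test__ = False  # keep pytest from collecting this dataclass

    statistic: float
    p_value: float
    reject: bool
    alpha: float = DEFAULT_TEST_ALPHA
    sided: str = "one_sided"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")
        if self.reject != (self.p_value < self.alpha):
            raise ValueError("reject flag inconsistent with p_value and alpha")

    def to_record(self) -> dict:
        return {"statistic": self.statistic, "p_value": self.p_value,
                "reject": self.reject, "alpha": self.alpha, "sided": self.sided}


def final_match(
    cohort: Cohort,
    covariate_names: Sequence[str] = ("x2", "x3", "x5"),
    caliper_multiplier: float = DEFAULT_CALIPER_MULTIPLIER,
    rng: Optional[np.random.Generator] = None,
) -> MatchResult:
    """Fit on the full cohort and match all treated against all controls.

    The matching rate of the returned result uses the control arm as
    denominator.  Propensity-fit failures propagate.
    """
    if rng is None:
        rng = np.random.default_rng()
    if cohort.n_control == 0 or cohort.n_treated == 0:
        raise ValueError("both arms must be non-empty for the final match")
    combined = cohort.all_subjects()
    eta = _fit_scores_with_fallback(combined, list(covariate_names))
    n_c = cohort.n_control
    c_logits = eta[:n_c]
    t_logits = eta[n_c:]
    caliper = compute_caliper(eta, caliper_multiplier)
    order = rng.permutation(len(t_logits))
    match = _greedy_match_core(t_logits, c_logits, float(caliper), order)
    c_ids = cohort.controls.index.to_numpy()
    t_ids = cohort.treated.index.to_numpy()
    pairs = [
        MatchPair(treated_id=t_ids[i], control_id=c_ids[match[i]],
                  logit_distance=float(abs(t_logits[i] - c_logits[match[i]])))
        for i in np.flatnonzero(match >= 0)
    ]
    return MatchResult(pairs=pairs, caliper=float(caliper),
                       caliper_multiplier=caliper_multiplier,
                       n_treated_in=len(t_ids), n_control_in=n_c,
                       rate_denominator="control")


def paired_outcomes(pairs: Sequence[MatchPair], cohort: Cohort) -> PairedOutcomeTable:
    """Cross-tabulate the binary outcomes of matched treated/control pairs.

    Pairs referencing subjects without an outcome raise; pairs referencing
    unknown ids raise.
    """
    if "y" not in cohort.treated.columns or "y" not in cohort.controls.columns:
        raise ValueError("cohort carries no outcome column 'y'")
    y_t = cohort.treated["y"]
    y_c = cohort.controls["y"]
    table = PairedOutcomeTable()
    for p in pairs:
        if p.treated_id not in y_t.index or p.control_id not in y_c.index:
            raise KeyError(f"pair ({p.treated_id}, {p.control_id}) references "
                           "unknown subjects")
        yt, yc = y_t.loc[p.treated_id], y_c.loc[p.control_id]
        if pd.isna(yt) or pd.isna(yc):
            raise ValueError(f"pair ({p.treated_id}, {p.control_id}) has a "
                             "missing outcome")
        if yt == 1 and yc == 1:
            table.n11 += 1
        elif yt == 1 and yc == 0:
            table.n10 += 1
        elif yt == 0 and yc == 1:
            table.n01 += 1
        else:
            table.n00 += 1
    return table


def mcnemar_one_sided(
    table: PairedOutcomeTable,
    alpha: float = DEFAULT_TEST_ALPHA,
    exact: bool = False,
) -> TestResult:
    """One-sided McNemar test for superiority of the treated arm.

    Asymptotic (default): z on the discordant counts without continuity
    correction, p = 1 - Phi(z).  Exact: binomial(n_d, 1/2) upper tail at
    n10.  No discordant pairs: p = 1, no rejection.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    n_d = table.n_discordant
    if n_d == 0:
        return TestResult(statistic=0.0, p_value=1.0, reject=False, alpha=alpha)
    if exact:
        p = float(binom.sf(table.n10 - 1, n_d, 0.5))
        stat = float(table.n10)
    else:
        stat = (table.n10 - table.n01) / np.sqrt(n_d)
        p = float(norm.sf(stat))
        stat = float(stat)
    return TestResult(statistic=stat, p_value=p, reject=p < alpha, alpha=alpha)
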
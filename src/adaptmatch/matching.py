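"""Propensity-score estimation and 1:1 caliper matching on the logit scale.

The propensity score e(X) = P(z=1 | X) is estimated by maximum-likelihood
logistic regression of the arm indicator on the declared baseline
covariates.  Pairs are formed on the logit of the estimated score,
ln(e/(1-e)), by greedy nearest-neighbour 1:1 matching WITHOUT replacement,
restricted to a caliper of 0.2 times the sample standard deviation of the
pooled logit scores (Austin's recommendation).

Matching without replacement is deliberate: the matched pairs feed a
McNemar-type paired analysis, which requires distinct pairs.  (Note this
differs from the with-replacement default of R's Matching::Match.)

The logistic fit is an in-package Newton-Raphson (IRLS) solver, compiled
with numba: it sits inside the resampling loop of the interim analysis
(hundreds of fits per interim, thousands of interims per simulation study),
where per-call overhead dominates.  Tests cross-check coefficients and
standard errors against statsmodels on shared data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from numba import njit

logger = logging.getLogger("adaptmatch")

#: caliper multiplier recommended for logit-scale propensity matching
DEFAULT_CALIPER_MULTIPLIER = 0.2

#: |linear predictor| beyond which fitted probabilities are numerically 0/1
#: and the logit transform is considered non-finite (separation guard)
_MAX_ABS_LOGIT = 30.0


class PropensityFitError(RuntimeError):
    """Logistic fit failed: non-convergence, separation, or singular design."""


@njit(cache=False)
def _irls_core(X, y, max_iter, tol):  # pragma: no cover - exercised via fit
    n, k = X.shape
    beta = np.zeros(k)
    converged = False
    n_iter = 0
    for it in range(max_iter):
        n_iter = it + 1
        eta = X @ beta
        # clamp to keep exp finite; beyond this the fit is flagged anyway
        eta_c = np.minimum(np.maximum(eta, -_MAX_ABS_LOGIT), _MAX_ABS_LOGIT)
        p = 1.0 / (1.0 + np.exp(-eta_c))
        w = p * (1.0 - p)
        grad = X.T @ (y - p)
        H = (X * w.reshape(-1, 1)).T @ X
        delta = np.linalg.solve(H, grad)
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
    return beta, converged, n_iter


@njit(cache=False)
def _greedy_match_core(t_logits, c_logits, caliper, order):  # pragma: no cover
    """Greedy nearest-neighbour 1:1 match without replacement.

    Treated subjects are visited in ``order``; each takes the nearest
    still-unmatched control within ``caliper`` (ties: lowest control index).
    Returns, per treated index, the matched control index or -1.
    """
    n_c = c_logits.shape[0]
    available = np.ones(n_c, np.bool_)
    match = np.full(t_logits.shape[0], -1, np.int64)
    for k in range(order.shape[0]):
        i = order[k]
        best = -1
        best_d = np.inf
        for j in range(n_c):
            if available[j]:
                d = abs(c_logits[j] - t_logits[i])
                if d < best_d:
                    best_d = d
                    best = j
        if best >= 0 and best_d <= caliper:
            available[best] = False
            match[i] = best
    return match


@dataclass
class PropensityModel:
    """Fitted logistic propensity model (intercept + one slope per covariate)."""

    covariate_names: list[str]
    coefficients: np.ndarray  # [intercept, slope_1, ..., slope_k]
    fit_converged: bool
    n_iter: int
    bse: np.ndarray = field(default=None)  # Wald standard errors, same order

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    def _design(self, data: pd.DataFrame) -> np.ndarray:
        X = np.column_stack(
            [np.ones(len(data))] + [data[c].to_numpy(dtype=float) for c in self.covariate_names]
        )
        return X

    def logit_scores(self, data: pd.DataFrame) -> pd.Series:
        """Linear predictor = logit of the estimated propensity score."""
        eta = self._design(data) @ self.coefficients
        return pd.Series(eta, index=data.index, name="logit_ps")

    def predict_proba(self, data: pd.DataFrame) -> pd.Series:
        """Estimated propensity scores e(X), strictly inside (0, 1)."""
        from scipy.special import expit

        return pd.Series(expit(self.logit_scores(data).to_numpy()),
                         index=data.index, name="ps")


def _fit_design(X: np.ndarray, y: np.ndarray, names: list[str]) -> PropensityModel:
    try:
        beta, converged, n_iter = _irls_core(X, y.astype(float), 50, 1e-10)
    except Exception as exc:  # singular Hessian inside numba linalg
        raise PropensityFitError(f"logistic fit failed: {exc}") from exc
    if not converged or not np.all(np.isfinite(beta)):
        raise PropensityFitError(
            "logistic fit did not converge (possible separation)"
        )
    eta = X @ beta
    if np.max(np.abs(eta)) > _MAX_ABS_LOGIT:
        raise PropensityFitError(
            "fitted probabilities numerically at 0/1 (separation): "
            "logit scores are non-finite"
        )
    # Wald SEs from the inverse observed information
    from scipy.special import expit

    p = expit(eta)
    w = p * (1.0 - p)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
        bse = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        bse = np.full(X.shape[1], np.nan)
    return PropensityModel(
        covariate_names=names, coefficients=beta,
        fit_converged=bool(converged), n_iter=int(n_iter), bse=bse,
    )


def _eta_or_fallback(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Logit scores from a design matrix, tolerating degenerate covariates.

    Tries the full fit first; on failure (typically a covariate constant in
    this particular sample, making the design collinear with the intercept)
    drops constant columns and refits, down to the intercept-only model whose
    logit score is constant.  Raises :class:`PropensityFitError` when no
    usable fit exists (e.g. separation).
    """
    try:
        beta, converged, _ = _irls_core(X, y, 50, 1e-10)
        if converged and np.all(np.isfinite(beta)):
            eta = X @ beta
            if np.max(np.abs(eta)) <= _MAX_ABS_LOGIT:
                return eta
    except Exception:
        pass
    keep = [0] + [j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0]
    if len(keep) < X.shape[1]:
        logger.warning("%d covariate column(s) constant in this sample were "
                       "dropped from the propensity fit", X.shape[1] - len(keep))
        if len(keep) == 1:
            p = float(np.mean(y))
            if not 0.0 < p < 1.0:
                raise PropensityFitError("one-arm sample: no propensity fit")
            return np.full(y.shape[0], np.log(p / (1.0 - p)))
        Xr = np.ascontiguousarray(X[:, keep])
        try:
            beta, converged, _ = _irls_core(Xr, y, 50, 1e-10)
            if converged and np.all(np.isfinite(beta)):
                eta = Xr @ beta
                if np.max(np.abs(eta)) <= _MAX_ABS_LOGIT:
                    return eta
        except Exception:
            pass
    raise PropensityFitError(
        "logistic fit failed (non-convergence, separation, or singular design)"
    )


def fit_propensity(
    subjects: pd.DataFrame, covariate_names: Sequence[str]
) -> PropensityModel:
    """ML logistic regression of the arm indicator ``z`` on named covariates.

    ``subjects`` must contain both arms and no named covariate may be
    constant across all subjects (raises ``ValueError``).  Non-convergence
    or perfect separation raises :class:`PropensityFitError` so callers can
    decide the fallback.
    """
    names = list(covariate_names)
    if "z" not in subjects.columns:
        raise ValueError("subjects frame lacks arm column 'z'")
    z = subjects["z"].to_numpy(dtype=float)
    if not (np.any(z == 0) and np.any(z == 1)):
        raise ValueError("both arms must be represented in the fitting sample")
    for c in names:
        if c not in subjects.columns:
            raise ValueError(f"covariate {c!r} not present in subjects frame")
        if subjects[c].nunique(dropna=False) < 2:
            raise ValueError(f"covariate {c!r} is constant across all subjects")
    X = np.column_stack(
        [np.ones(len(subjects))] + [subjects[c].to_numpy(dtype=float) for c in names]
    )
    return _fit_design(X, z, names)


def compute_caliper(
    logit_scores_all: Union[Sequence[float], np.ndarray, pd.Series],
    multiplier: float = DEFAULT_CALIPER_MULTIPLIER,
) -> float:
    """Caliper width: ``multiplier`` x sample SD (ddof=1) of the pooled logits.

    The SD is taken over the logit scores of *all* subjects entering the
    match (both arms pooled).
    """
    scores = np.asarray(logit_scores_all, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least 2 logit scores to compute a caliper")
    return float(multiplier) * float(np.std(scores, ddof=1))


@dataclass(frozen=True)
class MatchPair:
    treated_id: object
    control_id: object
    logit_distance: float


@dataclass
class MatchResult:
    """Outcome of one 1:1 caliper match."""

    pairs: list[MatchPair]
    caliper: float
    caliper_multiplier: float
    n_treated_in: int
    n_control_in: int
    rate_denominator: str  # 'treated' | 'control' | 'min_arm'

    def __post_init__(self) -> None:
        if self.rate_denominator not in ("treated", "control", "min_arm"):
            raise ValueError(f"bad rate_denominator {self.rate_denominator!r}")
        t_ids = [p.treated_id for p in self.pairs]
        c_ids = [p.control_id for p in self.pairs]
        if len(set(t_ids)) != len(t_ids) or len(set(c_ids)) != len(c_ids):
            raise ValueError("a subject appears in more than one pair")
        if len(self.pairs) > min(self.n_treated_in, self.n_control_in):
            raise ValueError("more pairs than the smaller arm allows")
        tol = 1e-9 * max(1.0, abs(self.caliper))
        for p in self.pairs:
            if p.logit_distance > self.caliper + tol:
                raise ValueError(
                    f"pair distance {p.logit_distance} exceeds caliper {self.caliper}"
                )

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def _denominator(self) -> int:
        if self.rate_denominator == "treated":
            return self.n_treated_in
        if self.rate_denominator == "control":
            return self.n_control_in
        return min(self.n_treated_in, self.n_control_in)

    @property
    def matching_rate(self) -> float:
        return matching_rate(self.n_pairs, self._denominator)

    def to_frame(
        self,
        treated_logits: Mapping | None = None,
        control_logits: Mapping | None = None,
    ) -> pd.DataFrame:
        """Pairs as a tidy frame (CSV-ready)."""
        rows = []
        for p in self.pairs:
            row = {"treated_id": p.treated_id, "control_id": p.control_id}
            if treated_logits is not None:
                row["logit_treated"] = treated_logits[p.treated_id]
            if control_logits is not None:
                row["logit_control"] = control_logits[p.control_id]
            row["distance"] = p.logit_distance
            rows.append(row)
        cols = ["treated_id", "control_id"]
        if treated_logits is not None:
            cols += ["logit_treated", "logit_control"]
        cols += ["distance"]
        return pd.DataFrame(rows, columns=cols)


def matching_rate(n_pairs: int, denominator: int) -> float:
    """Fraction of reference-arm subjects for whom a match was found."""
    if denominator < 1:
        raise ValueError("matching-rate denominator must be >= 1")
    if not 0 <= n_pairs <= denominator:
        raise ValueError(f"n_pairs={n_pairs} outside [0, {denominator}]")
    return n_pairs / denominator


def caliper_match(
    treated_logits: Union[Mapping, pd.Series],
    control_logits: Union[Mapping, pd.Series],
    caliper: float,
    rng: np.random.Generator,
    caliper_multiplier: float = DEFAULT_CALIPER_MULTIPLIER,
    rate_denominator: str = "min_arm",
) -> MatchResult:
    """Greedy 1:1 nearest-neighbour caliper match without replacement.

    Treated subjects are processed in a random order drawn from ``rng``;
    each is paired with the nearest unmatched control whose absolute logit
    difference is within ``caliper`` (ties broken by lowest control id).
    Empty arms yield zero pairs.
    """
    if caliper < 0:
        raise ValueError("caliper must be >= 0")
    t_ser = treated_logits if isinstance(treated_logits, pd.Series) \
        else pd.Series(dict(treated_logits), dtype=float)
    c_ser = control_logits if isinstance(control_logits, pd.Series) \
        else pd.Series(dict(control_logits), dtype=float)
    # controls in ascending id order so the kernel's first-minimum tie rule
    # selects the lowest control id
    c_ser = c_ser.sort_index()
    n_t, n_c = len(t_ser), len(c_ser)
    if n_t == 0 or n_c == 0:
        return MatchResult(pairs=[], caliper=float(caliper),
                           caliper_multiplier=caliper_multiplier,
                           n_treated_in=n_t, n_control_in=n_c,
                           rate_denominator=rate_denominator)
    order = rng.permutation(n_t)
    match = _greedy_match_core(
        t_ser.to_numpy(dtype=float), c_ser.to_numpy(dtype=float),
        float(caliper), order,
    )
    pairs = []
    t_vals = t_ser.to_numpy(dtype=float)
    c_vals = c_ser.to_numpy(dtype=float)
    for i in np.flatnonzero(match >= 0):
        j = match[i]
        pairs.append(MatchPair(
            treated_id=t_ser.index[i], control_id=c_ser.index[j],
            logit_distance=float(abs(t_vals[i] - c_vals[j])),
        ))
    return MatchResult(pairs=pairs, caliper=float(caliper),
                       caliper_multiplier=caliper_multiplier,
                       n_treated_in=n_t, n_control_in=n_c,
                       rate_denominator=rate_denominator)


def _match_count(
    t_logits: np.ndarray, c_logits: np.ndarray, caliper: float,
    rng: np.random.Generator,
) -> int:
    """Number of pairs from a greedy match; array fast path for hot loops."""
    if t_logits.size == 0 or c_logits.size == 0:
        return 0
    order = rng.permutation(t_logits.size)
    match = _greedy_match_core(t_logits, c_logits, float(caliper), order)
    return int(np.count_nonzero(match >= 0))
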
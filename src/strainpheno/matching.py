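"""Propensity-score matching of carriers to controls.

The propensity model is a logistic regression of carrier status on
standardized age, sex (0/1) and heart rate, fitted by iteratively
reweighted least squares with step-halving (monotone log-likelihood,
tolerance 1e-8, at most 100 iterations). Under perfect separation a small
ridge penalty (1e-4) is applied automatically with a logged warning.

Matching is greedy nearest-neighbor on the logit of the propensity score,
without replacement and without a caliper: cases are processed in
descending propensity order and each absorbs its `ratio` closest unused
controls (1:1 for the test set, 1:3 for training). Groups left short when
the pool runs dry are flagged incomplete rather than dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COVARIATES = ("age", "sex", "heart_rate")


@dataclass
class PropensityModel:
    coefficients: np.ndarray      # intercept + one weight per covariate (logit scale)
    means: np.ndarray             # standardization means (age, sex, heart_rate)
    scales: np.ndarray            # standardization scales (> 0)
    log_likelihood: list[float] = field(default_factory=list)
    ridge: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite propensity coefficients")
        if np.any(self.scales <= 0):
            raise ValueError("standardization scales must be positive")

    def _design(self, covariates: pd.DataFrame) -> np.ndarray:
        X = _covariate_matrix(covariates)
        Z = (X - self.means) / self.scales
        return np.column_stack([np.ones(len(Z)), Z])

    def predict_logit(self, covariates: pd.DataFrame) -> np.ndarray:
        return self._design(covariates) @ self.coefficients

    def predict_proba(self, covariates: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.predict_logit(covariates)))


@dataclass
class MatchGroup:
    case_id: str
    control_ids: list[str]
    ratio: int
    complete: bool = True

    def __post_init__(self) -> None:
        if len(set(self.control_ids)) != len(self.control_ids):
            raise ValueError(f"{self.case_id}: duplicate controls in match group")
        if len(self.control_ids) > self.ratio:
            raise ValueError(f"{self.case_id}: more controls than the intended ratio")


def _covariate_matrix(covariates: pd.DataFrame) -> np.ndarray:
    missing = [c for c in COVARIATES if c not in covariates.columns]
    if missing:
        raise ValueError(f"covariates missing columns {missing}")
    sex = covariates["sex"]
    if sex.dtype == object:
        sex = sex.map({"male": 1.0, "female": 0.0})
        if sex.isna().any():
            raise ValueError("sex column must be male/female or 0/1")
    X = np.column_stack(
        [
            covariates["age"].to_numpy(dtype=float),
            sex.to_numpy(dtype=float),
            covariates["heart_rate"].to_numpy(dtype=float),
        ]
    )
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite covariate values")
    return X


def _irls(
    Xd: np.ndarray, y: np.ndarray, ridge: float, tol: float = 1e-8, max_iter: int = 100
) -> tuple[np.ndarray, list[float], bool]:
    """Newton/IRLS with step-halving; returns (beta, loglik trajectory, converged).

    Constant (zero-variance) columns are unidentifiable; their coefficients
    are pinned at 0 and excluded from the Newton solve.
    """
    n, p = Xd.shape
    beta = np.zeros(p)
    active = np.array([True] + [Xd[:, j].std() > 0 for j in range(1, p)])
    pen = np.eye(p) * ridge
    pen[0, 0] = 0.0  # never penalize the intercept

    def loglik(b: np.ndarray) -> float:
        z = Xd @ b
        return float(np.sum(y * z - np.logaddexp(0.0, z)) - 0.5 * b @ pen @ b)

    lls = [loglik(beta)]
    for _ in range(max_iter):
        z = Xd @ beta
        mu = 1.0 / (1.0 + np.exp(-z))
        w = mu * (1.0 - mu)
        grad = (Xd.T @ (y - mu) - pen @ beta)[active]
        Xa = Xd[:, active]
        H = (Xa * w[:, None]).T @ Xa + pen[np.ix_(active, active)]
        try:
            step_a = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return beta, lls, False
        step = np.zeros(p)
        step[active] = step_a
        # step-halving keeps the log-likelihood monotone
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll = loglik(cand)
            if ll >= lls[-1]:
                break
            factor *= 0.5
        else:
            return beta, lls, True
        delta = float(np.max(np.abs(cand - beta)))
        beta = cand
        lls.append(ll)
        if delta < tol:  # coefficient-change tolerance
            return beta, lls, True
    return beta, lls, False


def fit_propensity(covariates: pd.DataFrame, labels) -> PropensityModel:
    """Fit the logistic propensity model of carrier status on covariates.

    ``labels`` may be 0/1 or "carrier"/"control". Degenerate single-class
    inputs raise; separation triggers the automatic ridge fallback.
    """
    y = np.asarray(
        [1.0 if v in (1, True, "carrier") else 0.0 for v in labels], dtype=float
    )
    if len(y) != len(covariates):
        raise ValueError("labels and covariates must align")
    n1 = int(y.sum())
    if n1 < 2 or len(y) - n1 < 2:
        raise ValueError("need at least 2 subjects in each class to fit the propensity model")

    X = _covariate_matrix(covariates)
    means = X.mean(axis=0)
    scales = X.std(axis=0)
    scales[scales == 0] = 1.0  # constant covariate carries no information
    Z = (X - means) / scales
    Xd = np.column_stack([np.ones(len(Z)), Z])

    beta, lls, converged = _irls(Xd, y, ridge=0.0)
    ridge = 0.0
    separated = np.max(np.abs(Xd @ beta)) > 30.0
    if not converged or separated or not np.all(np.isfinite(beta)):
        ridge = 1e-4
        logger.warning(
            "propensity fit shows (quasi-)separation; refitting with ridge penalty %g", ridge
        )
        beta, lls, converged = _irls(Xd, y, ridge=ridge)
        if not converged:
            raise RuntimeError("propensity model failed to converge even with ridge fallback")
    return PropensityModel(
        coefficients=beta, means=means, scales=scales, log_likelihood=lls, ridge=ridge
    )


def match(
    cases: pd.DataFrame,
    controls: pd.DataFrame,
    model: PropensityModel,
    ratio: int = 1,
) -> list[MatchGroup]:
    """Greedy nearest-neighbor matching without replacement.

    ``cases`` and ``controls`` are DataFrames with a ``subject_id`` column
    plus the covariate columns. Cases are processed in descending propensity
    order; distance is absolute difference of propensity logits; ties break
    on control subject_id lexicographic order.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    if len(controls) == 0:
        raise ValueError("control pool is empty")
    case_logit = model.predict_logit(cases)
    ctrl_logit = model.predict_logit(controls)
    case_ids = cases["subject_id"].tolist()
    ctrl_ids = controls["subject_id"].tolist()

    # stable greedy order: descending propensity, id as deterministic tiebreak
    case_order = sorted(range(len(case_ids)), key=lambda i: (-case_logit[i], case_ids[i]))
    ctrl_order = sorted(range(len(ctrl_ids)), key=lambda j: ctrl_ids[j])
    used = np.zeros(len(ctrl_ids), dtype=bool)

    groups: list[MatchGroup] = []
    for i in case_order:
        chosen: list[str] = []
        for _ in range(ratio):
            best_j, best_d = -1, np.inf
            for j in ctrl_order:
                if used[j]:
                    continue
                d = abs(case_logit[i] - ctrl_logit[j])
                if d < best_d:  # ties keep the lexicographically first control
                    best_j, best_d = j, d
            if best_j < 0:
                break
            used[best_j] = True
            chosen.append(ctrl_ids[best_j])
        complete = len(chosen) == ratio
        if not complete:
            logger.warning(
                "match group for %s incomplete: %d/%d controls", case_ids[i], len(chosen), ratio
            )
        groups.append(
            MatchGroup(case_id=case_ids[i], control_ids=chosen, ratio=ratio, complete=complete)
        )
    return groups


def standardized_mean_differences(
    cases: pd.DataFrame, controls: pd.DataFrame
) -> dict[str, float]:
    """Post-matching covariate balance: |mean difference| / pooled SD."""
    Xa = _covariate_matrix(cases)
    Xb = _covariate_matrix(controls)
    out = {}
    for k, name in enumerate(COVARIATES):
        pooled = np.sqrt((Xa[:, k].var(ddof=1) + Xb[:, k].var(ddof=1)) / 2.0)
        diff = abs(Xa[:, k].mean() - Xb[:, k].mean())
        out[name] = float(diff / pooled) if pooled > 0 else 0.0
    return out
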
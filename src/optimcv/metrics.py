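"""Concordance statistic and the logistic fitting/prediction contract.

The C statistic (area under the ROC curve) is computed as the proportion of
all case-control pairs in which the case's score exceeds the control's, with
exactly tied pairs counting one half. This is the Mann-Whitney form: it keeps
C = 0.5 for completely uninformative scores and depends only on the ordering
of the scores, so any strictly increasing transform (for logistic models, the
linear predictor versus the predicted probability) gives the same C.

The logistic fitter is an iteration-capped Newton-Raphson maximiser of the
binomial likelihood, written for the huge numbers of tiny refits the
resampling validators perform. At very low events-per-variable a non-trivial
fraction of training subsets is completely or quasi-completely separated; the
MLE then diverges. The fitter caps iterations, flags the event, and returns
the (large but finite) coefficients anyway: the diverged linear predictor
still defines a usable ranking, which is all the C statistic consumes, and
this mirrors what naive refitting inside each resample does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .data import CaseControlDataset
from .errors import DegenerateDesignError, UndefinedConcordanceError

#: |linear predictor| on the training data above which the fit is treated as separated.
SEPARATION_ETA = 15.0


@dataclass(frozen=True)
class ConcordanceResult:
    """C statistic with its pair bookkeeping.

    c = (n_concordant + 0.5 * n_tied) / n_pairs, n_pairs = cases x controls.
    """

    c: float
    n_pairs: int
    n_concordant: int
    n_tied: int


@dataclass(frozen=True)
class LinearPredictorModel:
    """Intercept + coefficient vector of a fitted logistic model.

    Prediction is the inverse logit of ``intercept + x . coefficients``.
    ``converged`` reports whether the Newton iterations met the gradient
    tolerance; ``separation_detected`` reports (quasi-)complete separation of
    the training data. Coefficients of columns that were constant in the
    training data are zero (they contribute nothing to the linear predictor).
    """

    intercept: float
    coefficients: np.ndarray
    converged: bool = True
    separation_detected: bool = False
    dropped_columns: tuple[int, ...] = field(default=())

    @property
    def p(self) -> int:
        return self.coefficients.shape[0]

    def linear_predictor(self, covariates: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[1] != self.p:
            raise ValueError(f"model expects {self.p} covariates, got {X.shape[1]}")
        return self.intercept + X @ self.coefficients

    def predict_probability(self, covariates: np.ndarray) -> np.ndarray:
        return expit(self.linear_predictor(covariates))


def concordance_statistic(scores: np.ndarray, outcome: np.ndarray) -> ConcordanceResult:
    """C statistic of ``scores`` against a binary ``outcome``.

    Ties between a case score and a control score count one half. Equality is
    exact on the computed floats (no epsilon), so results are bit-reproducible.
    The result is invariant to the row order of the inputs.
    """
    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome)
    if scores.shape != outcome.shape or scores.ndim != 1:
        raise ValueError("scores and outcome must be matching 1-D vectors")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    case_scores = scores[outcome == 1]
    control_scores = np.sort(scores[outcome == 0])
    n1, n0 = case_scores.size, control_scores.size
    if n1 == 0 or n0 == 0:
        raise UndefinedConcordanceError("concordance undefined without both cases and controls")
    lo = np.searchsorted(control_scores, case_scores, side="left")
    hi = np.searchsorted(control_scores, case_scores, side="right")
    n_concordant = int(lo.sum())
    n_tied = int((hi - lo).sum())
    n_pairs = n1 * n0
    return ConcordanceResult(
        c=(n_concordant + 0.5 * n_tied) / n_pairs,
        n_pairs=n_pairs,
        n_concordant=n_concordant,
        n_tied=n_tied,
    )


def _newton_logistic(X1: np.ndarray, y: np.ndarray, max_iter: int, tol: float):
    """Newton-Raphson with step halving on the design X1 (first column = 1)."""
    n, q = X1.shape
    beta = np.zeros(q)
    ybar = y.mean()
    beta[0] = np.log(ybar / (1.0 - ybar))  # start at the intercept-only MLE
    eta = X1 @ beta
    mu = expit(eta)
    eps = 1e-12
    dev = -2.0 * np.sum(y * np.log(mu + eps) + (1 - y) * np.log(1 - mu + eps))
    converged = False
    for _ in range(max_iter):
        grad = X1.T @ (y - mu)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        w = mu * (1.0 - mu)
        H = (X1 * w[:, None]).T @ X1
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            raise DegenerateDesignError("singular information matrix (collinear design)")
        # step halving keeps the deviance non-increasing
        for _ in range(30):
            cand = beta + step
            eta_c = X1 @ cand
            mu_c = expit(eta_c)
            dev_c = -2.0 * np.sum(y * np.log(mu_c + eps) + (1 - y) * np.log(1 - mu_c + eps))
            if dev_c <= dev + 1e-10:
                break
            step *= 0.5
        beta, eta, mu, dev = cand, eta_c, mu_c, dev_c
    return beta, eta, converged


def fit_logistic(
    data: CaseControlDataset,
    max_iter: int = 25,
    tol: float = 1e-8,
) -> LinearPredictorModel:
    """Maximum-likelihood logistic regression with linear covariate terms.

    Covariate columns constant within ``data`` are dropped for this fit (their
    coefficient is 0). A rank-deficient remaining design raises
    :class:`DegenerateDesignError` naming the offending columns. Separation is
    flagged when any training linear predictor exceeds ``SEPARATION_ETA`` in
    magnitude; the returned coefficients are still usable for ranking.
    """
    X = data.covariates
    y = data.outcome.astype(float)
    keep = np.flatnonzero(np.ptp(X, axis=0) > 0)
    dropped = tuple(int(j) for j in range(data.p) if j not in set(keep.tolist()))
    coef = np.zeros(data.p)
    if keep.size == 0:
        # intercept-only model
        ybar = y.mean()
        return LinearPredictorModel(float(np.log(ybar / (1 - ybar))), coef, True, False, dropped)
    Xk = X[:, keep]
    X1 = np.concatenate([np.ones((data.n, 1)), Xk], axis=1)
    if np.linalg.matrix_rank(X1) < X1.shape[1]:
        # pinpoint columns not independent of their predecessors
        bad = []
        r = 1
        for j in range(Xk.shape[1]):
            sub = X1[:, : 1 + j + 1]
            rr = np.linalg.matrix_rank(sub)
            if rr == r:
                bad.append(data.covariate_names[keep[j]])
            r = rr
        raise DegenerateDesignError(f"rank-deficient design; offending columns: {bad}", bad)
    try:
        beta, eta, converged = _newton_logistic(X1, y, max_iter, tol)
    except DegenerateDesignError:
        raise DegenerateDesignError(
            f"singular information matrix for columns {[data.covariate_names[j] for j in keep]}",
            [data.covariate_names[j] for j in keep],
        )
    coef[keep] = beta[1:]
    separated = bool(np.max(np.abs(eta)) > SEPARATION_ETA)
    return LinearPredictorModel(float(beta[0]), coef, bool(converged), separated, dropped)


def predict_probability(model: LinearPredictorModel, covariates: np.ndarray) -> np.ndarray:
    """Inverse-logit predictions of ``model`` on a covariate matrix."""
    return model.predict_probability(covariates)
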
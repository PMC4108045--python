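"""Internal-validation procedures that correct the C statistic for optimism.

A logistic model fitted to a small dataset and scored on the same data yields
the naive C statistic, which overstates the discrimination the model would
achieve in new data; the excess is the optimism. Each procedure here maps a
small case-control dataset to an optimism-corrected C:

``split_sample``
    One stratified random split (default two-thirds / one-third); fit on the
    larger part, score on the smaller.
``kfold_cv``
    Stratified k-fold cross-validation (default k = 10); the k held-out-fold
    C values are averaged.
``replicated_kfold_cv``
    r independent random repetitions of k-fold CV (defaults r = 20, k = 10);
    the mean of all r*k fold-level C values.
``loocv``
    Leave-one-out: each row's out-of-sample probability comes from a model
    fitted to the other n-1 rows; one C is pooled from the n probabilities.
``lpocv``
    Leave-pair-out: every (case, control) pair is held out in turn and scored
    by the model fitted on the remaining n-2 rows; C is the fraction of pairs
    ranked correctly (ties one half). Exhaustive, hence deterministic.
``bootstrap_optimism``
    Harrell's bootstrap: b resamples with replacement; the average of
    (C on the resample - C of the resample model on the original data)
    estimates the optimism, subtracted from the naive C.

Seed policy: every stochastic procedure derives its own independent random
stream from (master seed, method tag), so adding or reordering methods never
perturbs another method's resamples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data import CaseControlDataset
from .errors import InfeasibleFoldsError, UndefinedConcordanceError
from .metrics import LinearPredictorModel, concordance_statistic, fit_logistic

# fixed per-method stream tags: adding a method never perturbs another's stream
_METHOD_TAGS = {
    "split_sample": 11,
    "kfold_cv": 12,  # shared with replicated_kfold_cv so r=1 reduces exactly
    "replicated_kfold_cv": 12,
    "bootstrap_optimism": 14,
}

STOCHASTIC_METHODS = ("split_sample", "kfold_cv", "replicated_kfold_cv", "bootstrap_optimism")
DETERMINISTIC_METHODS = ("loocv", "lpocv")
ALL_METHODS = STOCHASTIC_METHODS + DETERMINISTIC_METHODS


@dataclass(frozen=True)
class MethodConfig:
    """Tuning parameters shared by the validation procedures.

    k folds, r cross-validation replications, b bootstrap resamples, the
    training fraction of the sample split, whether folds/splits are stratified
    by outcome, and the master seed for all stochastic procedures.
    """

    k: int = 10
    r: int = 20
    b: int = 200
    split_train_fraction: float = 2.0 / 3.0
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.r < 1 or self.b < 1:
            raise ValueError("r and b must be >= 1")
        if not 0.0 < self.split_train_fraction < 1.0:
            raise ValueError("split_train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class OptimismCorrectedEstimate:
    """Result of one validation procedure on one small dataset."""

    method: str
    naive_c: float
    corrected_c: float
    optimism: float
    n_models_fitted: int
    n_degenerate_fits: int
    seed_used: int | None
    n_redrawn_resamples: int = 0


def _method_rng(seed: int, method: str, *extra: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _METHOD_TAGS[method], *extra]))


def _fit(train: CaseControlDataset) -> tuple[LinearPredictorModel, int]:
    model = fit_logistic(train)
    degenerate = int(model.separation_detected or not model.converged)
    return model, degenerate


def naive_c(data: CaseControlDataset) -> float:
    """C of the full-data model scored on the data it was fitted to."""
    model = fit_logistic(data)
    return concordance_statistic(model.linear_predictor(data.covariates), data.outcome).c


def _estimate(method, data, corrected, n_models, n_degen, seed, n_redrawn=0):
    nav = naive_c(data)
    return OptimismCorrectedEstimate(
        method=method,
        naive_c=nav,
        corrected_c=float(corrected),
        optimism=nav - float(corrected),
        n_models_fitted=n_models,
        n_degenerate_fits=n_degen,
        seed_used=seed,
        n_redrawn_resamples=n_redrawn,
    )


# ---------------------------------------------------------------------------
# sample splitting
# ---------------------------------------------------------------------------

def split_sample(data: CaseControlDataset, config: MethodConfig = MethodConfig()) -> OptimismCorrectedEstimate:
    """Fit on a random training fraction, score C on the held-out remainder."""
    rng = _method_rng(config.seed, "split_sample")
    f = config.split_train_fraction
    if config.stratified:
        train_idx = []
        for cls_idx in (data.case_indices, data.control_indices):
            m = len(cls_idx)
            m_train = min(max(int(round(f * m)), 1), m - 1) if m >= 2 else m
            perm = rng.permutation(cls_idx)
            train_idx.append(perm[:m_train])
        train_idx = np.concatenate(train_idx)
    else:
        perm = rng.permutation(data.n)
        train_idx = perm[: min(max(int(round(f * data.n)), 1), data.n - 1)]
    mask = np.zeros(data.n, dtype=bool)
    mask[train_idx] = True
    if data.outcome[mask].min() == data.outcome[mask].max():
        raise UndefinedConcordanceError("training split contains a single outcome class")
    if data.outcome[~mask].min() == data.outcome[~mask].max():
        raise UndefinedConcordanceError("validation split contains a single outcome class")
    train = data.subset(np.flatnonzero(mask))
    valid = data.subset(np.flatnonzero(~mask))
    model, degen = _fit(train)
    c = concordance_statistic(model.linear_predictor(valid.covariates), valid.outcome).c
    return _estimate("split_sample", data, c, 1, degen, config.seed)


# ---------------------------------------------------------------------------
# k-fold cross-validation (single and replicated)
# ---------------------------------------------------------------------------

def _fold_assignment(data: CaseControlDataset, k: int, stratified: bool, rng) -> np.ndarray:
    folds = np.empty(data.n, dtype=int)
    if stratified:
        if k > data.n_cases or k > data.n_controls:
            raise InfeasibleFoldsError(
                f"k={k} exceeds a class count (cases={data.n_cases}, controls={data.n_controls})"
            )
        for cls_idx in (data.case_indices, data.control_indices):
            perm = rng.permutation(cls_idx)
            folds[perm] = np.arange(len(perm)) % k
    else:
        perm = rng.permutation(data.n)
        folds[perm] = np.arange(data.n) % k
    return folds


def _one_cv_replication(data, k, stratified, rng):
    folds = _fold_assignment(data, k, stratified, rng)
    fold_cs, n_degen = [], 0
    for f in range(k):
        test = folds == f
        y_test = data.outcome[test]
        if y_test.size == 0 or y_test.min() == y_test.max():
            raise UndefinedConcordanceError(f"fold {f} lacks an outcome class; C undefined")
        train = data.subset(np.flatnonzero(~test))
        model, degen = _fit(train)
        n_degen += degen
        c = concordance_statistic(model.linear_predictor(data.covariates[test]), y_test).c
        fold_cs.append(c)
    return fold_cs, n_degen


def replicated_kfold_cv(data: CaseControlDataset, config: MethodConfig = MethodConfig()) -> OptimismCorrectedEstimate:
    """Mean of the r*k fold-level C values over r random k-fold partitions."""
    all_cs, n_degen = [], 0
    for j in range(config.r):
        rng = _method_rng(config.seed, "replicated_kfold_cv", j)
        cs, d = _one_cv_replication(data, config.k, config.stratified, rng)
        all_cs.extend(cs)
        n_degen += d
    method = "kfold_cv" if config.r == 1 else "replicated_kfold_cv"
    return _estimate(method, data, float(np.mean(all_cs)), config.r * config.k, n_degen, config.seed)


def kfold_cv(data: CaseControlDataset, config: MethodConfig = MethodConfig()) -> OptimismCorrectedEstimate:
    """Single k-fold cross-validation: ``replicated_kfold_cv`` with r = 1."""
    return replicated_kfold_cv(data, replace(config, r=1))


# ---------------------------------------------------------------------------
# leave-one-out
# ---------------------------------------------------------------------------

def loocv(data: CaseControlDataset, config: MethodConfig = MethodConfig()) -> OptimismCorrectedEstimate:
    """One pooled C from the n out-of-sample probabilities. Deterministic.

    Pooling probabilities produced by n slightly different models is known to
    bias C downward; the procedure is included because it is in common use.
    """
    if data.n < 3:
        raise ValueError("leave-one-out needs n >= 3")
    probs = np.empty(data.n)
    n_degen = 0
    for i in range(data.n):
        train = data.drop_rows([i])
        model, degen = _fit(train)
        n_degen += degen
        probs[i] = model.predict_probability(data.covariates[i : i + 1])[0]
    c = concordance_statistic(probs, data.outcome).c
    return _estimate("loocv", data, c, data.n, n_degen, None)


# ---------------------------------------------------------------------------
# leave-pair-out
# ---------------------------------------------------------------------------

def lpocv(data: CaseControlDataset, config: MethodConfig = MethodConfig()) -> OptimismCorrectedEstimate:
    """Exhaustive leave-pair-out cross-validation. Deterministic.

    Every (case, control) pair is omitted; the model fitted to the remaining
    n-2 rows scores both members, and the corrected C is the fraction of
    pairs in which the case outranks the control (exact ties count one half).
    """
    cases, controls = data.case_indices, data.control_indices
    if len(cases) < 2 or len(controls) < 2:
        raise InfeasibleFoldsError("leave-pair-out needs at least 2 cases and 2 controls")
    total, n_degen = 0.0, 0
    for i in cases:
        for j in controls:
            train = data.drop_rows([i, j])
            model, degen = _fit(train)
            n_degen += degen
            # compare on the linear predictor: same ordering as the predicted
            # probability, but immune to expit saturating to exactly 1.0 for
            # separated fits (which would turn ranked pairs into spurious ties)
            pc, pk = model.linear_predictor(data.covariates[[i, j]])
            if pc > pk:
                total += 1.0
            elif pc == pk:
                total += 0.5
    n_pairs = len(cases) * len(controls)
    return _estimate("lpocv", data, total / n_pairs, n_pairs, n_degen, None)


# ---------------------------------------------------------------------------
# Harrell bootstrap
# ---------------------------------------------------------------------------

def bootstrap_optimism(data: CaseControlDataset, config: MethodConfig = MethodConfig()) -> OptimismCorrectedEstimate:
    """Harrell's bootstrap optimism correction with b resamples.

    Resamples that lack a class are redrawn (and counted), keeping exactly b
    effective resamples in the average. The corrected C is clipped to [0, 1];
    optimism is reported as naive - corrected so the two stay consistent.
    """
    rng = _method_rng(config.seed, "bootstrap_optimism")
    nav = naive_c(data)
    diffs = np.empty(config.b)
    n_degen = n_redrawn = 0
    for i in range(config.b):
        while True:
            idx = rng.integers(0, data.n, data.n)
            y_res = data.outcome[idx]
            if y_res.min() != y_res.max():
                break
            n_redrawn += 1
        resample = data.subset(idx)
        model, degen = _fit(resample)
        n_degen += degen
        c_res = concordance_statistic(model.linear_predictor(resample.covariates), resample.outcome).c
        c_orig = concordance_statistic(model.linear_predictor(data.covariates), data.outcome).c
        diffs[i] = c_res - c_orig
    corrected = float(np.clip(nav - diffs.mean(), 0.0, 1.0))
    return OptimismCorrectedEstimate(
        method="bootstrap_optimism",
        naive_c=nav,
        corrected_c=corrected,
        optimism=nav - corrected,
        n_models_fitted=config.b,
        n_degenerate_fits=n_degen,
        seed_used=config.seed,
        n_redrawn_resamples=n_redrawn,
    )


_DISPATCH = {
    "split_sample": split_sample,
    "kfold_cv": kfold_cv,
    "replicated_kfold_cv": replicated_kfold_cv,
    "loocv": loocv,
    "lpocv": lpocv,
    "bootstrap_optimism": bootstrap_optimism,
}


def run_method(name: str, data: CaseControlDataset, config: MethodConfig = MethodConfig()) -> OptimismCorrectedEstimate:
    """Run one validation procedure by name."""
    try:
        fn = _DISPATCH[name]
    except KeyError:
        raise KeyError(f"unknown method {name!r}; choose from {sorted(_DISPATCH)}") from None
    return fn(data, config)
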
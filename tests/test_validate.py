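import dataclasses

import numpy as np
import pytest

from optimcv import (
    ALL_METHODS,
    DETERMINISTIC_METHODS,
    STOCHASTIC_METHODS,
    InfeasibleFoldsError,
    MethodConfig,
    bootstrap_optimism,
    kfold_cv,
    loocv,
    lpocv,
    naive_c,
    replicated_kfold_cv,
    run_method,
    split_sample,
)
from optimcv.metrics import concordance_statistic
from optimcv.validate import _method_rng


def _roc_auc(y, scores):
    sklearn_metrics = pytest.importorskip("sklearn.metrics")
    return sklearn_metrics.roc_auc_score(y, scores)


def _sm_probs(train_y, train_x, test_x):
    sm = pytest.importorskip("statsmodels.api")
    model = sm.Logit(train_y, sm.add_constant(train_x, has_constant="add"))
    try:
        fit = model.fit(disp=0, method="newton")
    except np.linalg.LinAlgError:
        # separable training subset: Newton's Hessian is singular; a
        # quasi-Newton fit still yields the (diverged) ranking
        fit = model.fit(disp=0, method="bfgs", maxiter=2000)
    X1 = np.column_stack([np.ones(len(test_x)), test_x])
    return 1 / (1 + np.exp(-(X1 @ fit.params)))


class TestContracts:
    def test_naive_c_perfect_covariate(self, perfect_dataset):
        assert naive_c(perfect_dataset) == 1.0

    def test_naive_c_noise_covariate_near_half(self):
        rng = np.random.default_rng(8)
        vals = []
        for _ in range(10):
            y = np.repeat([1, 0], [60, 240])
            x = rng.standard_normal(300)
            from optimcv import CaseControlDataset

            vals.append(naive_c(CaseControlDataset(y, x)))
        assert abs(np.mean(vals) - 0.5) < 0.05

    def test_split_sizes_two_thirds(self, epv5_dataset):
        est = split_sample(epv5_dataset, MethodConfig(seed=1))
        assert est.n_models_fitted == 1
        assert est.optimism == pytest.approx(est.naive_c - est.corrected_c)

    def test_kfold_counts(self, epv5_dataset):
        est = kfold_cv(epv5_dataset, MethodConfig(seed=1))
        assert est.n_models_fitted == 10

    def test_replicated_counts_and_reduction(self, epv5_dataset):
        cfg = MethodConfig(seed=9)
        est = replicated_kfold_cv(epv5_dataset, cfg)
        assert est.n_models_fitted == 200  # r*k = 20*10 fold-level values
        single = replicated_kfold_cv(epv5_dataset, dataclasses.replace(cfg, r=1))
        assert single.corrected_c == kfold_cv(epv5_dataset, cfg).corrected_c

    def test_loocv_counts(self, epv5_dataset):
        est = loocv(epv5_dataset)
        assert est.n_models_fitted == epv5_dataset.n == 75
        assert est.seed_used is None

    def test_lpocv_pair_count(self, epv5_dataset):
        est = lpocv(epv5_dataset)
        assert est.n_models_fitted == 15 * 60
        assert est.seed_used is None

    def test_bootstrap_counts(self, tiny_overlap_dataset):
        est = bootstrap_optimism(tiny_overlap_dataset, MethodConfig(seed=2, b=25))
        assert est.n_models_fitted == 25
        assert 0.0 <= est.corrected_c <= 1.0

    def test_perfect_covariate_corrected_one(self, perfect_dataset):
        cfg = MethodConfig(seed=4, b=30, k=5)  # 5 cases -> at most 5 stratified folds
        for method in ("split_sample", "kfold_cv", "bootstrap_optimism"):
            est = run_method(method, perfect_dataset, cfg)
            assert est.corrected_c == 1.0, method
        assert bootstrap_optimism(perfect_dataset, cfg).optimism == 0.0

    def test_infeasible_folds(self, tiny_overlap_dataset):
        with pytest.raises(InfeasibleFoldsError):
            kfold_cv(tiny_overlap_dataset, MethodConfig(k=10, seed=0))  # only 4 cases

    def test_unknown_method(self, tiny_overlap_dataset):
        with pytest.raises(KeyError):
            run_method("jackknife", tiny_overlap_dataset)


class TestDeterminism:
    @pytest.mark.parametrize("method", DETERMINISTIC_METHODS)
    def test_deterministic_methods_bit_identical(self, method, tiny_overlap_dataset):
        a = run_method(method, tiny_overlap_dataset)
        b = run_method(method, tiny_overlap_dataset)
        assert a == b

    @pytest.mark.parametrize("method", STOCHASTIC_METHODS)
    def test_stochastic_methods_bit_identical_under_seed(self, method, epv5_dataset):
        cfg = MethodConfig(seed=123, b=40, r=3)
        a = run_method(method, epv5_dataset, cfg)
        b = run_method(method, epv5_dataset, cfg)
        assert a == b
        c = run_method(method, epv5_dataset, dataclasses.replace(cfg, seed=124))
        assert c.corrected_c != a.corrected_c  # seed actually matters

    def test_replication_reduces_between_run_spread(self, epv5_dataset):
        # SD over repeated runs shrinks roughly as 1/sqrt(r)
        sds = []
        for r in (1, 20):
            vals = [
                replicated_kfold_cv(epv5_dataset, MethodConfig(seed=s, r=r)).corrected_c
                for s in range(30)
            ]
            sds.append(np.std(vals, ddof=1))
        ratio = sds[0] / sds[1]
        assert np.sqrt(20) / 2 < ratio < np.sqrt(20) * 2


class TestOracles:
    def test_kfold_equals_two_fold_hand_computation(self, tiny_overlap_dataset):
        cfg = MethodConfig(k=2, seed=5)
        est = kfold_cv(tiny_overlap_dataset, cfg)
        # reproduce the stratified fold assignment from the same derived stream
        rng = _method_rng(cfg.seed, "replicated_kfold_cv", 0)
        d = tiny_overlap_dataset
        folds = np.empty(d.n, dtype=int)
        for cls in (d.case_indices, d.control_indices):
            perm = rng.permutation(cls)
            folds[perm] = np.arange(len(perm)) % 2
        cs = []
        for f in (0, 1):
            tr, te = folds != f, folds == f
            probs = _sm_probs(d.outcome[tr], d.covariates[tr], d.covariates[te])
            cs.append(_roc_auc(d.outcome[te], probs))
        assert est.corrected_c == pytest.approx(np.mean(cs), abs=1e-9)

    def test_loocv_matches_brute_force(self, tiny_overlap_dataset):
        d = tiny_overlap_dataset
        probs = np.empty(d.n)
        for i in range(d.n):
            mask = np.arange(d.n) != i
            probs[i] = _sm_probs(d.outcome[mask], d.covariates[mask], d.covariates[i : i + 1])[0]
        expected = _roc_auc(d.outcome, probs)
        assert loocv(d).corrected_c == pytest.approx(expected, abs=1e-9)

    def test_lpocv_matches_brute_force(self):
        from optimcv import CaseControlDataset

        rng = np.random.default_rng(31)
        y = np.array([1, 1, 1, 0, 0, 0, 0])
        x = np.where(y == 1, 0.8, 0.0) + rng.normal(0, 1, 7)
        d = CaseControlDataset(y, x)
        total = 0.0
        for i in d.case_indices:
            for j in d.control_indices:
                mask = ~np.isin(np.arange(d.n), [i, j])
                pi, pj = _sm_probs(d.outcome[mask], d.covariates[mask], d.covariates[[i, j]])
                total += 1.0 if pi > pj else (0.5 if pi == pj else 0.0)
        expected = total / 12
        assert lpocv(d).corrected_c == pytest.approx(expected, abs=1e-9)

    def test_bootstrap_matches_independent_resampling_oracle(self, tiny_overlap_dataset):
        d = tiny_overlap_dataset
        cfg = MethodConfig(seed=17, b=10)
        est = bootstrap_optimism(d, cfg)
        # same resample index stream; fitting and scoring fully independent
        rng = _method_rng(cfg.seed, "bootstrap_optimism")
        nav = _roc_auc(d.outcome, _sm_probs(d.outcome, d.covariates, d.covariates))
        diffs = []
        for _ in range(cfg.b):
            while True:
                idx = rng.integers(0, d.n, d.n)
                if d.outcome[idx].min() != d.outcome[idx].max():
                    break
            ptr = _sm_probs(d.outcome[idx], d.covariates[idx], d.covariates[idx])
            porig = _sm_probs(d.outcome[idx], d.covariates[idx], d.covariates)
            diffs.append(_roc_auc(d.outcome[idx], ptr) - _roc_auc(d.outcome, porig))
        expected = nav - np.mean(diffs)
        assert est.corrected_c == pytest.approx(expected, abs=1e-9)


class TestBiasDirectionSmall:
    def test_naive_exceeds_corrected_on_average_at_epv5(self, down_spec_small_mc):
        from optimcv import draw_case_control

        cfg = MethodConfig(b=40, r=5)
        diffs = []
        for rep in range(25):
            small = draw_case_control(down_spec_small_mc, 15, 60, np.random.default_rng(500 + rep))
            est = bootstrap_optimism(small, dataclasses.replace(cfg, seed=rep))
            diffs.append(est.naive_c - est.corrected_c)
        assert np.mean(diffs) > 0  # optimism is positive on average
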
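"""Evaluation harness: true C, error summaries, method comparisons, grids.

A small dataset's model has a "true" C — its concordance on a large gold
standard the model never saw (the pooled complement of a partitioned large
dataset, or a fresh simulated population). Each correction method's signed
error is (corrected C - true C); averaging those over many small datasets
exposes systematic optimism (positive) or pessimism (negative), and the
absolute error and MSE measure overall accuracy. Pairwise method contrasts
use per-dataset differences in absolute error with a Wilcoxon signed-rank
test, reported raw (no multiplicity adjustment).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import CaseControlDataset
from .errors import OptimcvError
from .metrics import LinearPredictorModel, concordance_statistic, fit_logistic
from .simulate import ExperimentDesign, PopulationSpec, draw_case_control, generate_population
from .stats import wilcoxon_signed_rank
from .validate import ALL_METHODS, MethodConfig, run_method

NAIVE_LABEL = "naive"


@dataclass(frozen=True)
class EvaluationRecord:
    """True/naive/corrected C values and derived errors for one small dataset."""

    replicate_id: int
    true_c: float
    naive_c: float
    corrected: Mapping[str, float]
    signed_error: Mapping[str, float] = field(default_factory=dict)
    absolute_error: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.signed_error:
            se = {m: c - self.true_c for m, c in self.corrected.items()}
            object.__setattr__(self, "signed_error", se)
            object.__setattr__(self, "absolute_error", {m: abs(v) for m, v in se.items()})

    def error_row(self, method: str) -> tuple[float, float]:
        if method == NAIVE_LABEL:
            se = self.naive_c - self.true_c
            return se, abs(se)
        return self.signed_error[method], self.absolute_error[method]


@dataclass(frozen=True)
class MethodComparison:
    """Row-vs-column contrast of absolute errors (column minus row)."""

    method_a: str  # row
    method_b: str  # column
    median_diff_abs_error: float
    iqr: tuple[float, float]
    p_value: float


# ---------------------------------------------------------------------------
# gold standards
# ---------------------------------------------------------------------------

def partition_small_datasets(
    large: CaseControlDataset, n_sets: int, rng: np.random.Generator
) -> list[CaseControlDataset]:
    """Disjoint, exhaustive partition into n_sets stratified small datasets.

    Per-set case counts differ by at most one, likewise controls; the union of
    the sets' rows is exactly the large dataset (no resampling).
    """
    if n_sets > large.n_cases or n_sets > large.n_controls:
        raise OptimcvError(f"cannot partition {large.n_cases} cases/{large.n_controls} controls into {n_sets} sets")
    groups: list[list[np.ndarray]] = [[] for _ in range(n_sets)]
    for cls_idx in (large.case_indices, large.control_indices):
        perm = rng.permutation(cls_idx)
        for g, chunk in enumerate(np.array_split(perm, n_sets)):
            groups[g].append(chunk)
    return [large.subset(np.concatenate(g)) for g in groups]


def true_c(model: LinearPredictorModel, gold: CaseControlDataset) -> float:
    """Concordance of a fitted model on a gold-standard dataset it never saw."""
    return concordance_statistic(model.linear_predictor(gold.covariates), gold.outcome).c


# ---------------------------------------------------------------------------
# per-dataset suite
# ---------------------------------------------------------------------------

def run_method_suite(
    small: CaseControlDataset,
    gold: CaseControlDataset,
    methods: Sequence[str] = ALL_METHODS,
    config: MethodConfig = MethodConfig(),
    replicate_id: int = 0,
) -> EvaluationRecord:
    """Naive, true, and every requested corrected C on one small dataset."""
    model = fit_logistic(small)
    nav = concordance_statistic(model.linear_predictor(small.covariates), small.outcome).c
    tc = true_c(model, gold)
    corrected = {}
    for m in methods:
        try:
            corrected[m] = run_method(m, small, config).corrected_c
        except OptimcvError as e:
            raise OptimcvError(f"method {m!r} failed on replicate {replicate_id}: {e}") from e
    return EvaluationRecord(replicate_id, tc, nav, corrected)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def records_to_frame(records: Sequence[EvaluationRecord]) -> pd.DataFrame:
    """Tidy frame: one row per (replicate, method), naive included as a method."""
    rows = []
    for rec in records:
        for m in (NAIVE_LABEL, *rec.corrected):
            se, ae = rec.error_row(m)
            corrected = rec.naive_c if m == NAIVE_LABEL else rec.corrected[m]
            rows.append((rec.replicate_id, m, rec.true_c, rec.naive_c, corrected, se, ae))
    return pd.DataFrame(
        rows, columns=["replicate_id", "method", "true_c", "naive_c", "corrected_c",
                       "signed_error", "absolute_error"]
    )


def frame_to_records(df: pd.DataFrame) -> list[EvaluationRecord]:
    """Inverse of :func:`records_to_frame` (summaries are pure record functions)."""
    records = []
    for rid, grp in df.groupby("replicate_id", sort=True):
        corrected = {
            r.method: r.corrected_c for r in grp.itertuples() if r.method != NAIVE_LABEL
        }
        records.append(
            EvaluationRecord(int(rid), float(grp.true_c.iloc[0]), float(grp.naive_c.iloc[0]), corrected)
        )
    return records


def summarize_errors(records: Sequence[EvaluationRecord]) -> pd.DataFrame:
    """Per-method error summary across small datasets.

    Columns: mean/median signed error, IQR of the signed error, mean/median
    absolute error, IQR of the absolute error, MSE, and a two-sided Wilcoxon
    p-value against a zero-centered signed error. The naive C appears as
    method "naive".
    """
    if not records:
        raise OptimcvError("summarize_errors needs at least one record")
    methods = [NAIVE_LABEL, *records[0].corrected]
    rows = []
    for m in methods:
        se = np.array([r.error_row(m)[0] for r in records])
        ae = np.abs(se)
        rows.append({
            "method": m,
            "n": se.size,
            "mean_signed_error": se.mean(),
            "median_signed_error": float(np.median(se)),
            "signed_q1": float(np.percentile(se, 25)),
            "signed_q3": float(np.percentile(se, 75)),
            "mean_absolute_error": ae.mean(),
            "median_absolute_error": float(np.median(ae)),
            "abs_q1": float(np.percentile(ae, 25)),
            "abs_q3": float(np.percentile(ae, 75)),
            "mse": float(np.mean(se**2)),
            "wilcoxon_p": wilcoxon_signed_rank(se),
        })
    return pd.DataFrame(rows).set_index("method")


def pairwise_comparison(
    records: Sequence[EvaluationRecord], method_a: str, method_b: str
) -> MethodComparison:
    """Contrast two methods' absolute errors (column ``method_b`` minus row ``method_a``)."""
    d = np.array([r.error_row(method_b)[1] - r.error_row(method_a)[1] for r in records])
    return MethodComparison(
        method_a,
        method_b,
        float(np.median(d)),
        (float(np.percentile(d, 25)), float(np.percentile(d, 75))),
        wilcoxon_signed_rank(d),
    )


def comparison_table(records: Sequence[EvaluationRecord], methods: Sequence[str]) -> pd.DataFrame:
    """All pairwise contrasts as a tidy frame (row method vs column method)."""
    rows = []
    for i, a in enumerate(methods):
        for b in methods[:i]:
            cmp_ = pairwise_comparison(records, a, b)
            rows.append({
                "row_method": a, "column_method": b,
                "median_diff_abs_error": cmp_.median_diff_abs_error,
                "iqr_low": cmp_.iqr[0], "iqr_high": cmp_.iqr[1], "p_value": cmp_.p_value,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# repeatability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatabilityResult:
    method: str
    n_repeats: int
    sd: float
    minimum: float
    maximum: float
    values: tuple[float, ...]


def repeatability(
    small: CaseControlDataset,
    method: str,
    n_repeats: int,
    config: MethodConfig = MethodConfig(),
) -> RepeatabilityResult:
    """SD and range of a method's corrected C over repeated runs.

    Stochastic methods get a distinct derived seed per repeat; deterministic
    methods (loocv, lpocv) return SD exactly 0 by construction.
    """
    values = []
    for i in range(n_repeats):
        seed_i = int(np.random.SeedSequence([int(config.seed), 9001, i]).generate_state(1)[0] % (2**31))
        est = run_method(method, small, replace(config, seed=seed_i))
        values.append(est.corrected_c)
    v = np.asarray(values)
    return RepeatabilityResult(method, n_repeats, float(v.std(ddof=1)) if n_repeats > 1 else 0.0,
                               float(v.min()), float(v.max()), tuple(values))


# ---------------------------------------------------------------------------
# simulation grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridCellResult:
    spec_name: str
    target_c: float | None
    design: ExperimentDesign
    records: tuple[EvaluationRecord, ...]
    summary: pd.DataFrame
    error: str | None = None


def run_simulation_cell(
    spec: PopulationSpec,
    design: ExperimentDesign,
    methods: Sequence[str],
    n_replicates: int,
    seed: int,
    config: MethodConfig = MethodConfig(),
    spec_name: str = "",
) -> GridCellResult:
    """One (population spec, design) cell of the simulation study.

    A fresh gold population of ``design.gold_standard_size`` individuals is
    generated for the cell; each replicate draws its own small case-control
    dataset from a fresh population and runs the full method suite with a
    derived seed.
    """
    name = spec_name or spec.covariate_model
    root = np.random.SeedSequence([int(seed), 71])
    gold_rng, *rep_rngs = [np.random.default_rng(s) for s in root.spawn(n_replicates + 1)]
    gold = generate_population(spec, design.gold_standard_size, gold_rng)
    records = []
    for j in range(n_replicates):
        small = draw_case_control(spec, design.n_cases, design.n_controls, rep_rngs[j])
        seed_j = int(np.random.SeedSequence([int(seed), 72, j]).generate_state(1)[0] % (2**31))
        rec = run_method_suite(small, gold, methods, replace(config, seed=seed_j), replicate_id=j)
        records.append(rec)
    return GridCellResult(name, spec.target_c, design, tuple(records), summarize_errors(records))


def simulation_grid(
    specs: Mapping[str, PopulationSpec],
    designs: Sequence[ExperimentDesign],
    methods: Sequence[str] = ALL_METHODS,
    n_replicates: int = 200,
    seed: int = 0,
    config: MethodConfig = MethodConfig(),
) -> list[GridCellResult]:
    """Run every (spec, design) cell; cell failures are recorded, not raised."""
    results = []
    for ci, (name, spec) in enumerate(sorted(specs.items())):
        for di, design in enumerate(designs):
            cell_seed = int(np.random.SeedSequence([int(seed), 73, ci, di]).generate_state(1)[0] % (2**31))
            try:
                results.append(
                    run_simulation_cell(spec, design, methods, n_replicates, cell_seed, config, name)
                )
            except OptimcvError as e:
                results.append(GridCellResult(name, spec.target_c, design, (), pd.DataFrame(), str(e)))
    return results
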
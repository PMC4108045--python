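"""Case-control dataset container and delimited-text I/O.

The unit of analysis everywhere in this package is a small case-control
dataset: a binary outcome (1 = case/event, 0 = control) plus a numeric
covariate matrix. Events per variable (EPV) — the number of cases divided by
the number of candidate predictors — is the quantity that drives overfitting
and hence optimism in the apparent C statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import OptimcvError

DEFAULT_OUTCOME_COL = "outcome"


@dataclass(frozen=True)
class CaseControlDataset:
    """Binary outcome plus numeric covariates.

    Parameters
    ----------
    outcome
        Length-n integer vector of 0/1 with at least one of each class.
    covariates
        n x p float matrix, no missing values.
    covariate_names
        p labels; defaults to x1..xp.
    """

    outcome: np.ndarray
    covariates: np.ndarray
    covariate_names: tuple[str, ...] = field(default=())

    def __post_init__(self):
        outcome = np.asarray(self.outcome)
        covariates = np.asarray(self.covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        if covariates.ndim != 2:
            raise OptimcvError("covariates must be a 2-D matrix")
        object.__setattr__(self, "covariates", covariates)
        if outcome.ndim != 1 or outcome.shape[0] != covariates.shape[0]:
            raise OptimcvError("outcome and covariates must have matching length")
        uniq = np.unique(outcome)
        if not np.all(np.isin(uniq, (0, 1))):
            raise OptimcvError("outcome must contain only 0 (control) and 1 (case)")
        object.__setattr__(self, "outcome", outcome.astype(np.int8))
        if self.n < 2:
            raise OptimcvError("dataset needs at least 2 rows")
        if self.n_cases == 0 or self.n_controls == 0:
            raise OptimcvError("dataset must contain at least one case and one control")
        if self.p < 1:
            raise OptimcvError("dataset needs at least one covariate")
        if not np.all(np.isfinite(covariates)):
            raise OptimcvError("covariates contain missing or non-finite values")
        names = tuple(self.covariate_names) or tuple(f"x{j + 1}" for j in range(self.p))
        if len(names) != self.p:
            raise OptimcvError(f"expected {self.p} covariate names, got {len(names)}")
        object.__setattr__(self, "covariate_names", names)

    # -- basic shape ---------------------------------------------------
    @property
    def n(self) -> int:
        return self.outcome.shape[0]

    @property
    def p(self) -> int:
        return self.covariates.shape[1]

    @property
    def n_cases(self) -> int:
        return int(np.sum(self.outcome == 1))

    @property
    def n_controls(self) -> int:
        return int(np.sum(self.outcome == 0))

    @property
    def epv(self) -> float:
        """Events per variable: cases / number of covariates."""
        return self.n_cases / self.p

    @property
    def case_indices(self) -> np.ndarray:
        return np.flatnonzero(self.outcome == 1)

    @property
    def control_indices(self) -> np.ndarray:
        return np.flatnonzero(self.outcome == 0)

    # -- derived datasets ----------------------------------------------
    def subset(self, indices: Sequence[int]) -> "CaseControlDataset":
        idx = np.asarray(indices, dtype=int)
        return CaseControlDataset(self.outcome[idx], self.covariates[idx], self.covariate_names)

    def drop_rows(self, indices: Sequence[int]) -> "CaseControlDataset":
        mask = np.ones(self.n, dtype=bool)
        mask[np.asarray(indices, dtype=int)] = False
        return CaseControlDataset(self.outcome[mask], self.covariates[mask], self.covariate_names)

    # -- pandas / CSV --------------------------------------------------
    def to_frame(self, outcome_col: str = DEFAULT_OUTCOME_COL) -> pd.DataFrame:
        df = pd.DataFrame(self.covariates, columns=list(self.covariate_names))
        df.insert(0, outcome_col, self.outcome.astype(int))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, outcome_col: str = DEFAULT_OUTCOME_COL) -> "CaseControlDataset":
        if outcome_col not in df.columns:
            raise OptimcvError(f"outcome column {outcome_col!r} not found in input")
        cov = df.drop(columns=[outcome_col])
        bad = [c for c in cov.columns if not np.issubdtype(np.asarray(cov[c]).dtype, np.number)]
        if bad:
            raise OptimcvError(f"non-numeric covariate columns: {bad}")
        return cls(df[outcome_col].to_numpy(), cov.to_numpy(dtype=float), tuple(map(str, cov.columns)))

    def write_csv(self, path: str | Path, outcome_col: str = DEFAULT_OUTCOME_COL) -> None:
        # 17 significant digits so floats round-trip exactly through text
        self.to_frame(outcome_col).to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path: str | Path, outcome_col: str = DEFAULT_OUTCOME_COL) -> "CaseControlDataset":
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"), outcome_col)
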
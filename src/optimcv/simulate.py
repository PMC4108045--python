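"""Synthetic populations for studying optimism correction at chosen EPV and C.

Two population generators emulate the statistical structure of the clinical
settings the methods are aimed at:

``down_like`` (p = 3)
    Antenatal aneuploidy screening. Maternal age follows a triangular
    distribution on [15, 47] with mode 31; two serum biomarkers (log10
    multiples of the median for alpha-fetoprotein and human chorionic
    gonadotropin) are bivariate normal with means linear in age. The binary
    outcome follows a logistic model in the three covariates.

``cesarean_like`` (p = 5)
    Emergency cesarean delivery in labouring nulliparous women at term.
    Gestational age is triangular on [37, 42] with mode 39.5; maternal age is
    uniform on [16, 37]; birthweight centile is uniform on [0, 100]; maternal
    height is normal with mean linear in age, gestational age and centile;
    infant sex is Bernoulli through a logistic link on the other four.
    The outcome again follows a logistic model in the five covariates.

The population C statistic — the discrimination of the *generating* model —
is controlled by multiplying all non-intercept outcome coefficients by a
single scale constant, calibrated by bisection against a Monte-Carlo
estimator on a common-random-numbers sample (targets such as 0.90 for the
down-like and 0.71 for the cesarean-like setting). Small study datasets are
then drawn case-control style (for example 15 cases and 60 controls for an
EPV of 5 on three predictors, with the 4:1 control:case ratio preserved as
EPV is scaled).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.special import expit

from .data import CaseControlDataset
from .errors import CalibrationError, OptimcvError, TooFewEventsError
from .metrics import concordance_statistic

DEFAULT_N_MC = 500_000
DEFAULT_CALIBRATION_TOL = 0.002


@dataclass(frozen=True)
class TriangularParams:
    low: float
    mode: float
    high: float

    def __post_init__(self):
        if not self.low < self.mode < self.high:
            raise OptimcvError("triangular parameters need low < mode < high")


@dataclass(frozen=True)
class UniformParams:
    low: float
    high: float

    def __post_init__(self):
        if not self.low < self.high:
            raise OptimcvError("uniform parameters need low < high")


def sample_triangular(low: float, mode: float, high: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF draws from a triangular distribution on [low, high]."""
    TriangularParams(low, mode, high)  # validates ordering
    u = rng.random(n)
    c = (mode - low) / (high - low)
    left = u < c
    out = np.empty(n)
    out[left] = low + np.sqrt(u[left] * (high - low) * (mode - low))
    out[~left] = high - np.sqrt((1.0 - u[~left]) * (high - low) * (high - mode))
    return out


@dataclass(frozen=True)
class DownCovariateParams:
    """Age-dependent bivariate-normal biomarkers on the log10-MoM scale.

    In unaffected pregnancies the multiple-of-the-median is 1 by construction,
    so the log10-MoM means sit near 0 with weak age trends; the SDs and the
    positive AFP-hCG correlation are typical of screening serum analytes.
    """

    age: TriangularParams = field(default_factory=lambda: TriangularParams(15.0, 31.0, 47.0))
    age_center: float = 31.0
    afp_mean: float = 0.0
    hcg_mean: float = 0.0
    afp_age_slope: float = -0.002
    hcg_age_slope: float = 0.003
    afp_sd: float = 0.20
    hcg_sd: float = 0.25
    biomarker_corr: float = 0.10

    def __post_init__(self):
        if self.afp_sd <= 0 or self.hcg_sd <= 0:
            raise OptimcvError("biomarker standard deviations must be positive")
        if not -1.0 < self.biomarker_corr < 1.0:
            raise OptimcvError("biomarker correlation must be in (-1, 1)")


@dataclass(frozen=True)
class CesareanCovariateParams:
    """Maternal/fetal covariates for the cesarean-like setting.

    Height (cm) is centred around 164 with mild dependence on the other
    continuous covariates; the sex link keeps male prevalence near 0.51.
    """

    gestation: TriangularParams = field(default_factory=lambda: TriangularParams(37.0, 39.5, 42.0))
    maternal_age: UniformParams = field(default_factory=lambda: UniformParams(16.0, 37.0))
    weight_centile: UniformParams = field(default_factory=lambda: UniformParams(0.0, 100.0))
    height_mean: float = 164.0
    height_age_slope: float = 0.08
    height_gestation_slope: float = 0.20
    height_weight_slope: float = 0.01
    height_sd: float = 6.5
    sex_intercept: float = 0.04
    sex_age_slope: float = 0.01
    sex_height_slope: float = 0.01
    sex_gestation_slope: float = 0.08
    sex_weight_slope: float = 0.002

    def __post_init__(self):
        if self.height_sd <= 0:
            raise OptimcvError("height standard deviation must be positive")


DOWN_NAMES = ("maternal_age", "log10_afp_mom", "log10_hcg_mom")
CESAREAN_NAMES = ("maternal_age", "height_cm", "gestational_age_wk", "infant_male", "birthweight_centile")

# Base outcome coefficients (before scaling). Signs follow clinical direction:
# Down risk rises with maternal age and hCG and falls with AFP; cesarean risk
# rises with maternal age, gestation, male sex and birthweight centile and
# falls with maternal height. Magnitudes are placeholders: the scale constant
# is calibrated so the generating model attains the requested population C.
_DOWN_COEF = (0.09, -4.0, 3.5)
_DOWN_INTERCEPT = -10.0  # ~1.5% prevalence at the scale reaching C = 0.90
_CESAREAN_COEF = (0.06, -0.06, 0.15, 0.25, 0.008)
_CESAREAN_INTERCEPT = 0.4  # ~15% prevalence at the scale reaching C = 0.71


@dataclass(frozen=True)
class PopulationSpec:
    """One synthetic population: covariate model + scaled logistic outcome."""

    covariate_model: Literal["down_like", "cesarean_like"]
    params: DownCovariateParams | CesareanCovariateParams
    intercept: float
    coefficients: tuple[float, ...]
    scale_constant: float = 1.0
    target_c: float | None = None

    def __post_init__(self):
        if self.scale_constant < 0:
            raise OptimcvError("scale_constant must be >= 0")
        expected = 3 if self.covariate_model == "down_like" else 5
        if len(self.coefficients) != expected:
            raise OptimcvError(f"{self.covariate_model} expects {expected} coefficients")

    @property
    def p(self) -> int:
        return len(self.coefficients)

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return DOWN_NAMES if self.covariate_model == "down_like" else CESAREAN_NAMES

    def scaled_coefficients(self) -> np.ndarray:
        return self.scale_constant * np.asarray(self.coefficients)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["coefficients"] = list(self.coefficients)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationSpec":
        d = dict(d)
        model = d["covariate_model"]
        pd_ = dict(d["params"])
        if model == "down_like":
            pd_["age"] = TriangularParams(**pd_["age"])
            params = DownCovariateParams(**pd_)
        elif model == "cesarean_like":
            pd_["gestation"] = TriangularParams(**pd_["gestation"])
            pd_["maternal_age"] = UniformParams(**pd_["maternal_age"])
            pd_["weight_centile"] = UniformParams(**pd_["weight_centile"])
            params = CesareanCovariateParams(**pd_)
        else:
            raise OptimcvError(f"unknown covariate model {model!r}")
        return cls(model, params, d["intercept"], tuple(d["coefficients"]),
                   d.get("scale_constant", 1.0), d.get("target_c"))

    def spec_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def down_like_spec(scale_constant: float = 1.0, target_c: float | None = 0.90) -> PopulationSpec:
    """Default down-like population spec (uncalibrated unless scale given)."""
    return PopulationSpec("down_like", DownCovariateParams(), _DOWN_INTERCEPT,
                          _DOWN_COEF, scale_constant, target_c)


def cesarean_like_spec(scale_constant: float = 1.0, target_c: float | None = 0.71) -> PopulationSpec:
    """Default cesarean-like population spec (uncalibrated unless scale given)."""
    return PopulationSpec("cesarean_like", CesareanCovariateParams(), _CESAREAN_INTERCEPT,
                          _CESAREAN_COEF, scale_constant, target_c)


# ---------------------------------------------------------------------------
# covariate + outcome generation
# ---------------------------------------------------------------------------

def _down_covariates(params: DownCovariateParams, n: int, rng) -> np.ndarray:
    age = sample_triangular(params.age.low, params.age.mode, params.age.high, n, rng)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    rho = params.biomarker_corr
    afp = params.afp_mean + params.afp_age_slope * (age - params.age_center) + params.afp_sd * z1
    hcg = (params.hcg_mean + params.hcg_age_slope * (age - params.age_center)
           + params.hcg_sd * (rho * z1 + np.sqrt(1 - rho ** 2) * z2))
    return np.column_stack([age, afp, hcg])


def _cesarean_covariates(params: CesareanCovariateParams, n: int, rng) -> np.ndarray:
    gest = sample_triangular(params.gestation.low, params.gestation.mode, params.gestation.high, n, rng)
    age = rng.uniform(params.maternal_age.low, params.maternal_age.high, n)
    wt = rng.uniform(params.weight_centile.low, params.weight_centile.high, n)
    age_c, gest_c, wt_c = age - 26.5, gest - 39.5, wt - 50.0
    height = (params.height_mean + params.height_age_slope * age_c
              + params.height_gestation_slope * gest_c
              + params.height_weight_slope * wt_c
              + params.height_sd * rng.standard_normal(n))
    sex_lp = (params.sex_intercept + params.sex_age_slope * age_c
              + params.sex_height_slope * (height - params.height_mean)
              + params.sex_gestation_slope * gest_c
              + params.sex_weight_slope * wt_c)
    sex = (rng.random(n) < expit(sex_lp)).astype(float)
    return np.column_stack([age, height, gest, sex, wt])


def generate_covariates(spec: PopulationSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec.covariate_model == "down_like":
        return _down_covariates(spec.params, n, rng)
    return _cesarean_covariates(spec.params, n, rng)


def linear_predictor(spec: PopulationSpec, covariates: np.ndarray) -> np.ndarray:
    """Generating-model linear predictor: intercept + scale * (beta . x)."""
    return spec.intercept + covariates @ spec.scaled_coefficients()


def generate_population(spec: PopulationSpec, n: int, rng: np.random.Generator) -> CaseControlDataset:
    """Draw n individuals: covariates per the spec, outcome ~ Bernoulli(expit(lp))."""
    X = generate_covariates(spec, n, rng)
    y = (rng.random(n) < expit(linear_predictor(spec, X))).astype(np.int8)
    return CaseControlDataset(y, X, spec.covariate_names)


def generate_down_population(n: int, spec: PopulationSpec, rng: np.random.Generator) -> CaseControlDataset:
    if spec.covariate_model != "down_like":
        raise OptimcvError("spec is not down_like")
    return generate_population(spec, n, rng)


def generate_cesarean_population(n: int, spec: PopulationSpec, rng: np.random.Generator) -> CaseControlDataset:
    if spec.covariate_model != "cesarean_like":
        raise OptimcvError("spec is not cesarean_like")
    return generate_population(spec, n, rng)


# ---------------------------------------------------------------------------
# population C and calibration
# ---------------------------------------------------------------------------

def population_c(
    spec: PopulationSpec,
    n_mc: int = DEFAULT_N_MC,
    rng: np.random.Generator | None = None,
    min_events: int = 1000,
) -> float:
    """Monte-Carlo estimate of the generating model's C on a fresh population."""
    rng = rng if rng is not None else np.random.default_rng()
    X = generate_covariates(spec, n_mc, rng)
    lp = linear_predictor(spec, X)
    y = rng.random(n_mc) < expit(lp)
    n_cases = int(y.sum())
    if n_cases < min_events or n_mc - n_cases < min_events:
        raise TooFewEventsError(
            f"Monte-Carlo sample has {n_cases} events of {n_mc}; need >= {min_events} per class"
        )
    return concordance_statistic(lp, y.astype(np.int8)).c


def _auc_se(c: float, n1: int, n0: int) -> float:
    """Hanley-McNeil standard error of an AUC estimate."""
    q1 = c / (2 - c)
    q2 = 2 * c * c / (1 + c)
    var = (c * (1 - c) + (n1 - 1) * (q1 - c * c) + (n0 - 1) * (q2 - c * c)) / (n1 * n0)
    return float(np.sqrt(max(var, 0.0)))


def calibrate_scale_constant(
    spec: PopulationSpec,
    target_c: float,
    tol: float = DEFAULT_CALIBRATION_TOL,
    rng: np.random.Generator | None = None,
    n_mc: int = DEFAULT_N_MC,
    bracket_high: float = 50.0,
    max_bracket_high: float = 1e6,
) -> PopulationSpec:
    """Bisect the coefficient scale constant until population C hits target_c.

    A single common-random-numbers sample (covariates and outcome uniforms
    drawn once) makes the empirical C an exactly non-decreasing function of
    the scale constant, so bisection is well posed. The returned spec is
    verified on an independent sample; the verification band is tol plus a
    3-SE Monte-Carlo allowance, since at finite n_mc the estimator's own
    sampling error is of the same order as tol.
    """
    if not 0.5 < target_c < 1.0:
        raise CalibrationError("target_c must be in (0.5, 1)")
    if tol <= 0:
        raise CalibrationError("tol must be positive")
    rng = rng if rng is not None else np.random.default_rng()
    rng_fit, rng_check = rng.spawn(2)

    X = generate_covariates(spec, n_mc, rng_fit)
    base_lp = X @ np.asarray(spec.coefficients)  # unit-scale contribution
    u = rng_fit.random(n_mc)

    def empirical_c(s: float) -> float:
        y = u < expit(spec.intercept + s * base_lp)
        n1 = int(y.sum())
        if n1 < 2 or n_mc - n1 < 2:
            raise TooFewEventsError(f"scale {s} leaves {n1} events in the calibration sample")
        return concordance_statistic(base_lp, y.astype(np.int8)).c

    lo, hi = 0.0, float(bracket_high)
    c_hi = empirical_c(hi)
    while c_hi < target_c and hi < max_bracket_high:
        hi *= 2.0
        c_hi = empirical_c(hi)
    c_lo = empirical_c(lo)
    if not c_lo - tol <= target_c <= c_hi + tol:
        raise CalibrationError(
            f"target C {target_c} unreachable: bracket C range [{c_lo:.4f}, {c_hi:.4f}]"
        )
    mid = 0.5 * (lo + hi)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        c_mid = empirical_c(mid)
        if abs(c_mid - target_c) <= 0.25 * tol:
            break
        if c_mid < target_c:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-9 * max(1.0, hi):
            break

    calibrated = replace(spec, scale_constant=float(mid), target_c=float(target_c))
    c_check = population_c(calibrated, n_mc, rng_check)
    n1 = max(int(round(n_mc * 0.005)), 100)  # conservative events count for the SE bound
    band = tol + 3.0 * _auc_se(target_c, n1, n_mc - n1)
    if abs(c_check - target_c) > max(band, 0.01):
        raise CalibrationError(
            f"calibrated C {c_check:.4f} misses target {target_c} beyond tolerance {band:.4f}"
        )
    return calibrated


# ---------------------------------------------------------------------------
# case-control sampling
# ---------------------------------------------------------------------------

def sample_case_control(
    population: CaseControlDataset,
    n_cases: int,
    n_controls: int,
    rng: np.random.Generator,
) -> CaseControlDataset:
    """Simple random sample without replacement within each outcome class."""
    if population.n_cases < n_cases or population.n_controls < n_controls:
        raise OptimcvError(
            f"population has {population.n_cases} cases / {population.n_controls} controls; "
            f"requested {n_cases}/{n_controls}"
        )
    ci = rng.choice(population.case_indices, size=n_cases, replace=False)
    ki = rng.choice(population.control_indices, size=n_controls, replace=False)
    return population.subset(np.concatenate([ci, ki]))


def draw_case_control(
    spec: PopulationSpec,
    n_cases: int,
    n_controls: int,
    rng: np.random.Generator,
    max_chunks: int = 60,
) -> CaseControlDataset:
    """Generate a fresh population big enough, then sample a case-control set.

    The population is grown in chunks until both classes are large enough,
    preserving the population-then-sample design (cases and controls keep the
    covariate distributions implied by the generating model and prevalence).
    """
    # pilot chunk to estimate prevalence (the intercept alone misleads when
    # the covariate spread contributes much of the linear predictor)
    pilot = 4000
    pX = generate_covariates(spec, pilot, rng)
    py = (rng.random(pilot) < expit(linear_predictor(spec, pX))).astype(np.int8)
    prev_guess = float(np.clip((py.sum() + 1) / (pilot + 2), 1e-4, 0.999))
    chunk = int(max(4 * n_cases / prev_guess, 4 * n_controls / (1 - prev_guess), 2000))
    ys, Xs = [py], [pX]
    tot_cases = int(py.sum())
    tot_controls = pilot - tot_cases
    if tot_cases >= n_cases and tot_controls >= n_controls:
        pop = CaseControlDataset(py, pX, spec.covariate_names)
        return sample_case_control(pop, n_cases, n_controls, rng)
    for _ in range(max_chunks):
        pop_X = generate_covariates(spec, chunk, rng)
        pop_y = (rng.random(chunk) < expit(linear_predictor(spec, pop_X))).astype(np.int8)
        ys.append(pop_y)
        Xs.append(pop_X)
        tot_cases += int(pop_y.sum())
        tot_controls += int(chunk - pop_y.sum())
        if tot_cases >= n_cases and tot_controls >= n_controls:
            pop = CaseControlDataset(np.concatenate(ys), np.vstack(Xs), spec.covariate_names)
            return sample_case_control(pop, n_cases, n_controls, rng)
    raise TooFewEventsError(
        f"could not accumulate {n_cases} cases after {max_chunks} chunks of {chunk}"
    )


@dataclass(frozen=True)
class ExperimentDesign:
    """Case/control counts for one simulation cell (control:case ratio 4:1)."""

    n_cases: int
    n_controls: int
    n_replicates: int = 200
    gold_standard_size: int = 100_000

    def epv(self, p: int) -> float:
        return self.n_cases / p


def design_for_epv(epv: float, p: int, control_ratio: float = 4.0, **kw) -> ExperimentDesign:
    """Design with n_cases = epv * p and the standard 4 controls per case."""
    n_cases = int(round(epv * p))
    return ExperimentDesign(n_cases, int(round(control_ratio * n_cases)), **kw)
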
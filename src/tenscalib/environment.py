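"""Data-driven simulated environment for offline agent training.

During offline training the recruited subject is replaced by three models
fitted on a trial dataset, one per answer component:

* perceived intensity -- ordinary least squares on the 4-level code
  (0 = not perceived .. 3 = too high) with a PA x PW interaction term,
  decoded by round-and-clamp;
* sensation type -- a majority-vote ensemble of k-nearest-neighbour
  classifiers, each trained on a random subset of the features
  (random-subspace ensemble); ties resolve to "comfortable";
* location -- Gaussian-process regression on the 0/1 somatotopy label with
  an exponential kernel k(x, x') = sf^2 * exp(-||x - x'|| / l), binarised
  at a probability threshold.

Features are PA, PW, PA*PW plus the subject covariates (gender, weight,
nerve), z-scored for the distance-based models, so that between-subject
variability flows through the simulated answers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.linalg import cho_factor, cho_solve
from sklearn.linear_model import LinearRegression
from sklearn.neighbors import KNeighborsClassifier

from .core import (
    Intensity,
    Location,
    ParamGrid,
    SensationReport,
    SensationType,
    StimParams,
    encode_state,
)

__all__ = [
    "EnvConfig",
    "EnvModels",
    "fit_environment",
    "predict_intensity",
    "predict_type",
    "predict_location",
    "env_step",
    "grid_state_table",
]

FEATURE_NAMES = [
    "pa", "pw", "pa_pw", "inv_pw", "gender_code", "weight_kg",
    "nerve_peroneal", "nerve_tibial", "nerve_sural",
]

_INTENSITY_CODE = {"NP": 0, "LOW": 1, "HIGH": 2, "TOOHIGH": 3}


@dataclass(frozen=True)
class EnvConfig:
    n_learners: int = 30
    knn_k: int = 5
    subspace_size: int | None = None  # default ceil(sqrt(n_features))
    gp_sigma_f: float = 1.0
    gp_noise: float = 1e-4  # sn^2
    gp_length: float | None = None  # default: median pairwise distance
    location_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.location_threshold < 1.0:
            raise ValueError("location threshold must lie in (0, 1)")
        if self.n_learners < 1:
            raise ValueError("type ensemble needs at least one learner")


def _covariate_features(gender: str, weight: float, nerve: str) -> list[float]:
    return [
        1.0 if gender == "M" else 0.0,
        float(weight),
        float(nerve == "peroneal"),
        float(nerve == "tibial"),
        float(nerve == "sural"),
    ]


def build_features(
    pa: np.ndarray, pw: np.ndarray, gender: str, weight: float, nerve: str
) -> np.ndarray:
    """Feature matrix for a single subject over arrays of (PA, PW)."""
    pa = np.asarray(pa, dtype=float)
    pw = np.asarray(pw, dtype=float)
    cov = np.tile(_covariate_features(gender, weight, nerve), (pa.size, 1))
    # 1000/pw captures the strength-duration threshold shape (the perception
    # threshold is linear in PA and 1/PW), which a plane in (PA, PW) cannot
    return np.column_stack([pa, pw, pa * pw, 1000.0 / pw, cov])


def features_from_trials(trials: pd.DataFrame) -> np.ndarray:
    pa = trials["pa_mA"].to_numpy(float)
    pw = trials["pw_us"].to_numpy(float)
    cov = np.array(
        [
            _covariate_features(g, w, n)
            for g, w, n in zip(trials["gender"], trials["weight_kg"], trials["nerve"])
        ]
    )
    return np.column_stack([pa, pw, pa * pw, 1000.0 / pw, cov])


@dataclass
class EnvModels:
    """The three fitted predictors plus the shared feature scaler."""

    config: EnvConfig
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    intensity_model: LinearRegression | float  # float => constant fallback
    type_learners: list  # (feature index array, fitted KNN) pairs
    type_constant: int | None
    gp_X: np.ndarray | None  # standardized training features
    gp_alpha: np.ndarray | None  # K^-1 y
    gp_length: float
    location_constant: int | None
    version: str = "tenscalib-env-1"

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scaler_mean) / self.scaler_std


def _median_heuristic(Xs: np.ndarray, rng: np.random.Generator) -> float:
    sub = Xs if len(Xs) <= 400 else Xs[rng.choice(len(Xs), 400, replace=False)]
    d = cdist(sub, sub)
    med = float(np.median(d[np.triu_indices_from(d, k=1)]))
    return med if med > 0 else 1.0


def fit_environment(trials: pd.DataFrame, config: EnvConfig = EnvConfig()) -> EnvModels:
    """Fit the three predictors on a trial table (see io.TRIAL_COLUMNS)."""
    if trials.empty:
        raise ValueError("cannot fit the environment on an empty trial table")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    X = features_from_trials(trials)
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Xs = (X - mean) / std

    # -- intensity: OLS with interaction on the 4-level code ----------------
    y_int = trials["intensity"].map(_INTENSITY_CODE).to_numpy(float)
    if np.unique(y_int).size == 1:
        warnings.warn("intensity labels are single-class; using constant predictor")
        intensity_model: LinearRegression | float = float(y_int[0])
    else:
        intensity_model = LinearRegression().fit(X, y_int)

    # -- type: random-subspace KNN ensemble ---------------------------------
    y_type = (trials["stype"] == "COM").to_numpy(int)
    n_feat = X.shape[1]
    sub_size = config.subspace_size or int(np.ceil(np.sqrt(n_feat)))
    type_learners: list = []
    type_constant: int | None = None
    if np.unique(y_type).size == 1:
        warnings.warn("type labels are single-class; using constant predictor")
        type_constant = int(y_type[0])
    else:
        k = min(config.knn_k, len(trials))
        for _ in range(config.n_learners):
            idx = rng.choice(n_feat, size=sub_size, replace=False)
            knn = KNeighborsClassifier(n_neighbors=k).fit(Xs[:, idx], y_type)
            type_learners.append((idx, knn))

    # -- location: exponential-kernel GP regression on the 0/1 label --------
    y_loc = (trials["location"] == "SOM").to_numpy(float)
    location_constant: int | None = None
    gp_X = gp_alpha = None
    length = config.gp_length or _median_heuristic(Xs, rng)
    if np.unique(y_loc).size == 1:
        warnings.warn("location labels are single-class; using constant predictor")
        location_constant = int(y_loc[0])
    else:
        K = config.gp_sigma_f**2 * np.exp(-cdist(Xs, Xs) / length)
        K[np.diag_indices_from(K)] += config.gp_noise
        gp_alpha = cho_solve(cho_factor(K, lower=True), y_loc)
        gp_X = Xs

    return EnvModels(
        config=config,
        scaler_mean=mean,
        scaler_std=std,
        intensity_model=intensity_model,
        type_learners=type_learners,
        type_constant=type_constant,
        gp_X=gp_X,
        gp_alpha=gp_alpha,
        gp_length=length,
        location_constant=location_constant,
    )


def _intensity_codes(m: EnvModels, X: np.ndarray) -> np.ndarray:
    if isinstance(m.intensity_model, float):
        raw = np.full(len(X), m.intensity_model)
    else:
        raw = m.intensity_model.predict(X)
    return np.clip(np.rint(raw), 0, 3).astype(int)


def _type_codes(m: EnvModels, Xs: np.ndarray) -> np.ndarray:
    if m.type_constant is not None:
        return np.full(len(Xs), m.type_constant, dtype=int)
    votes = np.zeros(len(Xs))
    for idx, knn in m.type_learners:
        votes += knn.predict(Xs[:, idx])
    # strict majority for "uncomfortable": ties resolve to comfortable
    return (votes >= len(m.type_learners) / 2.0).astype(int)


def _location_posterior(m: EnvModels, Xs: np.ndarray) -> np.ndarray:
    if m.location_constant is not None:
        return np.full(len(Xs), float(m.location_constant))
    k_star = m.config.gp_sigma_f**2 * np.exp(-cdist(Xs, m.gp_X) / m.gp_length)
    return np.clip(k_star @ m.gp_alpha, 0.0, 1.0)


def _location_codes(m: EnvModels, Xs: np.ndarray) -> np.ndarray:
    return (_location_posterior(m, Xs) > m.config.location_threshold).astype(int)


def predict_intensity(m: EnvModels, features: np.ndarray) -> Intensity:
    """Four-level perceived intensity from raw (unstandardized) features."""
    X = np.atleast_2d(features)
    return Intensity(int(_intensity_codes(m, X)[0]))


def predict_type(m: EnvModels, features: np.ndarray) -> SensationType:
    Xs = m.standardize(np.atleast_2d(features))
    return SensationType(int(_type_codes(m, Xs)[0]))


def predict_location(m: EnvModels, features: np.ndarray) -> Location:
    Xs = m.standardize(np.atleast_2d(features))
    return Location(int(_location_codes(m, Xs)[0]))


def env_step(
    m: EnvModels,
    gender: str,
    weight: float,
    nerve: str,
    p: StimParams,
) -> tuple[int, SensationReport]:
    """Simulated answer to one stimulus: (state id, report without SE)."""
    X = build_features(np.array([p.pa]), np.array([p.pw]), gender, weight, nerve)
    Xs = m.standardize(X)
    intensity = Intensity(int(_intensity_codes(m, X)[0]))
    report = SensationReport(
        intensity=intensity,
        stype=SensationType(int(_type_codes(m, Xs)[0])),
        location=Location(int(_location_codes(m, Xs)[0])),
    )
    return encode_state(report), report


def grid_state_table(
    m: EnvModels, gender: str, weight: float, nerve: str, grid: ParamGrid
) -> np.ndarray:
    """State id for every grid point, shape (n_pa, n_pw).

    Batch evaluation of :func:`env_step` over the whole grid; used to make
    training and testing episodes cheap (one table lookup per step).
    """
    pa = np.repeat(np.asarray(grid.pa_values, float), len(grid.pw_values))
    pw = np.tile(np.asarray(grid.pw_values, float), len(grid.pa_values))
    X = build_features(pa, pw, gender, weight, nerve)
    Xs = m.standardize(X)
    codes = _intensity_codes(m, X)
    types = _type_codes(m, Xs)
    locs = _location_codes(m, Xs)
    state = np.where(codes == 0, 0, 1 + 4 * (codes - 1) + 2 * locs + types)
    return state.reshape(len(grid.pa_values), len(grid.pw_values))
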
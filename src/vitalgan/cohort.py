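"""Simulated COPD monitoring cohorts.

One subject measured daily produces a small multivariate record stream: ten
correlated vital signs plus PEF, with the binary class cut at PEF = 400 L/min.
The simulator draws class-conditional multivariate Gaussians (shared
correlation structure, class-shifted means for the respiratory and
cardiovascular features), clamps to physiological bounds, and then rederives
each record's label from its generated PEF — so label and PEF can never
disagree, exactly as in the real labelling rule.

Default effect sizes make an FEV1 threshold rule learnable from ~43 records,
the regime the pipeline is designed for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .schema import (
    CLASS_HIGH,
    CLASS_LOW,
    FEATURE_NAMES,
    LabeledDataset,
    ValidationError,
    derive_label,
)

# (class-low mean, class-high mean, sd). "high" = good breathing performance
# (PEF >= 400): higher FEV1/PEF/MAP and pressures, lower resting heart rate.
_DEFAULT_MOMENTS: dict[str, tuple[float, float, float]] = {
    "oxygen": (95.0, 95.0, 1.5),
    "body_temperature": (36.6, 36.6, 0.3),
    "heart_rate": (80.0, 70.0, 6.0),
    "heart_rate_master": (80.0, 70.0, 6.0),
    "weight": (78.0, 78.0, 8.0),
    "bmi": (26.0, 26.0, 3.0),
    "fev1": (2.0, 2.6, 0.25),
    "pef": (360.0, 440.0, 30.0),
    "map": (88.0, 95.0, 6.0),
    "diastolic_pressure": (74.0, 80.0, 7.0),
    "systolic_pressure": (116.0, 125.0, 9.0),
}

_DEFAULT_CORRELATIONS: dict[tuple[str, str], float] = {
    ("fev1", "pef"): 0.7,
    ("systolic_pressure", "map"): 0.8,
    ("diastolic_pressure", "map"): 0.8,
    ("heart_rate", "heart_rate_master"): 0.9,
    # systolic and diastolic pressure are themselves correlated; without this
    # the MAP block above would not be positive semi-definite
    ("diastolic_pressure", "systolic_pressure"): 0.5,
}

#: Hard physiological clamps applied after sampling.
_BOUNDS: dict[str, tuple[float, float]] = {
    "oxygen": (70.0, 100.0),
    "body_temperature": (34.0, 42.0),
    "heart_rate": (35.0, 200.0),
    "heart_rate_master": (35.0, 200.0),
    "weight": (30.0, 250.0),
    "bmi": (12.0, 60.0),
    "fev1": (0.4, 6.0),
    "pef": (60.0, 800.0),
    "map": (50.0, 150.0),
    "diastolic_pressure": (35.0, 130.0),
    "systolic_pressure": (70.0, 230.0),
}

#: FEV1 value at which the two class-conditional densities cross (equal sds):
#: the midpoint of the class means.  Rule-recovery checks compare learned
#: thresholds against this.
FEV1_CLASS_BOUNDARY = 0.5 * (_DEFAULT_MOMENTS["fev1"][0] + _DEFAULT_MOMENTS["fev1"][1])


def default_correlation_matrix() -> np.ndarray:
    k = len(FEATURE_NAMES)
    R = np.eye(k)
    idx = {n: i for i, n in enumerate(FEATURE_NAMES)}
    for (a, b), r in _DEFAULT_CORRELATIONS.items():
        R[idx[a], idx[b]] = R[idx[b], idx[a]] = r
    return R


def _nearest_psd_correlation(R: np.ndarray) -> np.ndarray:
    """Eigenvalue-clip projection to the nearest PSD matrix, diag rescaled to 1."""
    w, V = np.linalg.eigh(R)
    w = np.clip(w, 0.0, None)
    S = (V * w) @ V.T
    d = np.sqrt(np.clip(np.diag(S), 1e-12, None))
    return S / np.outer(d, d)


@dataclass
class CohortParams:
    """Class-conditional moments, correlation structure and sampling knobs.

    ``moments`` maps each of the 11 features to ``(mean_low, mean_high, sd)``;
    ``correlation`` is the shared 11x11 feature correlation matrix;
    ``p_high`` is the prevalence of the initially drawn class; ``rho`` an
    optional AR(1) coefficient for day-to-day autocorrelation along record
    order; ``seed`` the default random seed.
    """

    moments: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_MOMENTS)
    )
    correlation: np.ndarray = field(default_factory=default_correlation_matrix)
    p_high: float = 0.5
    rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        missing = set(FEATURE_NAMES) - set(self.moments)
        if missing:
            raise ValidationError(f"moments missing for features: {sorted(missing)}")
        for name, (_, _, sd) in self.moments.items():
            if not sd > 0:
                raise ValidationError(f"standard deviation must be > 0 for {name}")
        if not 0.0 <= self.p_high <= 1.0:
            raise ValidationError("p_high must lie in [0, 1]")
        if not abs(self.rho) < 1.0:
            raise ValidationError("|rho| must be < 1")
        R = np.asarray(self.correlation, dtype=float)
        k = len(FEATURE_NAMES)
        if R.shape != (k, k):
            raise ValidationError(f"correlation matrix must be {k}x{k}")
        if not np.allclose(R, R.T, atol=1e-10):
            raise ValidationError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-10):
            raise ValidationError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-10:
            warnings.warn(
                "correlation matrix not positive semi-definite; "
                "projected to the nearest PSD matrix",
                UserWarning,
                stacklevel=2,
            )
            R = _nearest_psd_correlation(R)
        self.correlation = R

    def class_moments(self, cls: str) -> tuple[np.ndarray, np.ndarray]:
        i = 1 if cls == CLASS_HIGH else 0
        mu = np.array([self.moments[n][i] for n in FEATURE_NAMES])
        sd = np.array([self.moments[n][2] for n in FEATURE_NAMES])
        return mu, sd


def generate_cohort(
    n: int, params: CohortParams | None = None, seed: int | None = None
) -> LabeledDataset:
    """Draw ``n`` simulated monitoring records.

    Procedure: draw a class per record by prevalence; draw correlated standard
    normals (Cholesky of the correlation matrix, optional AR(1) filtering over
    record order); scale/shift by the class-conditional moments; clamp to
    physiological bounds; finally *rederive* the label from the generated PEF
    so every record satisfies ``label == derive_label(pef)``.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    params = params or CohortParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    k = len(FEATURE_NAMES)

    drawn_high = rng.random(n) < params.p_high
    eps = rng.standard_normal((n, k))
    if params.rho != 0.0:
        z = np.empty_like(eps)
        z[0] = eps[0]
        c = np.sqrt(1.0 - params.rho**2)
        for t in range(1, n):
            z[t] = params.rho * z[t - 1] + c * eps[t]
    else:
        z = eps
    L = np.linalg.cholesky(params.correlation + 1e-12 * np.eye(k))
    u = z @ L.T

    mu_lo, sd = params.class_moments(CLASS_LOW)
    mu_hi, _ = params.class_moments(CLASS_HIGH)
    mu = np.where(drawn_high[:, None], mu_hi, mu_lo)
    X = mu + u * sd
    lo = np.array([_BOUNDS[nm][0] for nm in FEATURE_NAMES])
    hi = np.array([_BOUNDS[nm][1] for nm in FEATURE_NAMES])
    X = np.clip(X, lo, hi)

    pef_idx = FEATURE_NAMES.index("pef")
    pef = X[:, pef_idx]
    labels = np.array([derive_label(v) for v in pef], dtype=object)
    predictors = np.delete(X, pef_idx, axis=1)
    return LabeledDataset(predictors, labels, provenance="simulated", pef=pef)
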
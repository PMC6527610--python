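"""Pupil light-reflex model: steady pupil diameter vs corneal stimulus.

The model is a decreasing logistic in the combined melanopic + photopic
drive,

    d(M, L) = A / (1 + exp(k_M M + k_L L)) + d0        [mm]

with amplitude A, floor d0 (the fully constricted diameter) and
non-negative gains k_M (per melanopic cd/m^2) and k_L (per cd/m^2).  At
zero stimulus the diameter is A/2 + d0; for very bright stimuli it tends
to d0.  The reference coefficient set (A = 1.74 mm, k_M = 0.0040,
k_L = 0.0012, d0 = 2.58 mm) is the published fit of this form to minimum
pupil diameters measured under six-primary metameric white stimuli and is
used as the generative default for simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "PupilParams",
    "REFERENCE_PUPIL_PARAMS",
    "predict_pupil",
    "PupilReflexModel",
    "fit_pupil",
]


@dataclass(frozen=True)
class PupilParams:
    """Coefficients of the logistic pupil model."""

    amplitude_mm: float  # A
    melanopic_gain: float  # k_M, per melanopic cd/m^2
    photopic_gain: float  # k_L, per cd/m^2
    floor_mm: float  # d0

    def __post_init__(self):
        if self.amplitude_mm <= 0 or self.floor_mm <= 0:
            raise ValueError("amplitude and floor must be positive")
        if self.melanopic_gain < 0 or self.photopic_gain < 0:
            raise ValueError("gains must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.amplitude_mm, self.melanopic_gain, self.photopic_gain, self.floor_mm]
        )


#: published coefficients of the logistic fit (minimum diameters, pooled data)
REFERENCE_PUPIL_PARAMS = PupilParams(1.74, 0.0040, 0.0012, 2.58)


def predict_pupil(M, L, params: PupilParams = REFERENCE_PUPIL_PARAMS):
    """Pupil diameter (mm) for melanopic luminance M and luminance L."""
    M = np.asarray(M, dtype=float)
    L = np.asarray(L, dtype=float)
    if np.any(M < 0) or np.any(L < 0):
        raise ValueError("stimulus intensities must be >= 0")
    drive = params.melanopic_gain * M + params.photopic_gain * L
    # A/(1+e^drive) = A*expit(-drive), overflow-safe for large drives
    d = params.amplitude_mm * expit(-drive) + params.floor_mm
    return d if d.shape else float(d)


def _softplus(x):
    return np.logaddexp(0.0, x)


def _softplus_inv(y):
    y = np.maximum(y, 1e-12)
    return y + np.log1p(-np.exp(-y))


class PupilReflexModel(RegressorMixin, BaseEstimator):
    """Scikit-learn style estimator for the logistic pupil model.

    Parameters
    ----------
    n_starts : int
        Number of multi-start initialisations for the nonlinear least
        squares (logistic fits are initialisation-sensitive).
    random_state : int
        Seed for the start-point jitter; fits are fully deterministic.

    Attributes
    ----------
    params_ : PupilParams
        Fitted coefficients.
    amplitude_mm_, melanopic_gain_, photopic_gain_, floor_mm_ : float
        The same coefficients individually.
    r_squared_ : float
        1 - SSres/SStot of the fit on the training data.
    """

    def __init__(self, n_starts: int = 5, random_state: int = 0):
        self.n_starts = n_starts
        self.random_state = random_state

    # internal parameterisation: [log A, raw kM, raw kL, log d0] with
    # softplus on the gains so positivity cannot be violated mid-search
    @staticmethod
    def _unpack(theta) -> PupilParams:
        return PupilParams(
            float(np.exp(theta[0])),
            float(_softplus(theta[1])),
            float(_softplus(theta[2])),
            float(np.exp(theta[3])),
        )

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=6)
        if X.shape[1] != 2:
            raise ValueError("X must have two columns: melanopic M and luminance L")
        if np.any(X < 0):
            raise ValueError("stimulus intensities must be >= 0")
        M, L = X[:, 0], X[:, 1]
        conditions = {(round(m, 9), round(l, 9)) for m, l in zip(M, L)}
        if len(conditions) < 6:
            raise ValueError("need >= 6 distinct (M, L) conditions")
        if np.linalg.matrix_rank(np.column_stack([M, L]), tol=1e-10 * max(M.max(), 1))\
                < 2:
            warnings.warn(
                "M and L are proportional across all rows; the two gains are "
                "not separately identifiable",
                stacklevel=2,
            )

        span = max(y.max() - y.min(), 0.05)
        scale_m = max(M.max(), 1.0)
        scale_l = max(L.max(), 1.0)
        base = np.array(
            [
                np.log(2.0 * span),
                _softplus_inv(1.0 / scale_m),
                _softplus_inv(1.0 / scale_l),
                np.log(max(y.min() * 0.9, 0.05)),
            ]
        )
        rng = np.random.default_rng(self.random_state)

        def residuals(theta):
            p = self._unpack(theta)
            return predict_pupil(M, L, p) - y

        best = None
        for k in range(self.n_starts):
            x0 = base if k == 0 else base + rng.normal(0.0, 0.5, size=4)
            sol = least_squares(residuals, x0, method="trf", xtol=1e-14, ftol=1e-14)
            if best is None or sol.cost < best.cost - 1e-15:
                best = sol
        self.params_ = self._unpack(best.x)
        self.amplitude_mm_ = self.params_.amplitude_mm
        self.melanopic_gain_ = self.params_.melanopic_gain
        self.photopic_gain_ = self.params_.photopic_gain
        self.floor_mm_ = self.params_.floor_mm
        ss_res = 2.0 * best.cost
        ss_tot = float(((y - y.mean()) ** 2).sum())
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        self.n_features_in_ = 2
        return self

    def predict(self, X):
        check_is_fitted(self, "params_")
        X = check_array(X)
        return predict_pupil(X[:, 0], X[:, 1], self.params_)


def fit_pupil(data, n_starts: int = 5, random_state: int = 0):
    """Fit the logistic pupil model to (M, L, d) triples.

    ``data`` may be an (n, 3) array or a DataFrame with columns
    ``M, L, d_mm``.  Returns ``(PupilParams, r_squared)``.
    """
    if isinstance(data, pd.DataFrame):
        arr = data[["M", "L", "d_mm"]].to_numpy(float)
    else:
        arr = np.asarray(data, dtype=float)
    model = PupilReflexModel(n_starts=n_starts, random_state=random_state)
    model.fit(arr[:, :2], arr[:, 2])
    return model.params_, model.r_squared_
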
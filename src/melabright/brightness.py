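"""Two-term power-law brightness model and the melanopsin contribution ratio.

Perceived brightness R (magnitude-estimation units, reference = 100) is
modelled as the sum of a melanopsin term and a cone term acting on the
*retinal* stimulus,

    R = a G^alpha + b E^beta,

with G the melanopic retinal illuminance (melanopic cd/m^2 mm^2) and E the
retinal illuminance (trolands); both are corneal quantities multiplied by
the pupil area S = pi (d/2)^2.  The melanopsin exponent alpha is close to
1 (a luxotonic, nearly linear drive) while the cone exponent beta is
strongly compressive, so the melanopsin share of brightness grows with
stimulus intensity.  The reference coefficient set
(a = 4.84e-3, alpha = 1.1, b = 2.31, beta = 0.48) is the published fit to
magnitude-estimation data under metameric white stimuli.

The melanopsin *contribution ratio* is the melanopsin term's share,
a G^alpha / (a G^alpha + b E^beta).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares, nnls
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .pupil import PupilParams, predict_pupil
from .spectra import pupil_area_mm2

__all__ = [
    "BrightnessParams",
    "REFERENCE_BRIGHTNESS_PARAMS",
    "FitResult",
    "predict_brightness_retinal",
    "predict_brightness_corneal",
    "contribution_ratio",
    "equibrightness_shift",
    "BrightnessModel",
    "fit_brightness",
    "normalized_to_reference",
]


@dataclass(frozen=True)
class BrightnessParams:
    """Coefficients of the two-term power-law brightness model."""

    coef_mel: float  # a
    exp_mel: float  # alpha
    coef_cone: float  # b
    exp_cone: float  # beta

    def __post_init__(self):
        if min(self.coef_mel, self.exp_mel, self.coef_cone, self.exp_cone) <= 0:
            raise ValueError("all brightness coefficients must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.coef_mel, self.exp_mel, self.coef_cone, self.exp_cone])


#: published coefficients (magnitude estimation, reference rating = 100)
REFERENCE_BRIGHTNESS_PARAMS = BrightnessParams(4.84e-3, 1.1, 2.31, 0.48)


def predict_brightness_retinal(G, E, params: BrightnessParams = REFERENCE_BRIGHTNESS_PARAMS):
    """R = a G^alpha + b E^beta for retinal inputs G, E (>= 0)."""
    G = np.asarray(G, dtype=float)
    E = np.asarray(E, dtype=float)
    if np.any(G < 0) or np.any(E < 0):
        raise ValueError("retinal stimulus intensities must be >= 0")
    r = params.coef_mel * G**params.exp_mel + params.coef_cone * E**params.exp_cone
    return r if r.shape else float(r)


def predict_brightness_corneal(
    M,
    L,
    pupil_params: PupilParams,
    brightness_params: BrightnessParams = REFERENCE_BRIGHTNESS_PARAMS,
):
    """Brightness from corneal quantities, composing the pupil model.

    The pupil diameter predicted from (M, L) converts the corneal stimulus
    to retinal illuminances G = M S and E = L S with S = pi (d/2)^2.
    """
    M = np.asarray(M, dtype=float)
    L = np.asarray(L, dtype=float)
    if np.any(M < 0) or np.any(L < 0):
        raise ValueError("corneal stimulus intensities must be >= 0")
    d = predict_pupil(M, L, pupil_params)
    s = np.pi * (np.asarray(d) / 2.0) ** 2
    return predict_brightness_retinal(M * s, L * s, brightness_params)


def contribution_ratio(G, E, params: BrightnessParams = REFERENCE_BRIGHTNESS_PARAMS):
    """Melanopsin share of modeled brightness, in (0, 1)."""
    G = np.asarray(G, dtype=float)
    E = np.asarray(E, dtype=float)
    mel = params.coef_mel * G**params.exp_mel
    cone = params.coef_cone * E**params.exp_cone
    total = mel + cone
    if np.any(total <= 0):
        raise ValueError("contribution ratio undefined when both terms are zero")
    r = mel / total
    return r if r.shape else float(r)


def equibrightness_shift(
    melanopic_contrast: float,
    operating_point: tuple,
    brightness_params: BrightnessParams = REFERENCE_BRIGHTNESS_PARAMS,
    pupil_params: PupilParams | None = None,
    bracket: tuple = (0.25, 4.0),
) -> float:
    """Radiance increase needed to match a melanopsin-boosted reference.

    The reference stimulus shares the operating point ``(L, M/P ratio)``
    but has its melanopic excitation raised by ``melanopic_contrast``
    (e.g. 0.11 for +11%) at unchanged cone excitation; the test stimulus
    is the operating-point spectrum scaled uniformly in radiance by a
    factor ``s`` until it matches the reference brightness.  Returns
    ``s - 1``.  With the pupil model supplied the pupil re-adapts at each
    radiance, as in a real viewing situation.
    """
    L0, mp = operating_point
    if L0 <= 0 or mp <= 0:
        raise ValueError("operating point must have positive luminance and M/P")
    M0 = mp * L0
    from .pupil import REFERENCE_PUPIL_PARAMS

    pp = REFERENCE_PUPIL_PARAMS if pupil_params is None else pupil_params

    r_ref = predict_brightness_corneal(
        M0 * (1.0 + melanopic_contrast), L0, pp, brightness_params
    )

    def gap(s):
        return predict_brightness_corneal(s * M0, s * L0, pp, brightness_params) - r_ref

    lo, hi = bracket
    if gap(lo) * gap(hi) > 0:
        raise ValueError("no equibrightness root inside the radiance bracket")
    s = brentq(gap, lo, hi, xtol=1e-12, rtol=1e-12)
    return s - 1.0


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of a brightness-model fit."""

    params: BrightnessParams | None
    coef_cone: float
    exp_cone: float
    r_squared: float
    residuals: pd.DataFrame
    model: str  # "full" | "cone-only"


class BrightnessModel(RegressorMixin, BaseEstimator):
    """Scikit-learn style estimator for the two-term power-law model.

    Parameters
    ----------
    model : {"full", "cone-only"}
        ``"full"`` fits (a, alpha, b, beta); ``"cone-only"`` drops the
        melanopsin term and fits (b, beta) alone — the nested reduction
        used to show that cones cannot explain the data.
    n_starts : int
        Multi-start count over neutral exponent initialisations.
    random_state : int
        Seed for start-point jitter (fits remain deterministic).

    Attributes
    ----------
    params_ : BrightnessParams (full model only)
    coef_mel_, exp_mel_, coef_cone_, exp_cone_ : float
    r_squared_ : float
    """

    _EXPONENT_STARTS = ((1.0, 0.5), (0.7, 0.7), (1.3, 0.4), (0.5, 1.0), (1.0, 1.0))

    def __init__(self, model: str = "full", n_starts: int = 5, random_state: int = 0):
        self.model = model
        self.n_starts = n_starts
        self.random_state = random_state

    def fit(self, X, y):
        if self.model not in ("full", "cone-only"):
            raise ValueError("model must be 'full' or 'cone-only'")
        X, y = check_X_y(X, y, ensure_min_samples=8)
        if X.shape[1] != 2:
            raise ValueError("X must have two columns: G and E")
        if np.any(X < 0) or np.any(y < 0):
            raise ValueError("stimuli and ratings must be >= 0")
        G, E = X[:, 0], X[:, 1]
        if len({(round(g, 9), round(e, 9)) for g, e in zip(G, E)}) < 8:
            raise ValueError("need >= 8 distinct (G, E) conditions")
        with np.errstate(divide="ignore"):
            rank = np.linalg.matrix_rank(
                np.column_stack([np.log(np.maximum(G, 1e-300)),
                                 np.log(np.maximum(E, 1e-300)),
                                 np.ones_like(G)]), tol=1e-8
            )
        if self.model == "full" and rank < 3:
            warnings.warn(
                "G and E are proportional across all rows; melanopsin and cone "
                "terms are not separately identifiable",
                stacklevel=2,
            )

        rng = np.random.default_rng(self.random_state)
        best = None
        starts = self._EXPONENT_STARTS[: max(self.n_starts, 1)]
        for k, (a0, b0) in enumerate(starts):
            exps = np.array([a0, b0])
            if k > 0:
                exps = exps * np.exp(rng.normal(0.0, 0.05, size=2))
            theta0 = self._initial_theta(G, E, y, *exps)
            sol = least_squares(
                self._residuals, theta0, args=(G, E, y),
                method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            if best is None or sol.cost < best.cost - 1e-15:
                best = sol
        theta = best.x
        if self.model == "full":
            self.coef_mel_ = float(np.exp(theta[0]))
            self.exp_mel_ = float(np.exp(theta[1]))
            self.coef_cone_ = float(np.exp(theta[2]))
            self.exp_cone_ = float(np.exp(theta[3]))
            self.params_ = BrightnessParams(
                self.coef_mel_, self.exp_mel_, self.coef_cone_, self.exp_cone_
            )
        else:
            self.coef_cone_ = float(np.exp(theta[0]))
            self.exp_cone_ = float(np.exp(theta[1]))
            self.params_ = None
        ss_res = 2.0 * best.cost
        ss_tot = float(((y - y.mean()) ** 2).sum())
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        self.n_features_in_ = 2
        return self

    # log-parameterisation keeps every coefficient positive
    def _residuals(self, theta, G, E, y):
        with np.errstate(over="ignore"):
            if self.model == "full":
                a, al, b, be = np.exp(theta)
                pred = a * G**al + b * E**be
            else:
                b, be = np.exp(theta)
                pred = b * E**be
            return np.clip(np.nan_to_num(pred - y, posinf=1e100), -1e100, 1e100)

    def _initial_theta(self, G, E, y, alpha0, beta0):
        # linear pre-fit of the coefficients at fixed trial exponents
        if self.model == "full":
            design = np.column_stack([G**alpha0, E**beta0])
            coef, _ = nnls(design, y)
            coef = np.maximum(coef, 1e-8)
            return np.log(np.array([coef[0], alpha0, coef[1], beta0]))
        design = E[:, None] ** beta0
        coef, _ = nnls(design, y)
        coef = np.maximum(coef, 1e-8)
        return np.log(np.array([coef[0], beta0]))

    def predict(self, X):
        check_is_fitted(self, "r_squared_")
        X = check_array(X)
        G, E = X[:, 0], X[:, 1]
        if self.model == "full":
            return predict_brightness_retinal(G, E, self.params_)
        return self.coef_cone_ * E**self.exp_cone_


def fit_brightness(dataset, model: str = "full", n_starts: int = 5,
                   random_state: int = 0) -> FitResult:
    """Fit the brightness model to (G, E, R) rows.

    ``dataset`` may be an (n, 3) array or a DataFrame with columns
    ``G, E, R`` (optionally a ``stimulus`` column carried into the
    residual table).
    """
    if isinstance(dataset, pd.DataFrame):
        df = dataset.copy()
        arr = df[["G", "E", "R"]].to_numpy(float)
    else:
        arr = np.asarray(dataset, dtype=float)
        df = pd.DataFrame(arr, columns=["G", "E", "R"])
    est = BrightnessModel(model=model, n_starts=n_starts, random_state=random_state)
    est.fit(arr[:, :2], arr[:, 2])
    pred = est.predict(arr[:, :2])
    resid = df.assign(predicted=pred, residual=arr[:, 2] - pred)
    return FitResult(
        params=est.params_,
        coef_cone=est.coef_cone_,
        exp_cone=est.exp_cone_,
        r_squared=est.r_squared_,
        residuals=resid,
        model=model,
    )


def normalized_to_reference(
    params: BrightnessParams,
    reference_ML: tuple,
    pupil_params: PupilParams,
    target: float = 100.0,
) -> BrightnessParams:
    """Rescale (a, b) so the reference condition predicts ``target``.

    Magnitude estimation anchors the rating scale at the reference
    stimulus (rating 100), so coefficient sets are only defined up to this
    common scale; exponents are untouched.
    """
    M_ref, L_ref = reference_ML
    r_ref = predict_brightness_corneal(M_ref, L_ref, pupil_params, params)
    k = target / r_ref
    return BrightnessParams(
        params.coef_mel * k, params.exp_mel, params.coef_cone * k, params.exp_cone
    )
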
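"""Spectral containers, photoreceptor sensitivities and melanopic photometry.

Everything downstream (metamer design, pupil and brightness modelling) is
expressed in terms of two photometric functionals of a spectral power
distribution P(lambda):

* luminance         L = 683 * integral V(lambda)  P(lambda) dlambda   [cd/m^2]
* melanopic
  luminance         M = 4557 * integral i(lambda) P(lambda) dlambda   [melanopic cd/m^2]

where V is the photopic luminous-efficiency function and i the (peak
normalised) melanopsin sensitivity.  Their ratio M/P is a scale-invariant
property of the spectrum: the melanopic stimulus strength per 1 cd/m^2.

Integrals are evaluated with the rectangle rule on a uniform wavelength
grid (default 380-780 nm at 1 nm), which keeps every photometric quantity
exactly linear in the spectrum.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_GRID",
    "PHOTOPIC_SCALE",
    "MELANOPIC_SCALE",
    "SpectrumError",
    "SampledSpectrum",
    "SensitivityCurve",
    "PhotoreceptorBank",
    "nomogram_sensitivity",
    "lens_transmission",
    "lens_corrected",
    "luminance",
    "melanopic_luminance",
    "mp_ratio",
    "receptor_excitations",
    "chromaticity_xy",
    "retinal_quantities",
    "pupil_area_mm2",
    "daylight_spd",
]

#: default wavelength grid, nm
DEFAULT_GRID = np.arange(380.0, 781.0, 1.0)

#: lm/W at the V(lambda) peak — the photopic luminous-efficacy constant
PHOTOPIC_SCALE = 683.0

#: companion scaling for the peak-normalised melanopsin curve, giving
#: "melanopic cd/m^2"; a fixed convention paired with i(lambda) below
MELANOPIC_SCALE = 4557.0


class SpectrumError(ValueError):
    """Raised for malformed spectra or ill-posed photometric requests."""


def _as_grid(wavelengths) -> np.ndarray:
    w = np.asarray(wavelengths, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise SpectrumError("wavelength grid must be a 1-D array with >= 2 points")
    steps = np.diff(w)
    if np.any(steps <= 0):
        raise SpectrumError("wavelength grid must be strictly increasing")
    if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
        raise SpectrumError("wavelength grid must be uniform")
    return w


@dataclass(frozen=True, eq=False)
class SampledSpectrum:
    """A radiometric quantity sampled on a uniform wavelength grid.

    Values are spectral radiance per nm (W sr^-1 m^-2 nm^-1) or any
    quantity proportional to it; all photometric operations are linear,
    so the absolute radiometric calibration only sets the overall scale.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        w = _as_grid(self.wavelengths_nm)
        v = np.asarray(self.values, dtype=float)
        if v.shape != w.shape:
            raise SpectrumError("values and wavelengths must have the same shape")
        if np.any(~np.isfinite(v)):
            raise SpectrumError("spectrum contains non-finite values")
        if np.any(v < 0):
            raise SpectrumError(
                "spectrum contains negative values; use SampledSpectrum.from_values "
                "to clip measurement noise"
            )
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "values", v)

    # -- constructors -------------------------------------------------
    @classmethod
    def from_values(cls, wavelengths_nm, values) -> "SampledSpectrum":
        """Build a spectrum, clipping small negative (noise) values to zero."""
        v = np.asarray(values, dtype=float)
        if np.any(v < 0):
            warnings.warn(
                "negative spectral values clipped to 0 (measurement noise)",
                stacklevel=2,
            )
            v = np.clip(v, 0.0, None)
        return cls(wavelengths_nm, v)

    @classmethod
    def from_csv(cls, path) -> "SampledSpectrum":
        """Read a two-column ``wavelength_nm,value`` CSV."""
        df = pd.read_csv(path, comment="#")
        if not {"wavelength_nm", "value"} <= set(df.columns):
            raise SpectrumError("spectrum CSV needs columns wavelength_nm,value")
        return cls.from_values(df["wavelength_nm"].to_numpy(), df["value"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"wavelength_nm": self.wavelengths_nm, "value": self.values}
        ).to_csv(path, index=False)

    # -- geometry ------------------------------------------------------
    @property
    def step_nm(self) -> float:
        return float(self.wavelengths_nm[1] - self.wavelengths_nm[0])

    def resample(self, grid) -> "SampledSpectrum":
        """Linear interpolation onto a new uniform grid; zero outside support."""
        g = _as_grid(grid)
        v = np.interp(g, self.wavelengths_nm, self.values, left=0.0, right=0.0)
        return SampledSpectrum(g, v)

    # -- linear algebra ------------------------------------------------
    def scaled(self, k: float) -> "SampledSpectrum":
        if k < 0:
            raise SpectrumError("scale factor must be >= 0")
        return SampledSpectrum(self.wavelengths_nm, self.values * k)

    def __add__(self, other: "SampledSpectrum") -> "SampledSpectrum":
        if not np.array_equal(self.wavelengths_nm, other.wavelengths_nm):
            other = other.resample(self.wavelengths_nm)
        return SampledSpectrum(self.wavelengths_nm, self.values + other.values)

    def integral(self) -> float:
        """Rectangle-rule integral over the grid."""
        return float(self.step_nm * self.values.sum())


@dataclass(frozen=True, eq=False)
class SensitivityCurve:
    """A relative spectral sensitivity, peak-normalised to 1."""

    wavelengths_nm: np.ndarray
    values: np.ndarray
    label: str
    provenance: str = "user"

    def __post_init__(self):
        w = _as_grid(self.wavelengths_nm)
        v = np.asarray(self.values, dtype=float)
        if v.shape != w.shape:
            raise SpectrumError("values and wavelengths must have the same shape")
        if np.any(v < 0) or np.any(~np.isfinite(v)):
            raise SpectrumError(f"sensitivity '{self.label}' must be finite and >= 0")
        if abs(v.max() - 1.0) > 1e-9:
            raise SpectrumError(
                f"sensitivity '{self.label}' must be peak-normalised (max == 1); "
                "use SensitivityCurve.normalised"
            )
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "values", v)

    @classmethod
    def normalised(cls, wavelengths_nm, values, label, provenance="user"):
        v = np.asarray(values, dtype=float)
        peak = v.max()
        if peak <= 0:
            raise SpectrumError(f"sensitivity '{label}' has no positive values")
        return cls(wavelengths_nm, v / peak, label, provenance)

    @classmethod
    def from_csv(cls, path, provenance="user") -> "SensitivityCurve":
        label = "unnamed"
        with open(path) as fh:
            text = fh.read()
        for line in text.splitlines():
            if line.startswith("#") and "label:" in line:
                label = line.split("label:", 1)[1].strip()
                break
        df = pd.read_csv(io.StringIO(text), comment="#")
        return cls.normalised(
            df["wavelength_nm"].to_numpy(), df["value"].to_numpy(), label, provenance
        )

    @property
    def step_nm(self) -> float:
        return float(self.wavelengths_nm[1] - self.wavelengths_nm[0])

    def resample(self, grid) -> "SensitivityCurve":
        g = _as_grid(grid)
        v = np.interp(g, self.wavelengths_nm, self.values, left=0.0, right=0.0)
        return SensitivityCurve.normalised(g, v, self.label, self.provenance)

    def peak_wavelength(self) -> float:
        return float(self.wavelengths_nm[int(np.argmax(self.values))])


# ---------------------------------------------------------------------------
# photopigment nomogram
# ---------------------------------------------------------------------------

def nomogram_sensitivity(lambda_max_nm: float, grid=None) -> SensitivityCurve:
    """Vitamin-A1 photopigment absorbance template (alpha band).

    The template is a fixed function of ``x = lambda_max / lambda`` whose
    shape is invariant on a log-wavelength axis, so shifting ``lambda_max``
    translates the curve.  It stands in for tabulated receptor
    sensitivities wherever a measured table is not supplied, keeping the
    whole pipeline self-contained.

    Parameters
    ----------
    lambda_max_nm:
        Peak wavelength of the pigment, 400-600 nm.
    grid:
        Wavelength grid (nm); default 380-780 at 1 nm.
    """
    if not 400.0 <= lambda_max_nm <= 600.0:
        raise SpectrumError("lambda_max must lie in [400, 600] nm")
    g = _as_grid(DEFAULT_GRID if grid is None else grid)
    # alpha-band template constants
    A, B, C, D = 69.7, 28.0, -14.9, 0.674
    b, c = 0.922, 1.104
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max_nm - 300.0) ** 2) / 11940.0)
    x = lambda_max_nm / g
    with np.errstate(over="ignore"):
        s = 1.0 / (
            np.exp(A * (a - x)) + np.exp(B * (b - x)) + np.exp(C * (c - x)) + D
        )
    return SensitivityCurve.normalised(
        g, s, f"nomogram-{lambda_max_nm:g}nm", provenance="nomogram"
    )


# ---------------------------------------------------------------------------
# ocular-media (lens) transmission with age
# ---------------------------------------------------------------------------

def _load_table(name: str) -> pd.DataFrame:
    with resources.files("melabright.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, comment="#")


def lens_transmission(age_years: float, grid=None) -> np.ndarray:
    """Ocular-media transmittance (0-1) at a given age.

    Uses the two-component optical-density model: a portion that grows
    linearly with age plus a stable short-wavelength portion,

        D(lambda) = TL1(lambda) * (1 + 0.02 (age - 32)) + TL2(lambda)

    for ages up to 60, with a steeper slope beyond 60.  The tabulation
    covers 400-650 nm; density is extrapolated linearly below 400 nm
    (clamped >= 0) and is zero above 650 nm.
    """
    if age_years < 10:
        raise SpectrumError("lens model requires age >= 10 years")
    g = _as_grid(DEFAULT_GRID if grid is None else grid)
    tab = _load_table("lens_density.csv")
    w = tab["wavelength_nm"].to_numpy(float)
    if age_years <= 60:
        dens_tab = tab["TL1"].to_numpy() * (1.0 + 0.02 * (age_years - 32.0))
    else:
        dens_tab = tab["TL1"].to_numpy() * (1.56 + 0.0667 * (age_years - 60.0))
    dens_tab = dens_tab + tab["TL2"].to_numpy()
    dens = np.interp(g, w, dens_tab, right=0.0)
    below = g < w[0]
    if np.any(below):
        slope = (dens_tab[1] - dens_tab[0]) / (w[1] - w[0])
        dens[below] = dens_tab[0] + slope * (g[below] - w[0])
    dens = np.clip(dens, 0.0, None)
    return 10.0 ** (-dens)


def lens_corrected(curve: SensitivityCurve, age_years: float) -> SensitivityCurve:
    """Filter a retinal sensitivity through the age-dependent ocular media.

    The product curve is re-peak-normalised, so only the *shape* change
    survives; short wavelengths are attenuated relative to long ones.
    """
    t = lens_transmission(age_years, curve.wavelengths_nm)
    return SensitivityCurve.normalised(
        curve.wavelengths_nm,
        curve.values * t,
        curve.label,
        provenance=f"{curve.provenance}+lens(age={age_years:g})",
    )


# ---------------------------------------------------------------------------
# CIE 1931 colour-matching functions (closed-form fit)
# ---------------------------------------------------------------------------

def _pw_gauss(lam, mu, s1, s2):
    sigma = np.where(lam < mu, s1, s2)
    return np.exp(-0.5 * ((lam - mu) / sigma) ** 2)


def cie1931_cmf(grid=None) -> np.ndarray:
    """Analytic multi-lobe Gaussian fit of the 2-degree colour-matching
    functions; returns a (3, n) array of x-bar, y-bar, z-bar."""
    g = _as_grid(DEFAULT_GRID if grid is None else grid)
    xbar = (
        1.056 * _pw_gauss(g, 599.8, 37.9, 31.0)
        + 0.362 * _pw_gauss(g, 442.0, 16.0, 26.7)
        - 0.065 * _pw_gauss(g, 501.1, 20.4, 26.2)
    )
    ybar = 0.821 * _pw_gauss(g, 568.8, 46.9, 40.5) + 0.286 * _pw_gauss(
        g, 530.9, 16.3, 31.1
    )
    zbar = 1.217 * _pw_gauss(g, 437.0, 11.8, 36.0) + 0.681 * _pw_gauss(
        g, 459.0, 26.0, 13.8
    )
    return np.vstack([xbar, ybar, zbar])


def _project_on_cones(cones: np.ndarray, target: np.ndarray, nonnegative=False) -> np.ndarray:
    """Least-squares projection of a CMF onto the cone-curve span.

    The fit preserves the target's integral (so the equal-energy white
    point of the projected CMF set matches the original), and the
    luminosity row is fit with non-negative coefficients, keeping the
    projected V(lambda) non-negative everywhere.
    """
    s = float(target.sum())
    if nonnegative:
        from scipy.optimize import nnls

        coefs, _ = nnls(cones.T, target)
        total = float(cones.sum(axis=1) @ coefs)
        coefs = coefs * (s / total)
    else:
        # equality-constrained least squares via KKT
        m = cones @ cones.T
        gsum = cones.sum(axis=1)
        kkt = np.block([[2.0 * m, gsum[:, None]], [gsum[None, :], np.zeros((1, 1))]])
        rhs = np.concatenate([2.0 * cones @ target, [s]])
        coefs = np.linalg.solve(kkt, rhs)[:-1]
    return coefs @ cones


# ---------------------------------------------------------------------------
# photoreceptor bank
# ---------------------------------------------------------------------------

#: canonical corneal peak wavelengths (nm) used by the nomogram defaults
RECEPTOR_PEAKS_NM = {
    "L": 566.0,
    "M": 541.0,
    "S": 441.0,
    "rod": 507.0,
    "melanopsin": 480.0,
}

RECEPTOR_NAMES = ("L", "M", "S", "rod", "melanopsin")


@dataclass(frozen=True, eq=False)
class PhotoreceptorBank:
    """All sensitivity curves needed by the pipeline, on one shared grid.

    Receptor curves (L/M/S cones, rod, melanopsin) are peak-normalised;
    the photopic V(lambda) used for luminance is the y-bar colour-matching
    function (peak-normalised), and the raw colour-matching functions are
    kept with their native relative scaling for chromaticity.
    """

    grid: np.ndarray
    curves: dict  # receptor name -> SensitivityCurve
    vlambda: SensitivityCurve
    cmf: np.ndarray  # (3, n): x-bar, y-bar, z-bar
    cmf_provenance: str = "user"

    def __post_init__(self):
        g = _as_grid(self.grid)
        object.__setattr__(self, "grid", g)
        for name in RECEPTOR_NAMES:
            if name not in self.curves:
                raise SpectrumError(f"bank is missing the '{name}' curve")
            if not np.array_equal(self.curves[name].wavelengths_nm, g):
                raise SpectrumError(f"curve '{name}' not on the bank grid")
        if not np.array_equal(self.vlambda.wavelengths_nm, g):
            raise SpectrumError("V(lambda) not on the bank grid")
        if self.cmf.shape != (3, g.size):
            raise SpectrumError("CMF array must be (3, n) on the bank grid")

    @property
    def step_nm(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def curve(self, name: str) -> SensitivityCurve:
        return self.curves[name]

    @classmethod
    def default(
        cls,
        grid=None,
        melanopsin_peak_nm: float = RECEPTOR_PEAKS_NM["melanopsin"],
        lens_age_years: float | None = None,
    ) -> "PhotoreceptorBank":
        """Build the standard bank from the nomogram and cone-based CMFs.

        Colour-matching functions and V(lambda) are obtained by
        least-squares projection of the analytic 1931 CMFs onto the span
        of the bank's own L/M/S cone curves.  This mirrors
        cone-fundamental-based colorimetry — luminance and chromaticity of
        a real observer *are* linear combinations of cone excitations —
        and guarantees that cone-silent metamers are also exactly
        luminance- and chromaticity-silent.

        ``melanopsin_peak_nm`` allows robustness checks with an alternative
        melanopic sensitivity; ``lens_age_years`` optionally pre-filters all
        receptor curves through the ocular media of an observer of that age.
        """
        g = _as_grid(DEFAULT_GRID if grid is None else grid)
        peaks = dict(RECEPTOR_PEAKS_NM, melanopsin=melanopsin_peak_nm)
        curves = {
            name: nomogram_sensitivity(peak, g) for name, peak in peaks.items()
        }
        for name, peak in peaks.items():
            c = curves[name]
            curves[name] = SensitivityCurve(c.wavelengths_nm, c.values, name, c.provenance)
        if lens_age_years is not None:
            curves = {k: lens_corrected(c, lens_age_years) for k, c in curves.items()}
        cones = np.vstack([curves[n].values for n in ("L", "M", "S")])
        target = cie1931_cmf(g)
        cmf = np.vstack(
            [
                _project_on_cones(cones, target[0]),
                _project_on_cones(cones, target[1], nonnegative=True),
                _project_on_cones(cones, target[2]),
            ]
        )
        vl = SensitivityCurve.normalised(
            g, cmf[1], "V", provenance="cone-projected-cie1931"
        )
        return cls(
            grid=g, curves=curves, vlambda=vl, cmf=cmf,
            cmf_provenance="cone-projected-cie1931",
        )


# ---------------------------------------------------------------------------
# photometric functionals
# ---------------------------------------------------------------------------

def _prepare(spd: SampledSpectrum, bank: PhotoreceptorBank) -> SampledSpectrum:
    if not np.array_equal(spd.wavelengths_nm, bank.grid):
        spd = spd.resample(bank.grid)
    return spd


def luminance(spd: SampledSpectrum, bank: PhotoreceptorBank) -> float:
    """Photopic luminance, 683 * integral V(lambda) P(lambda), in cd/m^2."""
    spd = _prepare(spd, bank)
    return PHOTOPIC_SCALE * bank.step_nm * float(bank.vlambda.values @ spd.values)


def melanopic_luminance(spd: SampledSpectrum, bank: PhotoreceptorBank) -> float:
    """Melanopic luminance, 4557 * integral i(lambda) P(lambda)."""
    spd = _prepare(spd, bank)
    i = bank.curves["melanopsin"].values
    return MELANOPIC_SCALE * bank.step_nm * float(i @ spd.values)


def mp_ratio(spd: SampledSpectrum, bank: PhotoreceptorBank) -> float:
    """Melanopic/photopic ratio — melanopic stimulus strength per 1 cd/m^2."""
    lum = luminance(spd, bank)
    if lum <= 0:
        raise SpectrumError("M/P ratio undefined for a spectrum of zero luminance")
    return melanopic_luminance(spd, bank) / lum


def receptor_excitations(
    spd: SampledSpectrum, bank: PhotoreceptorBank, receptors=RECEPTOR_NAMES
) -> dict:
    """Unscaled excitation integrals, one per photoreceptor class."""
    spd = _prepare(spd, bank)
    dl = bank.step_nm
    return {
        name: dl * float(bank.curves[name].values @ spd.values) for name in receptors
    }


def chromaticity_xy(spd: SampledSpectrum, bank: PhotoreceptorBank) -> tuple:
    """CIE 1931 (x, y) chromaticity of the spectrum."""
    spd = _prepare(spd, bank)
    X, Y, Z = bank.step_nm * (bank.cmf @ spd.values)
    total = X + Y + Z
    if total <= 0:
        raise SpectrumError("chromaticity undefined for a zero spectrum")
    return (X / total, Y / total)


def pupil_area_mm2(diameter_mm: float) -> float:
    if diameter_mm <= 0:
        raise SpectrumError("pupil diameter must be positive")
    return np.pi * (diameter_mm / 2.0) ** 2


def retinal_quantities(
    L_cdm2: float, M_melanopic_cdm2: float, pupil_diameter_mm: float
) -> tuple:
    """Convert corneal to retinal stimulus via the pupil area S = pi (d/2)^2.

    Returns ``(E, G)``: retinal illuminance E = L*S in trolands and
    melanopic retinal illuminance G = M*S in melanopic cd/m^2 mm^2.
    """
    if L_cdm2 < 0 or M_melanopic_cdm2 < 0:
        raise SpectrumError("luminances must be >= 0")
    s = pupil_area_mm2(pupil_diameter_mm)
    return (L_cdm2 * s, M_melanopic_cdm2 * s)


# ---------------------------------------------------------------------------
# daylight series
# ---------------------------------------------------------------------------

def daylight_spd(cct_K: float, grid=None) -> SampledSpectrum:
    """Reconstruct a daylight-phase spectrum from its characteristic vectors.

    Valid for correlated colour temperatures 2000-7000 K.  The daylight
    locus polynomial is defined from 4000 K upward; below 4000 K the same
    polynomial is extrapolated so that warm "daylight" phases down to
    2000 K can be compared against artificial sources.  Output is clipped
    at zero and normalised to unit peak.
    """
    if not 2000.0 <= cct_K <= 7000.0:
        raise SpectrumError("daylight CCT must lie in [2000, 7000] K")
    g = _as_grid(DEFAULT_GRID if grid is None else grid)
    T = float(cct_K)
    # daylight-locus chromaticity (4000-7000 K branch, extrapolated below)
    xd = 0.244063 + 0.09911e3 / T + 2.9678e6 / T**2 - 4.6070e9 / T**3
    yd = -3.000 * xd**2 + 2.870 * xd - 0.275
    denom = 0.0241 + 0.2562 * xd - 0.7341 * yd
    m1 = (-1.3515 - 1.7703 * xd + 5.9114 * yd) / denom
    m2 = (0.0300 - 31.4424 * xd + 30.0717 * yd) / denom
    tab = _load_table("daylight_components.csv")
    w = tab["wavelength_nm"].to_numpy(float)
    s = (
        tab["S0"].to_numpy() + m1 * tab["S1"].to_numpy() + m2 * tab["S2"].to_numpy()
    )
    v = np.interp(g, w, s)
    v = np.clip(v, 0.0, None)
    peak = v.max()
    if peak <= 0:
        raise SpectrumError("degenerate daylight reconstruction")
    return SampledSpectrum(g, v / peak)
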
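"""Silent-substitution metamer design on a multi-primary basis.

A *metamer family* is a set of spectra that produce identical excitations
in a chosen group of photoreceptors (here the L/M/S cones, optionally also
the rods) while differing as much as possible in melanopsin excitation.
With >= 4 linearly independent primaries the cone constraints leave free
dimensions along which melanopsin can be modulated; the extreme members of
a family are found by linear programming:

    extremise  m^T w   subject to  A_eq w = b,  0 <= w <= w_max,

where w are the primary drive weights, m the melanopsin excitation row and
A_eq stacks the constrained-receptor excitation rows plus the luminance
row.  Vertex solutions of the LP activate at most (number of constraints)
primaries, which reproduces the classic practice of building cone-silent
stimuli from 4 of 6 primaries and cone-and-rod-silent stimuli from 5 of 6.

Chromaticity targets enter through the tristimulus identities
X = (x/y) Y and Z = ((1-x-y)/y) Y, which keep the program linear.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .spectra import (
    PHOTOPIC_SCALE,
    PhotoreceptorBank,
    SampledSpectrum,
    SpectrumError,
    chromaticity_xy,
    luminance,
    melanopic_luminance,
    mp_ratio,
    receptor_excitations,
)

__all__ = [
    "PROJECTOR_PEAKS_NM",
    "PROJECTOR_FWHM_NM",
    "PrimaryBasis",
    "MetamerSolution",
    "StimulusFamily",
    "MetamerInfeasibleError",
    "gaussian_primary",
    "projector_basis",
    "excitation_matrix",
    "solve_metamer",
    "design_stimulus_family",
    "scale_solution",
]

#: peak wavelengths (nm) of the six projector primaries
PROJECTOR_PEAKS_NM = (610.0, 524.0, 438.0, 659.0, 547.0, 483.0)
#: full widths at half maximum (nm) of the same primaries
PROJECTOR_FWHM_NM = (37.0, 26.0, 15.0, 61.0, 42.0, 37.0)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class MetamerInfeasibleError(RuntimeError):
    """Raised when no primary mixture satisfies the requested constraints."""


def gaussian_primary(peak_nm: float, fwhm_nm: float, grid=None) -> SampledSpectrum:
    """Unit-peak Gaussian emission line; sigma = FWHM / (2 sqrt(2 ln 2))."""
    from .spectra import DEFAULT_GRID, _as_grid

    if fwhm_nm <= 0:
        raise SpectrumError("FWHM must be positive")
    g = _as_grid(DEFAULT_GRID if grid is None else grid)
    if not g[0] <= peak_nm <= g[-1]:
        raise SpectrumError("primary peak lies outside the wavelength grid")
    sigma = fwhm_nm * _FWHM_TO_SIGMA
    return SampledSpectrum(g, np.exp(-0.5 * ((g - peak_nm) / sigma) ** 2))


@dataclass(frozen=True, eq=False)
class PrimaryBasis:
    """An ordered set of primary spectra at unit drive with drive bounds."""

    primaries: tuple
    max_scale: np.ndarray

    def __post_init__(self):
        prims = tuple(self.primaries)
        if len(prims) < 3:
            raise SpectrumError("a primary basis needs at least 3 primaries")
        grid = prims[0].wavelengths_nm
        for p in prims[1:]:
            if not np.array_equal(p.wavelengths_nm, grid):
                raise SpectrumError("all primaries must share one wavelength grid")
        ms = np.asarray(self.max_scale, dtype=float)
        if ms.shape != (len(prims),) or np.any(ms <= 0):
            raise SpectrumError("max_scale must be positive, one entry per primary")
        mat = np.column_stack([p.values for p in prims])
        if np.linalg.matrix_rank(mat) < len(prims):
            raise SpectrumError("primaries are linearly dependent on this grid")
        object.__setattr__(self, "primaries", prims)
        object.__setattr__(self, "max_scale", ms)

    @property
    def grid(self) -> np.ndarray:
        return self.primaries[0].wavelengths_nm

    @property
    def n_primaries(self) -> int:
        return len(self.primaries)

    def matrix(self) -> np.ndarray:
        """(n_wavelengths, n_primaries) matrix of unit-drive spectra."""
        return np.column_stack([p.values for p in self.primaries])

    def mix(self, weights) -> SampledSpectrum:
        w = np.asarray(weights, dtype=float)
        return SampledSpectrum(self.grid, self.matrix() @ w)


def projector_basis(grid=None, radiance_budget: float = 1.0) -> PrimaryBasis:
    """Gaussian model of the six-primary projector used for the stimuli.

    The measured emission curves are available only graphically, so each
    primary is modelled as a unit-peak Gaussian with the published peak
    wavelength and FWHM; measured CSV spectra can be substituted via
    :class:`PrimaryBasis` directly.
    """
    prims = tuple(
        gaussian_primary(p, f, grid)
        for p, f in zip(PROJECTOR_PEAKS_NM, PROJECTOR_FWHM_NM)
    )
    return PrimaryBasis(prims, np.full(len(prims), float(radiance_budget)))


# ---------------------------------------------------------------------------
# excitation rows
# ---------------------------------------------------------------------------

def _row_for(name: str, bank: PhotoreceptorBank) -> np.ndarray:
    """Excitation functional (row over wavelengths) for a named channel."""
    dl = bank.step_nm
    if name in bank.curves:
        return dl * bank.curves[name].values
    if name == "Y":
        return dl * bank.cmf[1]
    if name == "X":
        return dl * bank.cmf[0]
    if name == "Z":
        return dl * bank.cmf[2]
    if name == "V":
        return dl * bank.vlambda.values
    raise SpectrumError(f"unknown receptor/channel '{name}'")


def excitation_matrix(basis: PrimaryBasis, bank: PhotoreceptorBank, receptors) -> np.ndarray:
    """(receptors x primaries) matrix of unit-drive excitations."""
    if not np.array_equal(basis.grid, bank.grid):
        raise SpectrumError("basis and bank must share one wavelength grid")
    rows = np.vstack([_row_for(name, bank) for name in receptors])
    return rows @ basis.matrix()


# ---------------------------------------------------------------------------
# solutions
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class MetamerSolution:
    """One primary mixture with its achieved photometric summary."""

    weights: np.ndarray
    excitations: dict
    xy: tuple
    luminance_cdm2: float
    melanopic_cdm2: float
    mp_ratio: float
    objective: str
    active_primaries: tuple
    label: str | None = None
    spectrum: SampledSpectrum = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "objective": self.objective,
            "weights": list(map(float, self.weights)),
            "active_primaries": list(self.active_primaries),
            "excitations": {k: float(v) for k, v in self.excitations.items()},
            "xy": [float(self.xy[0]), float(self.xy[1])],
            "luminance_cdm2": float(self.luminance_cdm2),
            "melanopic_cdm2": float(self.melanopic_cdm2),
            "mp_ratio": float(self.mp_ratio),
        }


def _summarise(
    basis: PrimaryBasis,
    bank: PhotoreceptorBank,
    weights: np.ndarray,
    objective: str,
    label=None,
) -> MetamerSolution:
    spd = basis.mix(weights)
    active = tuple(
        int(i) for i, w in enumerate(weights) if w > 1e-9 * basis.max_scale[i]
    )
    return MetamerSolution(
        weights=np.asarray(weights, float),
        excitations=receptor_excitations(spd, bank),
        xy=chromaticity_xy(spd, bank),
        luminance_cdm2=luminance(spd, bank),
        melanopic_cdm2=melanopic_luminance(spd, bank),
        mp_ratio=mp_ratio(spd, bank),
        objective=objective,
        active_primaries=active,
        label=label,
        spectrum=spd,
    )


def _polish(A: np.ndarray, b: np.ndarray, w: np.ndarray, ub: np.ndarray) -> np.ndarray:
    """Refine an LP vertex to machine-precision constraint satisfaction.

    Weights at their bounds are frozen and the remaining free weights are
    re-solved by least squares; the refinement is kept only if it stays
    inside the box and does not worsen the residual.
    """
    tol = 1e-9 * np.maximum(ub, 1.0)
    at_lower = w <= tol
    at_upper = w >= ub - tol
    free = ~(at_lower | at_upper)
    if not np.any(free):
        return w
    w_fixed = np.where(at_upper, ub, 0.0)
    rhs = b - A[:, ~free] @ w_fixed[~free]
    sol, *_ = np.linalg.lstsq(A[:, free], rhs, rcond=None)
    w_new = w_fixed.copy()
    w_new[free] = sol
    if np.any(w_new < -1e-12) or np.any(w_new > ub * (1 + 1e-12)):
        return w
    w_new = np.clip(w_new, 0.0, ub)
    if np.abs(A @ w_new - b).max() > np.abs(A @ w - b).max():
        return w
    return w_new


_HIGHS_OPTIONS = {
    "primal_feasibility_tolerance": 1e-10,
    "dual_feasibility_tolerance": 1e-10,
}


def solve_metamer(
    basis: PrimaryBasis,
    bank: PhotoreceptorBank,
    targets: dict,
    objective: str = "max",
    extra_equalities: dict | None = None,
    label=None,
    rtol: float = 1e-8,
) -> MetamerSolution:
    """Extremise melanopsin excitation subject to equality constraints.

    Parameters
    ----------
    targets:
        Mapping channel name -> required excitation value.  Channel names
        are receptor labels (``L``, ``M``, ``S``, ``rod``) or tristimulus
        channels (``X``, ``Y``, ``Z``).
    objective:
        ``"max"`` or ``"min"`` melanopsin excitation.
    extra_equalities:
        Additional equalities (e.g. a melanopsin level when filling in the
        interior of a family); with these the objective becomes a
        deterministic tie-break (minimal total drive).
    """
    if objective not in ("max", "min"):
        raise ValueError("objective must be 'max' or 'min'")
    names = list(targets)
    eqs = dict(targets)
    if extra_equalities:
        names += list(extra_equalities)
        eqs.update(extra_equalities)
    if basis.n_primaries <= len(names):
        raise SpectrumError(
            "need more primaries than equality constraints for a free dimension"
        )
    A = excitation_matrix(basis, bank, names)
    b = np.array([eqs[n] for n in names], dtype=float)
    # row scaling for numerical conditioning
    scale = np.abs(A).max(axis=1)
    scale[scale == 0] = 1.0
    A_s, b_s = A / scale[:, None], b / scale
    mel = excitation_matrix(basis, bank, ["melanopsin"])[0]
    c = -mel if objective == "max" else mel
    if extra_equalities:
        c = np.ones(basis.n_primaries)  # deterministic tie-break: min total drive
    res = linprog(
        c / np.abs(c).max(),
        A_eq=A_s,
        b_eq=b_s,
        bounds=list(zip(np.zeros(basis.n_primaries), basis.max_scale)),
        method="highs",
        options=_HIGHS_OPTIONS,
    )
    if res.status != 0 or res.x is None:
        worst = ""
        if res.status == 2:
            worst = f" (constraints: {', '.join(names)})"
        raise MetamerInfeasibleError(
            f"metamer program infeasible or failed: {res.message}{worst}"
        )
    w = _polish(A, b, np.clip(res.x, 0.0, basis.max_scale), basis.max_scale)
    resid = np.abs(A @ w - b) / np.maximum(np.abs(b), np.abs(A).max(axis=1) * 1e-6)
    if np.any(resid > rtol):
        raise MetamerInfeasibleError(
            f"constraint residual {resid.max():.2e} exceeds tolerance {rtol:.1e}"
        )
    return _summarise(basis, bank, w, objective, label=label)


# ---------------------------------------------------------------------------
# family design
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class StimulusFamily:
    """Metamer families indexed by luminance level.

    ``members[lum]`` lists solutions in decreasing melanopsin excitation;
    all members at one luminance agree in the silenced receptors and in
    luminance, and differ in melanopsin.
    """

    mode: str
    xy_target: tuple
    reference_luminance: float
    members: dict  # luminance -> list[MetamerSolution]

    @property
    def labels(self) -> tuple:
        return tuple(s.label for s in self.members[self.reference_luminance])

    def mp_ratios(self) -> dict:
        return {
            s.label: s.mp_ratio for s in self.members[self.reference_luminance]
        }

    def melanopic_contrast(self) -> float:
        ratios = [s.mp_ratio for s in self.members[self.reference_luminance]]
        return max(ratios) / min(ratios)

    def to_json(self, path=None) -> str:
        payload = {
            "mode": self.mode,
            "xy_target": list(self.xy_target),
            "reference_luminance": self.reference_luminance,
            "members": {
                f"{lum:g}": [s.to_dict() for s in sols]
                for lum, sols in self.members.items()
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


_MODE_CONSTRAINTS = {
    "cone-silent": ("L", "M", "S"),
    "cone-and-rod-silent": ("L", "M", "S", "rod"),
}


def scale_solution(
    solution: MetamerSolution,
    basis: PrimaryBasis,
    bank: PhotoreceptorBank,
    target_luminance: float,
) -> MetamerSolution:
    """Uniformly rescale a solution to a new luminance (M/P is invariant)."""
    k = target_luminance / solution.luminance_cdm2
    w = solution.weights * k
    if np.any(w > basis.max_scale * (1 + 1e-12)):
        raise SpectrumError(
            "scaling to the requested luminance violates primary drive bounds"
        )
    return _summarise(basis, bank, w, solution.objective, label=solution.label)


def _family_endpoints(
    basis: PrimaryBasis,
    bank: PhotoreceptorBank,
    xy_target: tuple,
    luminance_cdm2: float,
    silenced,
    rtol: float = 1e-8,
):
    """Jointly optimise the two extreme members of a metamer family.

    A single LP over the stacked weight vectors (w_hi, w_lo) maximises the
    melanopsin *difference* subject to (a) both mixtures hitting the exact
    tristimulus target (x, y, luminance) and (b) their silenced-receptor
    excitations being equal.  Optimising the pair jointly chooses the
    silenced-excitation operating point with the widest melanopsin range;
    extremising around a fixed pre-chosen point would typically land on a
    gamut vertex where melanopsin cannot move at all.
    """
    n = basis.n_primaries
    x, y = xy_target
    # raw tristimulus target: Y_raw such that 683 * ybar-normalised
    # integral equals the requested luminance
    Y = luminance_cdm2 / PHOTOPIC_SCALE * bank.cmf[1].max()
    t = np.array([(x / y) * Y, Y, ((1 - x - y) / y) * Y])
    A_xyz = excitation_matrix(basis, bank, ["X", "Y", "Z"])
    R = excitation_matrix(basis, bank, silenced)
    mel = excitation_matrix(basis, bank, ["melanopsin"])[0]
    zero = np.zeros_like(A_xyz)
    # w_hi carries the chromaticity/luminance anchor; w_lo is tied to it in
    # the silenced receptors.  Because the bank's CMFs lie in the cone
    # span, matching the cones transfers chromaticity and luminance to
    # every family member exactly; no separate luminance row is needed
    # (it would be linearly dependent and only degrade conditioning).
    A = np.block([[A_xyz, zero], [R, -R]])
    b = np.concatenate([t, np.zeros(len(R))])
    c = np.concatenate([-mel, mel])  # maximise mel_hi - mel_lo
    scale = np.abs(A).max(axis=1)
    res = linprog(
        c / np.abs(c).max(),
        A_eq=A / scale[:, None],
        b_eq=b / scale,
        bounds=list(zip(np.zeros(2 * n), np.tile(basis.max_scale, 2))),
        method="highs",
        options=_HIGHS_OPTIONS,
    )
    if res.status != 0 or res.x is None:
        raise MetamerInfeasibleError(
            f"family design infeasible at luminance {luminance_cdm2:g} cd/m^2, "
            f"chromaticity {xy_target}: {res.message}"
        )
    ub2 = np.tile(basis.max_scale, 2)
    z = _polish(A, b, np.clip(res.x, 0.0, ub2), ub2)
    w_hi, w_lo = z[:n], z[n:]
    if np.any(np.abs(A_xyz @ w_hi - t) / np.abs(t) > rtol):
        raise MetamerInfeasibleError("tristimulus residual above tolerance")
    spread = np.abs(R @ (w_hi - w_lo)) / np.abs(R @ w_hi)
    if np.any(spread > rtol):
        raise MetamerInfeasibleError(
            f"silenced-receptor spread {spread.max():.2e} above tolerance"
        )
    return w_hi, w_lo


def design_stimulus_family(
    basis: PrimaryBasis,
    bank: PhotoreceptorBank,
    xy_target: tuple = (0.328, 0.367),
    luminances=(112.0,),
    mode: str = "cone-silent",
    n_levels: int = 2,
    labels=None,
) -> StimulusFamily:
    """Design a metamer family at a fixed chromaticity across luminances.

    The two extreme members (melanopsin-high / melanopsin-low) are found
    by a joint linear program (see :func:`_family_endpoints`); the family
    is completed with ``n_levels`` members at evenly spaced melanopsin
    levels, taken as convex combinations of the extremes so that every
    member shares the silenced-receptor excitations, the chromaticity and
    the luminance exactly.  Members are ordered by decreasing melanopsin.

    The family is designed once at the highest luminance and scaled down
    to the other levels, mirroring how a projector modulates overall
    drive: uniform scaling preserves the M/P ratio and all excitation
    ratios.
    """
    if mode not in _MODE_CONSTRAINTS:
        raise ValueError(f"mode must be one of {sorted(_MODE_CONSTRAINTS)}")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    lums = sorted(float(v) for v in luminances)
    ref_lum = lums[-1]
    silenced = _MODE_CONSTRAINTS[mode]
    w_hi, w_lo = _family_endpoints(basis, bank, xy_target, ref_lum, silenced)

    thetas = np.linspace(1.0, 0.0, n_levels)
    members = [
        _summarise(
            basis,
            bank,
            th * w_hi + (1.0 - th) * w_lo,
            {1.0: "max", 0.0: "min"}.get(th, "interpolated"),
        )
        for th in thetas
    ]

    if labels is None:
        labels = tuple(chr(ord("A") + i) for i in range(n_levels))
    if len(labels) != n_levels:
        raise ValueError("need exactly one label per melanopsin level")
    for s, lab in zip(members, labels):
        s.label = lab

    by_lum = {ref_lum: members}
    for lum in lums[:-1]:
        by_lum[lum] = [scale_solution(s, basis, bank, lum) for s in members]
    return StimulusFamily(
        mode=mode, xy_target=tuple(xy_target), reference_luminance=ref_lum,
        members=by_lum,
    )
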
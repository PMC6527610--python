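import numpy as np
import pytest

import melabright as mb

STUDY_XY = (0.328, 0.367)
STUDY_LUMINANCES = (22.0, 42.0, 66.0, 102.0, 112.0)


@pytest.fixture(scope="session")
def bank():
    return mb.PhotoreceptorBank.default()


@pytest.fixture(scope="session")
def basis(bank):
    return mb.projector_basis(bank.grid)


@pytest.fixture(scope="session")
def cone_family(basis, bank):
    return mb.design_stimulus_family(
        basis, bank, STUDY_XY, STUDY_LUMINANCES, mode="cone-silent", n_levels=5,
        labels=tuple("CDEFG"),
    )


@pytest.fixture(scope="session")
def rod_family(basis, bank):
    return mb.design_stimulus_family(
        basis, bank, STUDY_XY, STUDY_LUMINANCES, mode="cone-and-rod-silent",
        n_levels=2, labels=("A", "B"),
    )


@pytest.fixture(scope="session")
def manifest_zero_noise():
    return mb.run_all(
        {"seed": 0, "rating_sigma": 0.0, "participant_sigma": 0.0,
         "pupil_sigma_mm": 0.0}
    )


@pytest.fixture(scope="session")
def manifest_noisy():
    return mb.run_all({"seed": 0})


@pytest.fixture
def flat_spectrum(bank):
    return mb.SampledSpectrum(bank.grid, np.ones_like(bank.grid))


def profiled_grid_oracle(X, y, rounds=4, points=13):
    """Independent grid-refinement oracle for the two-power-term fit.

    The model is linear in (a, b) at fixed exponents, so those are
    profiled out in closed form (lstsq) and the grid search runs over the
    2-D exponent space only, refining around the incumbent each round.
    Returns (cost, alpha, beta, (a, b), final_spacing).
    """
    ca, wa = 1.0, 0.5
    cb, wb = 0.6, 0.5
    best = None
    for _ in range(rounds):
        for al in np.linspace(ca - wa, ca + wa, points):
            for be in np.linspace(cb - wb, cb + wb, points):
                design = np.column_stack([X[:, 0] ** al, X[:, 1] ** be])
                coef, *_ = np.linalg.lstsq(design, y, rcond=None)
                r = design @ coef - y
                c = float(r @ r)
                if best is None or c < best[0]:
                    best = (c, al, be, coef)
        ca, cb = best[1], best[2]
        wa, wb = wa / 4.0, wb / 4.0
    spacing = 2.0 * wa * 4.0 / (points - 1)  # spacing of the last round
    return best[0], best[1], best[2], best[3], spacing
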
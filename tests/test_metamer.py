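"""Silent-substitution metamer design: LP solver and family properties."""

import numpy as np
import pytest

import melabright as mb
from melabright.metamer import PROJECTOR_FWHM_NM, PROJECTOR_PEAKS_NM

from conftest import STUDY_LUMINANCES, STUDY_XY


class TestGaussianPrimary:
    def test_unit_peak(self, bank):
        p = mb.gaussian_primary(547.0, 42.0, bank.grid)
        assert p.values.max() == pytest.approx(1.0)
        assert p.wavelengths_nm[np.argmax(p.values)] == 547.0

    def test_half_maximum_at_half_width(self, bank):
        peak, fwhm = 524.0, 26.0
        p = mb.gaussian_primary(peak, fwhm, bank.grid)
        for lam in (peak - fwhm / 2, peak + fwhm / 2):
            v = p.values[np.where(bank.grid == lam)][0]
            assert v == pytest.approx(0.5, abs=1e-6)

    def test_integral_matches_closed_form(self, bank):
        peak, fwhm = 483.0, 37.0
        p = mb.gaussian_primary(peak, fwhm, bank.grid)
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        assert p.integral() == pytest.approx(sigma * np.sqrt(2 * np.pi), rel=5e-3)

    def test_peak_outside_grid_rejected(self, bank):
        with pytest.raises(mb.SpectrumError):
            mb.gaussian_primary(900.0, 10.0, bank.grid)


class TestExcitationMatrix:
    def test_matches_per_primary_excitations(self, basis, bank):
        mat = mb.excitation_matrix(basis, bank, ["L", "M", "S", "rod", "melanopsin"])
        assert np.all(mat >= 0)
        for j, prim in enumerate(basis.primaries):
            exc = mb.receptor_excitations(prim, bank)
            np.testing.assert_allclose(
                mat[:, j],
                [exc["L"], exc["M"], exc["S"], exc["rod"], exc["melanopsin"]],
                rtol=1e-12,
            )

    def test_column_scales_with_primary(self, bank):
        prims = [
            mb.gaussian_primary(p, f, bank.grid)
            for p, f in zip(PROJECTOR_PEAKS_NM[:4], PROJECTOR_FWHM_NM[:4])
        ]
        b1 = mb.PrimaryBasis(tuple(prims), np.ones(4))
        scaled = tuple(prims[:1] + [prims[1].scaled(3.0)] + prims[2:])
        b2 = mb.PrimaryBasis(scaled, np.ones(4))
        m1 = mb.excitation_matrix(b1, bank, ["L", "melanopsin"])
        m2 = mb.excitation_matrix(b2, bank, ["L", "melanopsin"])
        np.testing.assert_allclose(m2[:, 1], 3.0 * m1[:, 1], rtol=1e-12)
        np.testing.assert_allclose(m2[:, 0], m1[:, 0], rtol=1e-12)


def four_primary_basis(bank):
    prims = tuple(
        mb.gaussian_primary(p, f, bank.grid)
        for p, f in zip((610.0, 524.0, 438.0, 483.0), (37.0, 26.0, 15.0, 37.0))
    )
    return mb.PrimaryBasis(prims, np.ones(4))


class TestSolveMetamer:
    def cone_targets(self, basis, bank):
        w0 = np.full(basis.n_primaries, 0.3)
        exc = mb.receptor_excitations(basis.mix(w0), bank)
        return {k: exc[k] for k in ("L", "M", "S")}

    def test_max_at_least_min(self, basis, bank):
        targets = self.cone_targets(basis, bank)
        hi = mb.solve_metamer(basis, bank, targets, objective="max")
        lo = mb.solve_metamer(basis, bank, targets, objective="min")
        assert hi.excitations["melanopsin"] >= lo.excitations["melanopsin"]

    def test_constraints_satisfied_to_tolerance(self, basis, bank):
        targets = self.cone_targets(basis, bank)
        for sense in ("max", "min"):
            sol = mb.solve_metamer(basis, bank, targets, objective=sense)
            for k, v in targets.items():
                assert sol.excitations[k] == pytest.approx(v, rel=1e-8)

    def test_lp_matches_null_space_line_search(self, bank):
        """With 4 primaries and 3 cone constraints, the feasible set is a
        segment; a dense line search along the null-space direction is an
        independent oracle for the LP optimum."""
        basis = four_primary_basis(bank)
        w0 = np.array([0.2, 0.25, 0.15, 0.3])
        A = mb.excitation_matrix(basis, bank, ["L", "M", "S"])
        b = A @ w0
        targets = dict(zip(("L", "M", "S"), b))
        mel = mb.excitation_matrix(basis, bank, ["melanopsin"])[0]

        # oracle: w = w0 + t * n over the feasible t interval
        _, _, vt = np.linalg.svd(A)
        n = vt[-1]
        with np.errstate(divide="ignore"):
            lo_bounds = np.where(n > 0, -w0 / n, (1 - w0) / n)
            hi_bounds = np.where(n > 0, (1 - w0) / n, -w0 / n)
        t_lo, t_hi = np.max(lo_bounds[n != 0]), np.min(hi_bounds[n != 0])
        ts = np.linspace(t_lo, t_hi, 200001)
        mel_vals = mel @ w0 + ts * (mel @ n)
        oracle_max, oracle_min = mel_vals.max(), mel_vals.min()

        hi = mb.solve_metamer(basis, bank, targets, objective="max")
        lo = mb.solve_metamer(basis, bank, targets, objective="min")
        assert hi.excitations["melanopsin"] == pytest.approx(oracle_max, rel=1e-6)
        assert lo.excitations["melanopsin"] == pytest.approx(oracle_min, rel=1e-6)

    def test_infeasible_target_raises(self, basis, bank):
        targets = {"L": 1.0, "M": 1e-9, "S": 1.0}  # unreachable cone combination
        with pytest.raises(mb.MetamerInfeasibleError):
            mb.solve_metamer(basis, bank, targets)

    def test_reproducible(self, basis, bank):
        targets = self.cone_targets(basis, bank)
        a = mb.solve_metamer(basis, bank, targets, objective="max")
        b = mb.solve_metamer(basis, bank, targets, objective="max")
        np.testing.assert_array_equal(a.weights, b.weights)


class TestStimulusFamily:
    def test_two_levels_are_the_extremes(self, basis, bank, cone_family):
        fam2 = mb.design_stimulus_family(
            basis, bank, STUDY_XY, (STUDY_LUMINANCES[-1],), "cone-silent", 2
        )
        ref = cone_family.members[cone_family.reference_luminance]
        pair = fam2.members[fam2.reference_luminance]
        mels5 = [s.excitations["melanopsin"] for s in ref]
        mels2 = [s.excitations["melanopsin"] for s in pair]
        assert mels2[0] == pytest.approx(max(mels5), rel=1e-9)
        assert mels2[1] == pytest.approx(min(mels5), rel=1e-9)

    def test_within_family_cone_agreement(self, cone_family):
        for members in cone_family.members.values():
            for rec in ("L", "M", "S"):
                vals = np.array([s.excitations[rec] for s in members])
                assert np.ptp(vals) / vals.mean() < 1e-8

    def test_within_family_chromaticity_and_luminance(self, cone_family):
        for lum, members in cone_family.members.items():
            xs = np.array([s.xy[0] for s in members])
            ys = np.array([s.xy[1] for s in members])
            assert np.ptp(xs) < 0.002 and np.ptp(ys) < 0.002
            lums = np.array([s.luminance_cdm2 for s in members])
            assert np.ptp(lums) / lums.mean() < 1e-3
            assert lums.mean() == pytest.approx(lum, rel=1e-6)

    def test_chromaticity_hits_target(self, cone_family):
        ref = cone_family.members[cone_family.reference_luminance][0]
        assert ref.xy[0] == pytest.approx(STUDY_XY[0], abs=1e-6)
        assert ref.xy[1] == pytest.approx(STUDY_XY[1], abs=1e-6)

    def test_rod_silencing_also_holds_in_rod_mode(self, rod_family):
        for members in rod_family.members.values():
            vals = np.array([s.excitations["rod"] for s in members])
            assert np.ptp(vals) / vals.mean() < 1e-8

    def test_rod_mode_range_is_subset_of_cone_mode(self, cone_family, rod_family):
        cs = [s.mp_ratio for s in cone_family.members[112.0]]
        rs = [s.mp_ratio for s in rod_family.members[112.0]]
        assert min(rs) >= min(cs) - 1e-9
        assert max(rs) <= max(cs) + 1e-9

    def test_members_sorted_by_melanopsin(self, cone_family):
        mels = [
            s.excitations["melanopsin"]
            for s in cone_family.members[cone_family.reference_luminance]
        ]
        assert np.all(np.diff(mels) < 0)

    def test_gamut_violation_reported(self, basis, bank):
        with pytest.raises(mb.MetamerInfeasibleError):
            mb.design_stimulus_family(
                basis, bank, (0.72, 0.27), (112.0,), "cone-silent", 2
            )


class TestScaling:
    def test_scaling_preserves_mp_ratio(self, basis, bank, cone_family):
        sol = cone_family.members[cone_family.reference_luminance][0]
        scaled = mb.scale_solution(sol, basis, bank, 22.0)
        assert scaled.mp_ratio == pytest.approx(sol.mp_ratio, rel=1e-12)

    def test_luminance_scales_linearly(self, basis, bank, cone_family):
        sol = cone_family.members[cone_family.reference_luminance][0]
        scaled = mb.scale_solution(sol, basis, bank, 56.0)
        assert scaled.luminance_cdm2 == pytest.approx(56.0, rel=1e-9)
        np.testing.assert_allclose(
            scaled.weights, sol.weights * 56.0 / sol.luminance_cdm2, rtol=1e-12
        )

    def test_scaling_beyond_bounds_rejected(self, basis, bank, cone_family):
        sol = cone_family.members[cone_family.reference_luminance][0]
        with pytest.raises(mb.SpectrumError):
            mb.scale_solution(sol, basis, bank, 1e9)
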
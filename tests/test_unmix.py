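import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import nnls

from patquant import (HB_PAIR, PressureSpectrum, Spectrum, cc_estimate,
                      clu_unmix, get_extinction, lu_unmix, so2_from_conc,
                      thb_from_conc)
from patquant.errors import CompensationDomainError
from patquant.unmix import _design_matrix, _mixture_extinction

from conftest import make_synthetic_eigenspectra


def pressure_from(grid, amplitudes):
    return PressureSpectrum(grid, np.asarray(amplitudes, float))


class TestSaturationFormulas:
    @pytest.mark.parametrize("c_ox,c_de,so2,thb", [
        (1.0, 0.0, 100.0, 1.0),
        (1.0, 1.0, 50.0, 2.0),
        (3.0, 1.0, 75.0, 4.0),
    ])
    def test_exact_values(self, c_ox, c_de, so2, thb):
        assert so2_from_conc(c_ox, c_de) == so2
        assert thb_from_conc(c_ox, c_de) == thb

    def test_undefined_and_domain(self):
        assert math.isnan(so2_from_conc(0.0, 0.0))
        with pytest.raises(ValueError):
            so2_from_conc(-1.0, 0.0)
        with pytest.raises(ValueError):
            thb_from_conc(0.0, -1.0)


class TestLinearUnmixing:
    def test_exact_single_species(self, table, phantom_grid):
        eox = get_extinction("HbO2", phantom_grid, table).amplitudes
        r = lu_unmix(pressure_from(phantom_grid, 2.0 * eox), table, HB_PAIR)
        assert r.c_ox == pytest.approx(2.0, abs=1e-9)
        assert r.c_de == pytest.approx(0.0, abs=1e-9)
        assert r.so2_pct == pytest.approx(100.0, abs=1e-9)

    def test_symmetric_mixture(self, table, phantom_grid):
        e = _design_matrix(phantom_grid, table, HB_PAIR)
        r = lu_unmix(pressure_from(phantom_grid, e[:, 0] + e[:, 1]), table)
        assert r.so2_pct == pytest.approx(50.0, abs=1e-9)
        assert r.thb_rel == pytest.approx(2.0, abs=1e-9)

    def test_all_zero_is_flagged_not_raised(self, table, phantom_grid):
        r = lu_unmix(pressure_from(phantom_grid, np.zeros(11)), table)
        assert not r.so2_defined
        assert (r.c_ox, r.c_de, r.thb_rel) == (0.0, 0.0, 0.0)

    def test_spectral_coloring_underestimates(self, table, phantom_grid):
        """A fluence decreasing with wavelength biases LU's saturation low;
        the NNLS solution is cross-checked against the unconstrained
        least-squares oracle when that oracle is feasible."""
        e = _design_matrix(phantom_grid, table, HB_PAIR)
        phi = np.exp(-0.002 * (phantom_grid.values - 730.0))
        p = phi * (0.8 * e[:, 0] + 0.2 * e[:, 1])
        r = lu_unmix(pressure_from(phantom_grid, p), table)
        oracle, _, _, _ = np.linalg.lstsq(e, p, rcond=None)
        if np.all(oracle >= 0):
            np.testing.assert_allclose([r.c_ox, r.c_de], oracle, rtol=1e-8)
        assert r.so2_pct < 80.0

    @pytest.mark.parametrize("truth", [50.0, 60.0, 70.0, 80.0, 90.0, 100.0])
    def test_monotone_bias_for_decreasing_fluence(self, table, phantom_grid, truth):
        e = _design_matrix(phantom_grid, table, HB_PAIR)
        phi = np.exp(-0.0015 * (phantom_grid.values - 730.0))
        p = phi * _mixture_extinction(e, truth)
        r = lu_unmix(pressure_from(phantom_grid, p), table)
        assert r.so2_pct <= truth + 1e-9

    @settings(deadline=None, derandomize=True)
    @given(scale=st.floats(1e-4, 1e4), truth=st.floats(5, 95))
    def test_scale_invariance(self, table, phantom_grid, scale, truth):
        """Gamma and laser energy are unknown positive scales: so2 must not
        depend on them."""
        e = _design_matrix(phantom_grid, table, HB_PAIR)
        p = _mixture_extinction(e, truth)
        base = lu_unmix(pressure_from(phantom_grid, p), table)
        scaled = lu_unmix(pressure_from(phantom_grid, scale * p), table)
        assert scaled.so2_pct == pytest.approx(base.so2_pct, abs=1e-6)


class TestCompensatedLinearUnmixing:
    def test_identity_compensation_equals_lu_bitwise(self, table, phantom_grid):
        rng = np.random.default_rng(4)
        p = pressure_from(phantom_grid, rng.uniform(0.1, 2.0, 11))
        ones = Spectrum(phantom_grid, np.ones(11))
        a, b = clu_unmix(p, ones, table), lu_unmix(p, table)
        assert (a.c_ox, a.c_de, a.so2_pct, a.thb_rel) == \
            (b.c_ox, b.c_de, b.so2_pct, b.thb_rel)

    def test_exact_model_match(self, table, phantom_grid, synthetic_eig):
        e = _design_matrix(phantom_grid, table, HB_PAIR)
        phi = synthetic_eig.phi_ave
        p = pressure_from(phantom_grid, phi.amplitudes * _mixture_extinction(e, 60.0))
        r = clu_unmix(p, phi, table)
        assert r.so2_pct == pytest.approx(60.0, abs=1e-9)

    def test_nonpositive_compensator_rejected(self, table, phantom_grid):
        p = pressure_from(phantom_grid, np.ones(11))
        bad = Spectrum(phantom_grid, np.linspace(1.0, -0.1, 11))
        with pytest.raises(CompensationDomainError):
            clu_unmix(p, bad, table)

    def test_phi_ave_beats_lu_on_average_over_members(self, table, phantom_grid,
                                                      synthetic_eig):
        """Exhaustive evaluation over member fluences: compensating with the
        ensemble mean reduces the mean absolute saturation error vs LU."""
        e = _design_matrix(phantom_grid, table, HB_PAIR)
        truth = 80.0
        err_lu, err_clu = [], []
        for member in synthetic_eig.spectra:
            p = pressure_from(phantom_grid,
                              member.amplitudes * _mixture_extinction(e, truth))
            err_lu.append(abs(lu_unmix(p, table).so2_pct - truth))
            err_clu.append(abs(clu_unmix(p, synthetic_eig.phi_ave, table).so2_pct
                               - truth))
        assert np.mean(err_clu) < np.mean(err_lu)


def independent_cc_oracle(p, eig, table, pair, so2_grid):
    """Exhaustive-search reimplementation with an explicitly different angle
    formula (arctan of orthogonal/parallel split)."""
    e = _design_matrix(p.grid, table, pair)
    phis = np.column_stack([s.amplitudes for s in eig.spectra])
    best = (np.inf, None)
    for s in so2_grid:
        gens = phis * _mixture_extinction(e, s)[:, None]
        coef, _ = nnls(gens, p.amplitudes)
        proj = gens @ coef
        npj = np.linalg.norm(proj)
        if npj == 0:
            ang = np.pi / 2
        else:
            u = proj / npj
            par = float(p.amplitudes @ u)
            orth = float(np.linalg.norm(p.amplitudes - par * u))
            ang = math.atan2(orth, par)
        if ang < best[0] - 1e-15:
            best = (ang, s)
    return best[1], best[0]


class TestConvexCone:
    def test_member_spectrum_recovered_exactly(self, table, phantom_grid,
                                               synthetic_eig):
        e = _design_matrix(phantom_grid, table, HB_PAIR)
        p = pressure_from(phantom_grid,
                          synthetic_eig.spectra[0].amplitudes *
                          _mixture_extinction(e, 80.0))
        r = cc_estimate(p, synthetic_eig, table)
        assert r.so2_pct == pytest.approx(80.0, abs=1e-9)
        assert r.residual < 1e-9

    def test_interior_cone_point(self, table, phantom_grid, synthetic_eig):
        e = _design_matrix(phantom_grid, table, HB_PAIR)
        mix = 0.5 * synthetic_eig.spectra[0].amplitudes + \
            0.5 * synthetic_eig.spectra[1].amplitudes
        p = pressure_from(phantom_grid, mix * _mixture_extinction(e, 40.0))
        r = cc_estimate(p, synthetic_eig, table)
        assert r.so2_pct == pytest.approx(40.0, abs=0.5)
        assert r.residual < 1e-6

    def test_zero_spectrum_flagged(self, table, phantom_grid, synthetic_eig):
        r = cc_estimate(pressure_from(phantom_grid, np.zeros(11)),
                        synthetic_eig, table)
        assert not r.so2_defined

    def test_matches_independent_oracle(self, table, phantom_grid):
        """100 random in-cone instances, 1% grid: winning candidate agrees
        with the exhaustive-search oracle."""
        eig = make_synthetic_eigenspectra(
            phantom_grid, slopes=(-0.002, -0.0005, 0.0008, 0.0015))
        e = _design_matrix(phantom_grid, table, HB_PAIR)
        members = np.stack([s.amplitudes for s in eig.spectra])
        so2_grid = np.arange(0.0, 100.5, 1.0)
        rng = np.random.default_rng(9)
        for _ in range(100):
            truth = float(rng.uniform(2, 98))
            alpha = rng.dirichlet(np.ones(4))
            p = pressure_from(phantom_grid,
                              (alpha @ members) * _mixture_extinction(e, truth))
            mine = cc_estimate(p, eig, table, so2_grid=so2_grid)
            oracle_s, oracle_ang = independent_cc_oracle(p, eig, table,
                                                         HB_PAIR, so2_grid)
            assert mine.so2_pct == pytest.approx(oracle_s, abs=1e-9)
            assert mine.residual == pytest.approx(oracle_ang, abs=1e-9)

    @pytest.mark.parametrize("scale", [1e-3, 0.37, 42.0, 1e3])
    def test_scale_invariance(self, table, phantom_grid, synthetic_eig, scale):
        e = _design_matrix(phantom_grid, table, HB_PAIR)
        p0 = synthetic_eig.spectra[1].amplitudes * _mixture_extinction(e, 30.0)
        a = cc_estimate(pressure_from(phantom_grid, p0), synthetic_eig, table)
        b = cc_estimate(pressure_from(phantom_grid, scale * p0),
                        synthetic_eig, table)
        assert a.so2_pct == b.so2_pct


class TestPressureSpectrumContract:
    def test_minimum_three_wavelengths(self):
        from patquant import WavelengthGrid
        g = WavelengthGrid(np.array([750.0, 800.0]))
        with pytest.raises(ValueError, match="3 wavelengths"):
            PressureSpectrum(g, np.array([1.0, 2.0]))
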
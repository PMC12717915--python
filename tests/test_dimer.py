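import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyespec.dimer import (DimerizationModel, composite_spectrum,
                           concentration_series_spectra,
                           dimer_shift_sensitivity, fit_dimerization,
                           speciate)
from dyespec.spectra import Spectrum
from dyespec.synthetic import dilution_concentrations, GeneratorConfig

from .oracles import speciate_root


class TestSpeciate:
    def test_no_dimerization_limit(self):
        sp = speciate(0.0, 4.0e-4)
        assert sp.monomer_conc == 4.0e-4
        assert sp.dimer_conc == 0.0

    def test_reference_point(self):
        """K_D = 1000 1/M, C_i = 5e-4 M has the closed-form monomer
        concentration (−1+√5)/4000."""
        sp = speciate(1000.0, 5.0e-4)
        assert sp.monomer_conc == pytest.approx((-1 + math.sqrt(5)) / 4000,
                                                rel=1e-12)
        assert sp.dimer_conc == pytest.approx(9.549150281e-5, rel=1e-8)
        # defining relation K_D = [D]/[M]^2
        assert sp.dimer_conc / sp.monomer_conc ** 2 == pytest.approx(1000.0,
                                                                     rel=1e-10)

    def test_strong_dimerization_asymptote(self):
        k_d, c_i = 1.0e9, 1.0e-2
        sp = speciate(k_d, c_i)
        assert sp.monomer_conc == pytest.approx(math.sqrt(c_i / (2 * k_d)),
                                                rel=1e-3)

    @given(st.floats(min_value=-3, max_value=3),
           st.floats(min_value=-7, max_value=-1))
    @settings(deadline=None, derandomize=True, max_examples=80)
    def test_mass_conservation_over_decades(self, log_kd, log_ci):
        """[M] + 2[D] = C_i to 1e-12 relative across 6 decades of both
        K_D and C_i."""
        k_d, c_i = 10.0 ** log_kd, 10.0 ** log_ci
        sp = speciate(k_d, c_i)
        assert sp.total == pytest.approx(c_i, rel=1e-12)
        assert sp.monomer_conc >= 0 and sp.dimer_conc >= 0

    @given(st.floats(min_value=-4, max_value=6),
           st.floats(min_value=-8, max_value=-1))
    @settings(deadline=None, derandomize=True, max_examples=80)
    def test_agrees_with_root_finder(self, log_kd, log_ci):
        k_d, c_i = 10.0 ** log_kd, 10.0 ** log_ci
        sp = speciate(k_d, c_i)
        m_ref, _ = speciate_root(k_d, c_i)
        assert sp.monomer_conc == pytest.approx(m_ref, rel=1e-10)

    def test_continuity_at_series_switch(self):
        c_i = 1.0e-4
        for x in (0.9e-8, 1.1e-8):
            k_d = x / c_i
            lo = speciate(k_d * 0.999999, c_i).monomer_conc
            hi = speciate(k_d * 1.000001, c_i).monomer_conc
            assert lo == pytest.approx(hi, rel=1e-10)

    def test_monomer_fraction_monotone(self):
        fracs_kd = [speciate(k, 1e-4).monomer_conc / 1e-4
                    for k in (1e1, 1e2, 1e3, 1e4, 1e5)]
        assert all(a > b for a, b in zip(fracs_kd, fracs_kd[1:]))
        fracs_ci = [speciate(1e3, c).monomer_conc / c
                    for c in (1e-6, 1e-5, 1e-4, 1e-3)]
        assert all(a > b for a, b in zip(fracs_ci, fracs_ci[1:]))

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            speciate(-1.0, 1e-4)
        with pytest.raises(ValueError):
            speciate(1.0, 0.0)


def _rect(grid, lo, hi):
    vals = ((grid >= lo) & (grid <= hi)).astype(float)
    return Spectrum(grid, vals)


class TestCompositeSpectrum:
    def test_monomer_only_limit(self, monomer_basis, dimer_bases):
        model = DimerizationModel(k_d=0.0, c_i=5e-4, eps_m=2.0, eps_d=3.0)
        out = composite_spectrum(model, monomer_basis, *dimer_bases)
        assert np.allclose(out.values, 2.0 * 5e-4 * monomer_basis.values)

    def test_zero_dimer_bands(self, monomer_basis, grid):
        zero = Spectrum(grid, np.zeros_like(grid))
        model = DimerizationModel(k_d=2e3, c_i=5e-4, eps_m=1.5, eps_d=9.9)
        out = composite_spectrum(model, monomer_basis, zero, zero)
        sp = speciate(2e3, 5e-4)
        assert np.allclose(out.values,
                           1.5 * sp.monomer_conc * monomer_basis.values)

    def test_rectangular_basis_hand_evaluation(self, grid):
        """With unit-height rectangular bases and unit epsilons the output
        values equal the concentration factors of the superposition."""
        a_m = _rect(grid, 1.75, 1.85)
        a_da = _rect(grid, 2.00, 2.10)
        a_db = _rect(grid, 2.30, 2.40)
        model = DimerizationModel(k_d=1000.0, c_i=5e-4)
        out = composite_spectrum(model, a_m, a_da, a_db)
        sp = speciate(1000.0, 5e-4)
        i_m = np.searchsorted(grid, 1.80)
        i_da = np.searchsorted(grid, 2.05)
        i_db = np.searchsorted(grid, 2.35)
        assert out.values[i_m] == pytest.approx(sp.monomer_conc, rel=1e-12)
        assert out.values[i_da] == pytest.approx(sp.dimer_conc, rel=1e-12)
        assert out.values[i_db] == pytest.approx(sp.dimer_conc, rel=1e-12)

    def test_split_conformers_halves_dimer_terms(self, grid):
        a_m = _rect(grid, 1.75, 1.85)
        a_da = _rect(grid, 2.00, 2.10)
        a_db = _rect(grid, 2.30, 2.40)
        model = DimerizationModel(k_d=1000.0, c_i=5e-4)
        full = composite_spectrum(model, a_m, a_da, a_db)
        half = composite_spectrum(model, a_m, a_da, a_db,
                                  split_conformers=True)
        i_da = np.searchsorted(grid, 2.05)
        assert half.values[i_da] == pytest.approx(full.values[i_da] / 2)

    def test_linearity_in_basis(self, monomer_basis, dimer_bases):
        model = DimerizationModel(k_d=2e3, c_i=3e-4, eps_m=1.0, eps_d=1.0)
        a_da, a_db = dimer_bases
        out1 = composite_spectrum(model, monomer_basis, a_da, a_db)
        doubled = monomer_basis.with_values(2.0 * monomer_basis.values)
        out2 = composite_spectrum(model, doubled, a_da, a_db)
        sp = speciate(2e3, 3e-4)
        extra = sp.monomer_conc * monomer_basis.values
        assert np.allclose(out2.values, out1.values + extra)

    def test_grid_mismatch_rejected(self, monomer_basis, dimer_bases):
        a_da, _ = dimer_bases
        coarse = Spectrum(np.linspace(1.7, 2.6, 50), np.zeros(50))
        model = DimerizationModel(k_d=1e3, c_i=1e-4)
        with pytest.raises(ValueError, match="grid"):
            composite_spectrum(model, monomer_basis, a_da, coarse)


class TestDimerShift:
    def test_rigid_shift_moves_band_max(self, dimer_bases):
        a_da, a_db = dimer_bases
        sh_a, sh_b = dimer_shift_sensitivity(a_da, a_db, 0.02)
        for orig, shifted in ((a_da, sh_a), (a_db, sh_b)):
            m0 = orig.energies[np.argmax(orig.values)]
            m1 = shifted.energies[np.argmax(shifted.values)]
            assert m1 == pytest.approx(m0 - 0.02, abs=1e-12)

    def test_round_trip_identity(self, dimer_bases):
        a_da, a_db = dimer_bases
        sh_a, sh_b = dimer_shift_sensitivity(a_da, a_db, 0.02)
        back_a, back_b = dimer_shift_sensitivity(sh_a, sh_b, -0.02)
        assert np.allclose(back_a.energies, a_da.energies, atol=1e-15)
        assert np.allclose(back_b.energies, a_db.energies, atol=1e-15)

    def test_guard(self, dimer_bases):
        with pytest.raises(ValueError):
            dimer_shift_sensitivity(*dimer_bases, 0.2)
        dimer_shift_sensitivity(*dimer_bases, 0.2, force=True)


class TestConcentrationSeries:
    def test_dimer_share_increases_with_concentration(self, monomer_basis,
                                                      dimer_bases):
        concs = dilution_concentrations(GeneratorConfig())
        specs = concentration_series_spectra(2e3, 1.0, 1.0, concs,
                                             monomer_basis, *dimer_bases)
        grid = monomer_basis.energies
        dimer_window = (grid >= 2.21) & (grid <= 2.30)
        shares = []
        for s in specs:
            total = s.area()
            dimer_part = np.trapezoid(s.values[dimer_window],
                                      grid[dimer_window])
            shares.append(dimer_part / total)
        # concentrations decrease along the ladder, so the dimer share must too
        assert all(a > b for a, b in zip(shares, shares[1:]))

    def test_equal_concentrations_identical(self, monomer_basis, dimer_bases):
        specs = concentration_series_spectra(2e3, 1.0, 1.0, [1e-4, 1e-4],
                                             monomer_basis, *dimer_bases)
        assert np.array_equal(specs[0].values, specs[1].values)


class TestFitDimerization:
    def test_noiseless_roundtrip(self, monomer_basis, dimer_bases):
        """A noiseless series generated with known parameters is recovered
        to solver tolerance."""
        k_d, eps_m, eps_d = 2.0e3, 5.0e4, 3.0e4
        concs = dilution_concentrations(GeneratorConfig())
        specs = concentration_series_spectra(k_d, eps_m, eps_d, concs,
                                             monomer_basis, *dimer_bases)
        fit = fit_dimerization(list(zip(concs, specs)), monomer_basis,
                               *dimer_bases)
        assert fit.converged
        assert fit.k_d == pytest.approx(k_d, rel=1e-6)
        assert fit.eps_m == pytest.approx(eps_m, rel=1e-6)
        assert fit.eps_d == pytest.approx(eps_d, rel=1e-6)

    def test_null_recovery_without_dimerization(self, monomer_basis,
                                                dimer_bases):
        """Data generated with K_D = 0 must not yield a fitted dimer
        contribution above the noise floor."""
        concs = dilution_concentrations(GeneratorConfig())
        specs = concentration_series_spectra(0.0, 5.0e4, 3.0e4, concs,
                                             monomer_basis, *dimer_bases)
        rng = np.random.default_rng(7)
        noisy = [s.with_values(s.values *
                               (1 + 0.01 * rng.standard_normal(s.values.size)))
                 for s in specs]
        fit = fit_dimerization(list(zip(concs, noisy)), monomer_basis,
                               *dimer_bases)
        # dimer absorbance share implied by the fit stays below 1% of total
        sp = speciate(fit.k_d, float(concs[0]))
        dimer_signal = abs(fit.eps_d) * sp.dimer_conc
        monomer_signal = fit.eps_m * sp.monomer_conc
        assert dimer_signal < 0.01 * monomer_signal

    def test_too_few_concentrations_rejected(self, monomer_basis,
                                             dimer_bases):
        concs = [1e-4, 2e-4]
        specs = concentration_series_spectra(1e3, 1.0, 1.0, concs,
                                             monomer_basis, *dimer_bases)
        with pytest.raises(ValueError):
            fit_dimerization(list(zip(concs, specs)), monomer_basis,
                             *dimer_bases)
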
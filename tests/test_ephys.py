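"""Reversal potentials, LJP correction, permeability ratios, Hill pH50 fits."""

import numpy as np
import pytest

from asorpipe.biophysics import thermal_voltage_mv
from asorpipe.ephys import (
    HillPHActivation,
    IVCurve,
    correct_ljp,
    current_density,
    current_ratio,
    extract_erev,
    fit_ph_activation,
    ghk_reversal,
    nernst_potential,
    nernst_potential_ph,
    percent_inhibition,
    permeability_ratio_biionic,
)
from asorpipe.errors import DivalentIonError, InsufficientDataError, NoRootError
from asorpipe.solutions import SolutionSpec


def solution(name, ph=5.0, **comp):
    return SolutionSpec(name, comp, ph=ph)


class TestNernst:
    def test_proton_gradient_reproduces_113_mv(self):
        e = nernst_potential_ph(ph_out=5.25, ph_in=7.2, temperature_c=20.0)
        assert round(e) == 113

    def test_equilibrium_is_zero(self):
        assert nernst_potential(-1, 150.0, 150.0) == 0.0

    def test_tenfold_anion_gradient(self):
        e = nernst_potential(-1, 150.0, 15.0, temperature_c=20.0)
        assert e == pytest.approx(-thermal_voltage_mv(20.0) * np.log(10.0), rel=1e-12)
        assert e == pytest.approx(-58.2, abs=0.05)

    def test_positive_activity_required(self):
        from asorpipe.errors import SolutionError

        with pytest.raises(SolutionError):
            nernst_potential(-1, 0.0, 150.0)


class TestGhkReversal:
    def test_symmetric_single_anion_reverses_at_zero(self):
        pip = solution("p", Cl=150)
        bath = solution("b", Cl=150)
        assert ghk_reversal({"Cl": 1.0}, pip, bath) == pytest.approx(0.0, abs=1e-9)

    def test_single_ion_reduces_to_nernst(self):
        pip = solution("p", Cl=160)
        bath = solution("b", Cl=156)
        e = ghk_reversal({"Cl": 1.0}, pip, bath)
        assert e == pytest.approx(nernst_potential(-1, 156, 160), abs=1e-9)

    def test_single_ion_matches_nernst_over_random_draws(self, rng):
        for _ in range(50):
            ion, z = ("Cl", -1) if rng.random() < 0.5 else ("Na", 1)
            ci, co = rng.uniform(1, 300, size=2)
            t = rng.uniform(10, 37)
            pip = solution("p", **{ion: ci})
            bath = solution("b", **{ion: co})
            assert ghk_reversal({ion: 1.0}, pip, bath, temperature_c=t) == pytest.approx(
                nernst_potential(z, co, ci, temperature_c=t), abs=1e-9
            )

    def test_biionic_closed_form(self):
        pip = solution("p", Cl=150, Cs=150)
        bath = solution("b", I=150, Na=150)
        e = ghk_reversal({"Cl": 1.0, "I": 2.0}, pip, bath)
        assert e == pytest.approx(-thermal_voltage_mv(20.0) * np.log(2.0), abs=1e-6)

    def test_no_root_on_bracket_raises(self):
        pip = solution("p", Cl=150)
        bath = solution("b", Na=150)
        # only permeant species is intracellular: current always outward
        with pytest.raises(NoRootError):
            ghk_reversal({"Cl": 1.0}, pip, bath)


class TestExtractErev:
    def test_ohmic_curve_exact_crossing(self):
        v = np.linspace(-80, 80, 321)
        est = extract_erev(IVCurve(v, 2.5 * (v - 10.0)))
        assert est.crossing_found
        assert est.erev_mv == pytest.approx(10.0, abs=1e-9)

    def test_no_crossing_flagged(self):
        v = np.linspace(-80, 80, 321)
        est = extract_erev(IVCurve(v, np.full_like(v, 5.0)))
        assert not est.crossing_found
        assert np.isnan(est.erev_mv)

    def test_background_subtraction_shifts_crossing(self):
        v = np.linspace(-80, 80, 321)
        total = 2.0 * (v - 10.0) + 0.5 * (v + 30.0)
        bg = IVCurve(v, 0.5 * (v + 30.0))
        est = extract_erev(IVCurve(v, total), background=bg)
        assert est.erev_mv == pytest.approx(10.0, abs=1e-9)

    def test_multiple_crossings_prefer_nearest_reference(self):
        v = np.linspace(-80, 80, 1601)
        i = (v - 50.0) * (v + 50.0) * v / 1e3  # crossings at -50, 0, +50
        est = extract_erev(IVCurve(v, i), smooth_pts=None)
        assert est.erev_mv == pytest.approx(0.0, abs=1e-9)
        est = extract_erev(IVCurve(v, i), smooth_pts=None, previous_mv=45.0)
        assert est.erev_mv == pytest.approx(50.0, abs=1e-9)

    def test_noise_free_ghk_ramp_matches_root_oracle(self, rng):
        from asorpipe.synth import ChannelModel, simulate_iv_recording

        pip = solution("p", ph=7.2, Cs=150, Cl=160)
        for _ in range(10):
            perms = {"Cl": 1.0, "I": rng.uniform(0.1, 10.0)}
            bath = solution("b", ph=4.8, Na=300, I=rng.uniform(30, 200),
                            Cl=rng.uniform(5, 100))
            sweep = simulate_iv_recording(ChannelModel(permeabilities=perms),
                                          pip, bath, protocol="ramp")
            est = extract_erev(IVCurve.from_ramp_sweep(sweep))
            assert est.erev_mv == pytest.approx(
                ghk_reversal(perms, pip, bath), abs=0.1
            )


class TestLjp:
    def test_stated_convention(self):
        assert correct_ljp(10.0, 4.5) == pytest.approx(5.5)

    def test_zero_ljp_is_identity(self):
        assert correct_ljp(-23.4, 0.0) == -23.4

    def test_per_solution_ljps_adjust_delta_erev(self):
        # Erev difference between iodide (LJP 4.3) and chloride (LJP 4.5)
        # baths: corrected difference = raw difference + 0.2 mV
        raw_i, raw_cl = -20.0, -2.0
        delta = correct_ljp(raw_i, 4.3) - correct_ljp(raw_cl, 4.5)
        assert delta == pytest.approx((raw_i - raw_cl) + 0.2)

    def test_estimate_correct_method(self):
        v = np.linspace(-80, 80, 321)
        est = extract_erev(IVCurve(v, v - 10.0)).correct(4.5)
        assert est.erev_corrected_mv == pytest.approx(10.0 - 4.5, abs=1e-9)


class TestPermeabilityRatio:
    def test_no_shift_equal_concentrations_is_unity(self):
        assert permeability_ratio_biionic(0.0, 150.0, 150.0) == pytest.approx(1.0)

    def test_ln2_shift_gives_ratio_two(self):
        d = -thermal_voltage_mv(20.0) * np.log(2.0)
        assert permeability_ratio_biionic(d, 150.0, 150.0) == pytest.approx(2.0, rel=1e-12)

    def test_round_trip_through_ghk(self):
        pip = solution("p", ph=7.2, NMDG=140, Cl=150)
        bath_cl = solution("cl", ph=5.25, Na=150, Cl=150)
        bath_i = solution("i", ph=5.25, Na=150, I=150)
        for ratio in (0.1, 0.37, 1.0, 3.7, 10.0):
            perms = {"Cl": 1.0, "I": ratio}
            delta = ghk_reversal(perms, pip, bath_i) - ghk_reversal(perms, pip, bath_cl)
            rec = permeability_ratio_biionic(delta, 150.0, 150.0)
            assert rec == pytest.approx(ratio, rel=1e-6)

    def test_delta_erev_antisymmetric_under_swap(self):
        pip = solution("p", ph=7.2, NMDG=140, Cl=150)
        bath_cl = solution("cl", ph=5.25, Na=150, Cl=150)
        bath_i = solution("i", ph=5.25, Na=150, I=150)
        perms = {"Cl": 1.0, "I": 2.3}
        e_i = correct_ljp(ghk_reversal(perms, pip, bath_i), 4.3)
        e_cl = correct_ljp(ghk_reversal(perms, pip, bath_cl), 4.5)
        assert (e_i - e_cl) == pytest.approx(-(e_cl - e_i), rel=1e-12)

    def test_divalent_directed_to_delta_erev(self):
        with pytest.raises(DivalentIonError):
            permeability_ratio_biionic(-30.0, 100.0, 150.0, valence=-2)


def hill_currents(ph, ph50=5.3, n_h=3.0, i_max=1200.0):
    return i_max / (1 + 10 ** (n_h * (np.asarray(ph, float) - ph50)))


PH_GRID = np.array([7.4, 6.0, 5.8, 5.5, 5.25, 5.0, 4.8, 4.6])


class TestHillFit:
    def test_noise_free_recovery_exact(self):
        fit = fit_ph_activation(PH_GRID, hill_currents(PH_GRID))
        assert fit.converged
        assert fit.ph50 == pytest.approx(5.3, abs=1e-6)
        assert fit.n_h == pytest.approx(3.0, abs=1e-6)
        assert fit.i_max == pytest.approx(1200.0, rel=1e-6)

    def test_half_maximum_identity_at_fitted_ph50(self):
        fit = fit_ph_activation(PH_GRID, hill_currents(PH_GRID, ph50=5.1, n_h=2.0))
        assert fit.predict(fit.ph50) == pytest.approx(fit.i_max / 2, rel=1e-9)

    def test_flat_currents_flagged_nonconverged(self):
        fit = fit_ph_activation(PH_GRID, np.full(PH_GRID.size, 500.0))
        assert not fit.converged

    def test_insufficient_data_raises(self):
        with pytest.raises(InsufficientDataError):
            fit_ph_activation([5.0, 5.5, 6.0], [1.0, 0.5, 0.1])
        with pytest.raises(InsufficientDataError):
            fit_ph_activation([4.6, 5.0, 5.3, 5.6, 6.0],
                              [1, 0.9, 0.5, 0.2, 0.0], with_inactivation=True)

    def test_biphasic_fit_recovers_inactivation(self):
        ph = np.array([7.4, 6.0, 5.5, 5.25, 5.0, 4.8, 4.6, 4.2, 3.8, 3.4])
        y = hill_currents(ph) / (1 + 10 ** (2.0 * (4.0 - ph)))
        fit = fit_ph_activation(ph, y, with_inactivation=True)
        assert fit.converged
        assert fit.ph50 == pytest.approx(5.3, abs=1e-3)
        assert fit.ph_i == pytest.approx(4.0, abs=1e-3)

    def test_recovery_under_noise_is_reliable(self):
        """pH50 recovered within +/-0.1 in at least 95/100 seeded noisy runs
        (8 cells, 5% multiplicative noise)."""
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            ph = np.tile(PH_GRID, 8)
            sigma = np.sqrt(np.log1p(0.05**2))
            y = hill_currents(ph) * np.exp(r.normal(-sigma**2 / 2, sigma, ph.size))
            fit = HillPHActivation(ph, y).fit()
            if abs(fit.ph50 - 5.3) <= 0.1:
                hits += 1
        assert hits >= 95

    def test_negative_currents_supported(self):
        y = -hill_currents(PH_GRID)
        fit = fit_ph_activation(PH_GRID, y)
        assert fit.ph50 == pytest.approx(5.3, abs=1e-6)
        assert fit.i_max == pytest.approx(-1200.0, rel=1e-6)

    def test_summary_mentions_parameters(self):
        fit = fit_ph_activation(PH_GRID, hill_currents(PH_GRID))
        text = fit.summary()
        assert "ph50" in text and "n_h" in text


class TestScalarOps:
    def test_current_density(self):
        assert current_density(800.0, 10.0) == 80.0
        assert current_density(0.0, 12.0) == 0.0
        with pytest.raises(ValueError):
            current_density(800.0, 0.0)

    def test_percent_inhibition(self):
        assert percent_inhibition(100.0, 25.0) == pytest.approx(75.0)
        assert percent_inhibition(100.0, 100.0) == 0.0
        # potentiation (e.g. MTSES on a pore mutant): ratio 2 == -100%
        assert percent_inhibition(100.0, 200.0) == pytest.approx(-100.0)
        assert current_ratio(200.0, 100.0) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            percent_inhibition(0.0, 5.0)
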
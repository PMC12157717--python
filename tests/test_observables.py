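"""Titration forward models: dilution bookkeeping, signals and conservation."""

import math

import numpy as np
import pandas as pd
import pytest

from ionpairing.equilibria import EquilibriumModel
from ionpairing.observables import (
    ConductivityParams,
    EnthalpySet,
    IseCalibration,
    ShiftParams,
    SpectralParams,
    TitrationSchedule,
    calibrate_ise,
    fit_conductometric,
    itc_delta_moles,
    simulate_conductometric,
    simulate_itc,
    simulate_nmr_fast,
    simulate_potentiometric,
    simulate_uv,
)
from ionpairing.salts import SaltParams, regime_test, salt_model


def binding_model(log_k=8.0):
    return EquilibriumModel(["C", "H"], [("CH", [1, 1], log_k)])


class TestSchedule:
    def test_dilution_matches_independent_mole_ledger(self):
        sched = TitrationSchedule(
            25e-3, {"Na": 1e-4, "X": 2e-4}, {"Cl": 1e-2, "X": 1e-3}, [5e-6] * 20
        )
        comps = ["Na", "Cl", "X"]
        totals = sched.totals(comps)
        moles = np.array([25e-3 * 1e-4, 0.0, 25e-3 * 2e-4])
        vol = 25e-3
        assert np.allclose(totals[0], moles / vol, rtol=1e-15)
        for k, dv in enumerate(sched.additions, start=1):
            moles = moles + dv * np.array([0.0, 1e-2, 1e-3])
            vol += dv
            assert np.allclose(totals[k], moles / vol, rtol=1e-14)

    def test_nonpositive_volumes_rejected(self):
        with pytest.raises(ValueError):
            TitrationSchedule(0.0, {}, {}, [1e-6])
        with pytest.raises(ValueError):
            TitrationSchedule(1e-3, {}, {}, [0.0])


class TestPotentiometric:
    def test_nernstian_response_point(self):
        sched = TitrationSchedule(25e-3, {"Na": 1e-3}, {"Cl": 1e-2}, [1e-9])
        model = salt_model(None, 0.0)
        df = simulate_potentiometric(sched, model, IseCalibration(0.0, 59.2))
        assert df.pna.iloc[0] == pytest.approx(3.0, abs=1e-9)
        assert df.E.iloc[0] == pytest.approx(-177.6, abs=1e-6)

    def test_identical_totals_give_identical_pna(self):
        # jointly halving cell and addition volumes leaves every total, and
        # hence the whole pNa trace, unchanged (pure bookkeeping)
        a = TitrationSchedule(25e-3, {"Na": 1e-4}, {"A": 1e-2}, [10e-6] * 10)
        b = TitrationSchedule(12.5e-3, {"Na": 1e-4}, {"A": 1e-2}, [5e-6] * 10)
        model = salt_model(2e-9, 7.7e3)
        cal = IseCalibration(0.0, 59.2)
        pa = simulate_potentiometric(a, model, cal).pna
        pb = simulate_potentiometric(b, model, cal).pna
        assert np.allclose(pa, pb, rtol=1e-10)

    def test_onset_index_matches_regime_test(self):
        sched = TitrationSchedule(25e-3, {"Na": 1e-4}, {"Cl": 1e-2}, [5e-6] * 30)
        model = salt_model(2e-9, 7.7e3)
        df = simulate_potentiometric(sched, model, IseCalibration(0.0, 59.2))
        params = SaltParams(2e-9, 7.7e3)
        totals = sched.totals(["Na", "A"])
        expected = [
            regime_test(cn, ca, params) == "solid" for cn, ca in totals
        ]
        assert df.solid_present.tolist() == expected
        # the pNa series is continuous in value across the onset
        assert np.max(np.abs(np.diff(df.pna))) < 0.2


class TestIseCalibration:
    def test_exact_line_through_two_points(self):
        cal = calibrate_ise([1e-3, 1e-2], [-180.0, -120.0])
        assert cal.slope == pytest.approx(60.0)
        assert cal.intercept == pytest.approx(0.0, abs=1e-9)

    def test_noisy_slope_recovery_and_permutation(self, rng):
        c = np.logspace(-4, -2, 8)
        e = 12.0 + 58.5 * np.log10(c) + 0.3 * rng.standard_normal(8)
        cal = calibrate_ise(c, e)
        assert cal.slope == pytest.approx(58.5, abs=1.5)
        perm = rng.permutation(8)
        cal2 = calibrate_ise(c[perm], e[perm])
        assert cal2.slope == pytest.approx(cal.slope, rel=1e-12)

    def test_identical_standards_rejected(self):
        with pytest.raises(ValueError):
            calibrate_ise([1e-3, 1e-3], [-180.0, -180.1])


class TestConductometric:
    def test_unit_chain_single_ion(self):
        model = EquilibriumModel(["X"], charges=[1])
        sched = TitrationSchedule(25e-3, {"X": 1e-3}, {}, [1e-9])
        df = simulate_conductometric(sched, model, ConductivityParams({"X": 50.0}))
        assert df.kappa.iloc[0] == pytest.approx(5e-5, rel=1e-9)

    def test_no_pairing_is_linear_in_added_moles(self):
        model = EquilibriumModel(["B", "A"], charges=[1, -1])
        sched = TitrationSchedule(25e-3, {}, {"B": 5e-3, "A": 5e-3}, [100e-6] * 15)
        df = simulate_conductometric(
            sched, model, ConductivityParams({"B": 60.0, "A": 80.0})
        )
        vol = 25e-3 + sched.cumulative_volume
        moles_like = df.kappa.to_numpy() * vol  # dilution-corrected
        ratio = moles_like[1:] / sched.cumulative_volume[1:]
        assert np.allclose(ratio, ratio[0], rtol=1e-10)

    def test_ion_pairing_lowers_conductivity_pointwise(self):
        lam = ConductivityParams({"Na": 76.9, "A": 58.5})
        sched = TitrationSchedule(25e-3, {"Na": 5e-4}, {"A": 5e-3}, [100e-6] * 15)
        paired = simulate_conductometric(sched, salt_model(None, 3.6e4), lam)
        free = simulate_conductometric(sched, salt_model(None, 0.0), lam)
        assert np.all(paired.kappa.to_numpy() <= free.kappa.to_numpy())
        assert paired.kappa.iloc[-1] < free.kappa.iloc[-1]
        # the deficit vs. the pairing-free reference grows along the titration
        deficit = (free.kappa - paired.kappa).to_numpy()
        assert np.all(np.diff(deficit) > 0)

    def test_missing_lambda_for_charged_species(self):
        model = EquilibriumModel(["X", "Y"], charges=[1, -1])
        sched = TitrationSchedule(25e-3, {"X": 1e-3, "Y": 1e-3}, {}, [1e-9])
        with pytest.raises(ValueError, match="no molar conductivity"):
            simulate_conductometric(sched, model, ConductivityParams({"X": 50.0}))

    def test_joint_fit_recovers_kip_and_lambda(self):
        kip_true, lam_unknown = 3.6e4, 58.5
        lam = {"Na": 76.9, "ClO4": 103.7, "TBA": 61.6}
        sched = TitrationSchedule(
            25e-3, {"Na": 5e-4, "ClO4": 5e-4}, {"TBA": 5e-3, "A": 5e-3}, [240e-6] * 20
        )

        def builder(kip):
            species = [("NaA", [1, 1, 0, 0], math.log10(kip))] if kip > 0 else []
            return EquilibriumModel(
                ["Na", "A", "ClO4", "TBA"], species, charges=[1, -1, -1, 1]
            )

        data = simulate_conductometric(
            sched, builder(kip_true), ConductivityParams({**lam, "A": lam_unknown})
        )
        fr = fit_conductometric(data, sched, builder, lam, "A")
        assert fr.params["K_IP"] == pytest.approx(kip_true, rel=0.01)
        assert fr.params["lambda_A"] == pytest.approx(lam_unknown, rel=0.01)

    def test_lambda_from_dilution_series_agrees_with_titration_route(self):
        """Two independent synthetic routes to the anion conductivity agree."""
        lam_true = 58.5
        lam = {"Na": 76.9, "ClO4": 103.7, "TBA": 61.6}

        def builder(kip):
            species = [("NaA", [1, 1, 0, 0], math.log10(kip))] if kip > 0 else []
            return EquilibriumModel(
                ["Na", "A", "ClO4", "TBA"], species, charges=[1, -1, -1, 1]
            )

        sched_t = TitrationSchedule(
            25e-3, {"Na": 5e-4, "ClO4": 5e-4}, {"TBA": 5e-3, "A": 5e-3}, [240e-6] * 20
        )
        data_t = simulate_conductometric(
            sched_t, builder(3.6e4), ConductivityParams({**lam, "A": lam_true})
        )
        route1 = fit_conductometric(data_t, sched_t, builder, lam, "A")
        # pairing-free dilution series of the TBA salt alone
        sched_d = TitrationSchedule(25e-3, {}, {"TBA": 5e-3, "A": 5e-3}, [240e-6] * 15)
        data_d = simulate_conductometric(
            sched_d, builder(0.0), ConductivityParams({**lam, "A": lam_true})
        )
        route2 = fit_conductometric(data_d, sched_d, builder, lam, "A", fit_kip=False)
        assert route1.params["lambda_A"] == pytest.approx(
            route2.params["lambda_A"], rel=0.03
        )


class TestItc:
    def test_zero_enthalpy_zero_heats(self):
        sched = TitrationSchedule(1.43e-3, {"H": 2e-4}, {"C": 2e-3}, [10e-6] * 10)
        df = simulate_itc(sched, binding_model(), EnthalpySet({"CH": 0.0}, 1.43e-3))
        assert np.allclose(df.heat_uJ, 0.0, atol=1e-9)

    def test_strong_binding_plateau_and_equivalence(self):
        sched = TitrationSchedule(1.43e-3, {"H": 2e-4}, {"C": 2e-3}, [10e-6] * 25)
        df = simulate_itc(sched, binding_model(8.0), EnthalpySet({"CH": -40.0}, 1.43e-3))
        per_inj = -40.0 * 2e-3 * 10e-6 * 1e9  # drH x moles injected, in uJ
        assert np.allclose(df.heat_uJ.iloc[:8], per_inj, rtol=0.01)
        assert np.all(np.abs(df.heat_uJ.iloc[-5:]) < 0.01 * abs(per_inj))
        total_expected = -40.0 * 1.43e-3 * 2e-4 * 1e9
        assert df.heat_uJ.sum() == pytest.approx(total_expected, rel=0.05)

    def test_ledger_conservation_any_model(self):
        """Per-injection heats sum to the final-minus-initial species inventory."""
        model = salt_model(2.6e-8, 3.6e4)
        sched = TitrationSchedule(1.43e-3, {"Na": 5e-4}, {"A": 5e-3}, [10e-6] * 20)
        dn = itc_delta_moles(sched, model, 1.43e-3)
        # reconstruct the closed-system inventory independently
        from ionpairing.equilibria import solve_speciation

        v0 = 1.43e-3
        c_cell = np.array([5e-4, 0.0])
        c_syr = np.array([0.0, 5e-3])
        st0 = solve_speciation(model, c_cell)
        syr = solve_speciation(model, c_syr, allow_solids=False)
        expelled = np.zeros(len(model.species))
        for dv in sched.additions:
            c_cell = (c_cell * v0 + c_syr * dv) / (v0 + dv)
            st = solve_speciation(model, c_cell)
            expelled += dv * st.species
        final = v0 * st.species + expelled
        initial = v0 * st0.species + syr.species * sched.additions.sum()
        assert np.allclose(dn.sum(axis=0), final - initial, rtol=1e-9, atol=1e-18)

    def test_shallow_exothermic_pairing_curve(self):
        model = salt_model(None, 3.6e4)
        sched = TitrationSchedule(1.43e-3, {"Na": 5e-4}, {"A": 5e-3}, [10e-6] * 20)
        df = simulate_itc(sched, model, EnthalpySet({"NaA": -7.0}, 1.43e-3))
        q = df.heat_uJ.to_numpy()
        assert np.all(q < 0)  # exothermic throughout
        assert np.all(np.diff(np.abs(q)) < 0)  # shallow, monotonically fading


class TestUv:
    def test_single_species_linearity(self):
        wl = np.arange(260.0, 266.0)
        eps = np.linspace(100.0, 600.0, 6)
        model = EquilibriumModel(["H"])
        sched = TitrationSchedule(2.2e-3, {"H": 2e-4}, {}, [1e-9])
        a = simulate_uv(sched, model, SpectralParams(wl, {"H": eps}, 1.0))
        assert np.allclose(a.iloc[0].to_numpy(), eps * 2e-4, rtol=1e-9)

    def test_isosbestic_point_invariance(self):
        """Two-state crossing spectra: dilution-corrected A is constant at the crossing."""
        wl = np.arange(250.0, 291.0)
        eps_a = 5000.0 * np.exp(-0.5 * ((wl - 265) / 8) ** 2)
        eps_b = 7000.0 * np.exp(-0.5 * ((wl - 278) / 8) ** 2)
        cross = np.argmin(np.abs(eps_a - eps_b)[10:30]) + 10
        # refine: make them cross exactly at that wavelength
        eps_b *= eps_a[cross] / eps_b[cross]
        model = EquilibriumModel(["H", "A"], [("HA", [1, 1], 4.0)])
        sched = TitrationSchedule(2.2e-3, {"H": 2e-4}, {"A": 5e-3}, [20e-6] * 15)
        a = simulate_uv(
            sched, model, SpectralParams(wl, {"H": eps_a, "HA": eps_b}, 1.0)
        )
        vol = 2.2e-3 + sched.cumulative_volume
        corrected = a.iloc[:, cross].to_numpy() * vol
        assert np.allclose(corrected, corrected[0], rtol=1e-9)

    def test_third_spectrum_reconstruction_by_linear_algebra(self):
        from ionpairing.observables import titration_speciation

        wl = np.arange(260.0, 281.0)
        eps = {
            "H": 4000.0 * np.exp(-0.5 * ((wl - 268) / 7) ** 2),
            "A": np.zeros_like(wl),
            "HA": 9000.0 * np.exp(-0.5 * ((wl - 274) / 7) ** 2),
        }
        model = EquilibriumModel(["H", "A"], [("HA", [1, 1], 4.0)])
        sched = TitrationSchedule(2.2e-3, {"H": 2e-4}, {"A": 5e-3}, [20e-6] * 12)
        a = simulate_uv(sched, model, SpectralParams(wl, eps, 1.0)).to_numpy()
        states = titration_speciation(sched, model)
        conc = np.array([st.species for st in states])
        names = model.species_names
        known = conc[:, names.index("H")][:, None] * eps["H"][None, :]
        coef = conc[:, names.index("HA")][:, None]
        recovered, *_ = np.linalg.lstsq(coef, a - known, rcond=None)
        assert np.allclose(recovered[0], eps["HA"], rtol=1e-8, atol=1e-6)


class TestNmr:
    def test_single_species_returns_its_shift(self):
        model = EquilibriumModel(["H"])
        sched = TitrationSchedule(0.5e-3, {"H": 2e-4}, {}, [1e-9])
        df = simulate_nmr_fast(
            sched, model, ShiftParams({"H": 7.3}, {"H"}), pool="H"
        )
        assert np.allclose(df.delta_obs, 7.3)

    def test_fifty_fifty_average(self):
        # K and totals chosen so exactly half the pool is complexed
        model = EquilibriumModel(["H", "A"], [("HA", [1, 1], 4.0)])
        # [HA] = [H] requires free A = 1/K = 1e-4: use a large excess buffer
        sched = TitrationSchedule(0.5e-3, {"H": 1e-6, "A": 1e-4 + 5e-7}, {}, [1e-9])
        df = simulate_nmr_fast(
            sched, model, ShiftParams({"H": 7.0, "HA": 9.0}, {"H", "HA"}), pool="H"
        )
        assert df.delta_obs.iloc[0] == pytest.approx(8.0, abs=0.01)

    def test_observed_shift_within_fast_pool_hull(self):
        model = EquilibriumModel(["H", "A"], [("HA", [1, 1], 3.27)])
        sched = TitrationSchedule(0.5e-3, {"H": 2e-4}, {"A": 7e-3}, [10e-6] * 12)
        shifts = ShiftParams({"H": 7.0, "HA": 9.0}, {"H", "HA"})
        df = simulate_nmr_fast(sched, model, shifts, pool="H")
        assert df.delta_obs.between(7.0, 9.0).all()
        assert df.delta_obs.is_monotonic_increasing  # saturating downfield drift

    def test_slow_pool_strict_mode_raises(self):
        model = EquilibriumModel(["C", "H"], [("CH", [1, 1], 6.69)])
        sched = TitrationSchedule(0.5e-3, {"C": 1e-4, "H": 2e-4}, {}, [1e-9])
        shifts = ShiftParams({"H": 6.5}, {"H"})  # CH is slow and holds pool
        with pytest.raises(ValueError, match="fast-pool fractions"):
            simulate_nmr_fast(sched, model, shifts, pool="H", normalize=False)

    def test_slow_species_reported_as_separate_track(self):
        model = EquilibriumModel(["C", "H"], [("CH", [1, 1], 6.69)])
        sched = TitrationSchedule(0.5e-3, {"C": 1e-4, "H": 2e-4}, {}, [1e-9])
        shifts = ShiftParams({"H": 6.5, "CH": 7.0}, {"H"})
        df = simulate_nmr_fast(sched, model, shifts, pool="H")
        assert "frac_CH" in df and "delta_CH" in df
        assert df.frac_CH.iloc[0] == pytest.approx(0.5, rel=1e-2)
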
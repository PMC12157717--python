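"""Closed-form salt models vs. the generic solver, and method A/B/E/F fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ionpairing.equilibria import solve_speciation
from ionpairing.salts import (
    PnaTitrationData,
    SaltParams,
    SolubilitySeries,
    aes_solubility,
    fit_method_A,
    fit_method_B,
    fit_method_E,
    fit_method_F,
    free_na_no_solid,
    free_na_with_solid,
    kip_from_saturated,
    ks_from_solubility,
    phosphate_free_na_saturated,
    phosphate_solubility_implicit,
    regime_test,
    salt_model,
    solubility_pure,
    solubility_with_common_anion,
)


class TestClosedForms:
    @pytest.mark.parametrize(
        "ks, kip, expected",
        [
            (1e-8, 0.0, 1e-4),
            (2e-9, 7.7e3, math.sqrt(2e-9) + 2e-9 * 7.7e3),  # ~6.01e-5
        ],
    )
    def test_pure_solubility(self, ks, kip, expected):
        assert solubility_pure(ks, kip) == pytest.approx(expected, rel=1e-12)

    def test_ks_recovered_from_printed_sulfate_numbers(self):
        # s ~ 1.16e-3 with K_IP ~ 3.6e4 implies Ks ~ 2.6e-8 (printed value)
        ks = ks_from_solubility(1.16e-3, 3.6e4)
        assert ks == pytest.approx(2.6e-8, rel=0.15)

    @given(
        log_ks=st.floats(-14, -8),
        log_kip=st.floats(0, 9),
    )
    @settings(max_examples=50, deadline=None)
    def test_ks_inversion_is_exact(self, log_ks, log_kip):
        ks, kip = 10.0**log_ks, 10.0**log_kip
        assert ks_from_solubility(solubility_pure(ks, kip), kip) == pytest.approx(
            ks, rel=1e-9
        )

    def test_common_anion_at_zero_equals_pure(self):
        assert solubility_with_common_anion(2e-9, 7.7e3, 0.0) == solubility_pure(
            2e-9, 7.7e3
        )

    def test_common_anion_worked_value(self):
        s = solubility_with_common_anion(2e-9, 7.7e3, 1e-3)
        assert s == pytest.approx(
            0.5 * (3.08e-5 - 1e-3 + math.sqrt(1e-6 + 8e-9)), rel=1e-6
        )
        assert s == pytest.approx(1.74e-5, rel=1e-2)

    def test_common_anion_floor_is_ion_pair_term(self):
        ks, kip = 2e-9, 7.7e3
        s_vals = [solubility_with_common_anion(ks, kip, c) for c in np.logspace(-5, 0, 30)]
        ionic = np.array(s_vals) - ks * kip
        assert np.all(np.diff(ionic) < 0)  # common-ion suppression
        assert s_vals[-1] == pytest.approx(ks * kip, rel=1e-2)

    def test_free_na_no_solid_limit_branch(self):
        assert free_na_no_solid(1e-3, 5e-4, 0.0) == 1e-3

    def test_free_na_no_solid_symmetric_quadratic(self):
        # 1e4 x^2 + x = 1e-3  ->  x = 2.7016e-4
        x = free_na_no_solid(1e-3, 1e-3, 1e4)
        assert x == pytest.approx((-1 + math.sqrt(41)) / 2e4, rel=1e-12)

    @given(
        c_na=st.floats(1e-6, 1e-2),
        c_an=st.floats(1e-6, 1e-2),
        log_kip=st.floats(1, 7),
    )
    @settings(max_examples=60, deadline=None)
    def test_free_na_no_solid_matches_solver(self, c_na, c_an, log_kip):
        kip = 10.0**log_kip
        model = salt_model(None, kip)
        ref = solve_speciation(model, [c_na, c_an]).free[0]
        assert free_na_no_solid(c_na, c_an, kip) == pytest.approx(ref, rel=1e-8)

    @pytest.mark.parametrize(
        "c_na, c_an, ks, expected",
        [
            (1e-4, 1e-4, 2e-9, math.sqrt(2e-9)),
            (2e-4, 1e-4, 2e-9, 0.5 * (1e-4 + math.sqrt(1e-8 + 8e-9))),  # 1.1708e-4
            (2e-4, 1e-4, 0.0, 1e-4),  # Ks -> 0 limit: max(delta, 0)
        ],
    )
    def test_free_na_with_solid(self, c_na, c_an, ks, expected):
        assert free_na_with_solid(c_na, c_an, ks) == pytest.approx(expected, rel=1e-10)

    def test_regime_classification(self):
        params = SaltParams(2e-9, 1e4)
        assert regime_test(1e-6, 1e-6, params) == "no_solid"
        assert regime_test(1e-3, 1e-3, params) == "solid"
        # boundary: totals just below / above the pure-salt solubility
        s = solubility_pure(2e-9, 1e4)
        assert regime_test(s * (1 - 1e-6), s * (1 - 1e-6), params) == "no_solid"
        assert regime_test(s * (1 + 1e-4), s * (1 + 1e-4), params) == "solid"


class TestPhosphateForms:
    KS, KIP, KDIM = 2e-14, 1e9, 1e2

    def test_reduces_to_pure_solubility(self):
        s = phosphate_solubility_implicit(self.KS, self.KIP, 0.0, 0.0)
        assert s == pytest.approx(solubility_pure(self.KS, self.KIP), rel=1e-12)

    def test_matches_saturated_speciation(self):
        model = salt_model(self.KS, self.KIP, self.KDIM)
        sat = solve_speciation(model, [1.0, 1.0])
        s_ref = sat.free[0] + sat.species_conc("NaA")
        s = phosphate_solubility_implicit(self.KS, self.KIP, self.KDIM, 0.0)
        assert s == pytest.approx(s_ref, rel=1e-6)

    def test_common_ion_suppression_direction(self):
        s0 = phosphate_solubility_implicit(self.KS, self.KIP, self.KDIM, 0.0)
        s1 = phosphate_solubility_implicit(self.KS, self.KIP, self.KDIM, 5e-4)
        assert s1 < s0

    def test_free_na_saturated_limit(self):
        x = phosphate_free_na_saturated(self.KS, 1e-6)
        assert x == pytest.approx(math.sqrt(self.KS), rel=1e-3)

    def test_free_na_saturated_vs_solver(self):
        model = salt_model(self.KS, self.KIP, self.KDIM)
        sat = solve_speciation(model, [1.0, 1.0])
        assert phosphate_free_na_saturated(self.KS, self.KDIM) == pytest.approx(
            sat.free[0], rel=1e-6
        )

    def test_scaling_regime(self):
        # when K_dim*sqrt(Ks) << 1, scaling Ks by 100 scales the root by 10
        x1 = phosphate_free_na_saturated(1e-16, 10.0)
        x2 = phosphate_free_na_saturated(1e-14, 10.0)
        assert x2 / x1 == pytest.approx(10.0, rel=1e-3)

    def test_kip_from_saturated(self):
        assert kip_from_saturated(1.16e-3, 1.61e-4, 2.6e-8) == pytest.approx(
            3.8e4, rel=0.02
        )
        assert kip_from_saturated(1e-4, 1e-4, 1e-8) == 0.0
        with pytest.raises(ValueError):
            kip_from_saturated(1e-4, 2e-4, 1e-8)

    @given(log_k=st.floats(2, 6))
    @settings(max_examples=30, deadline=None)
    def test_kip_round_trip(self, log_k):
        ks, kip = 1e-9, 10.0**log_k
        s = solubility_pure(ks, kip)
        assert kip_from_saturated(s, math.sqrt(ks), ks) == pytest.approx(kip, rel=1e-9)


class TestAes:
    def test_printed_protocol_value(self):
        # 1.6 ppm, x10 dilution, 5.00 g water, 3.00 mL aliquot, M(Na)=22.99
        s = aes_solubility(1.6, 10, 5.00, 3.00, 22.99)
        assert s == pytest.approx(1.16e-3, rel=0.01)

    def test_zero_reading(self):
        assert aes_solubility(0.0, 10, 5.0, 3.0, 22.99) == 0.0

    def test_aliquot_volume_proportionality(self):
        a = aes_solubility(1.6, 10, 5.0, 3.0, 22.99)
        b = aes_solubility(1.6, 10, 5.0, 6.0, 22.99)
        assert a == pytest.approx(2 * b, rel=1e-12)


class TestEquivalenceWithSolver:
    """Closed forms agree with the speciation solver over random parameter draws."""

    def test_random_draws(self, rng):
        for _ in range(100):
            ks = 10.0 ** rng.uniform(-14, -8)
            kip = 10.0 ** rng.uniform(3, 9)
            c = 10.0 ** rng.uniform(-5, -2)
            # saturated solubility with common anion (Eq. 7 analog);
            # excess totals guarantee the solid phase is present
            model = salt_model(ks, kip)
            excess = 10.0 * (solubility_pure(ks, kip) + c)
            sat = solve_speciation(model, [excess, excess + c])
            s_ref = sat.free[0] + sat.species_conc("NaA")
            assert solubility_with_common_anion(ks, kip, c) == pytest.approx(
                s_ref, rel=1e-6
            )
            # homogeneous free cation (Eq. 10 analog)
            cn, ca = 10.0 ** rng.uniform(-5, -3, size=2)
            hom = solve_speciation(salt_model(None, kip), [cn, ca])
            assert free_na_no_solid(cn, ca, kip) == pytest.approx(
                hom.free[0], rel=1e-6
            )

    def test_compensation_property(self):
        """Raising K_IP by 1e6 while lowering Ks by 1e5 changes s as Eq.-(6) predicts."""
        ks, kip = 2e-9, 7.7e3
        s_ref = solubility_pure(ks, kip)
        s_new = solubility_pure(ks * 1e-5, kip * 1e6)
        predicted = math.sqrt(ks * 1e-5) + (ks * 1e-5) * (kip * 1e6)
        assert s_new == pytest.approx(predicted, rel=1e-12)
        assert s_new / s_ref == pytest.approx(predicted / s_ref, rel=1e-12)


def _series(ks, kip, kdim=0.0, c=(0.0, 1e-4, 3e-4, 6e-4, 1e-3)):
    if kdim > 0:
        s = [phosphate_solubility_implicit(ks, kip, kdim, x) for x in c]
    else:
        s = [solubility_with_common_anion(ks, kip, x) for x in c]
    return SolubilitySeries(np.array(c), np.array(s))


def _method_b_data(ks, kip, c0=1e-4, n=30, dv=5e-6, v0=25e-3, ct=1e-2):
    vad = np.cumsum(np.full(n, dv))
    cna = c0 * v0 / (v0 + vad)
    ca = ct * vad / (v0 + vad)
    params = SaltParams(ks, kip)
    lab = np.array([regime_test(x, y, params) for x, y in zip(cna, ca)])
    free = np.where(
        lab == "solid",
        [free_na_with_solid(x, y, ks) for x, y in zip(cna, ca)],
        [free_na_no_solid(x, y, kip) for x, y in zip(cna, ca)],
    )
    return PnaTitrationData(cna, ca, -np.log10(free)), lab


class TestFitters:
    def test_method_A_noise_free_recovery(self):
        fr = fit_method_A(_series(2e-9, 7.7e3))
        assert fr.params["Ks"] == pytest.approx(2e-9, rel=1e-3)
        assert fr.params["K_IP"] == pytest.approx(7.7e3, rel=1e-3)

    def test_method_A_noisy_recovery(self, rng):
        data = _series(2e-9, 7.7e3)
        noisy = SolubilitySeries(data.c_coion, data.s * (1 + 0.01 * rng.standard_normal(len(data.s))))
        fr = fit_method_A(noisy)
        assert fr.params["Ks"] == pytest.approx(2e-9, rel=0.2)
        assert fr.params["K_IP"] == pytest.approx(7.7e3, rel=0.2)

    def test_method_A_degenerate_design_flagged(self):
        with pytest.raises(ValueError, match="non-identifiable"):
            fit_method_A(SolubilitySeries(np.zeros(4), np.full(4, 6e-5)))

    def test_method_B_two_regime_recovery(self):
        data, lab = _method_b_data(2e-9, 7.7e3)
        assert {"no_solid", "solid"} <= set(lab)
        fr = fit_method_B(data)
        assert fr.params["s"] == pytest.approx(solubility_pure(2e-9, 7.7e3), rel=5e-3)
        assert fr.params["Ks"] == pytest.approx(2e-9, rel=5e-3)
        assert fr.params["K_IP"] == pytest.approx(7.7e3, rel=5e-3)

    def test_method_B_constrained_high_concentration(self):
        data, lab = _method_b_data(2e-9, 7.7e3, c0=5e-4, n=25, dv=50e-6)
        assert np.all(lab == "solid")
        fr = fit_method_B(data, s_fixed=solubility_pure(2e-9, 7.7e3))
        assert fr.params["Ks"] == pytest.approx(2e-9, rel=1e-3)

    def test_method_B_row_order_invariance(self, rng):
        data, _ = _method_b_data(2e-9, 7.7e3)
        perm = rng.permutation(len(data.pna))
        shuffled = PnaTitrationData(data.c_na[perm], data.c_anion[perm], data.pna[perm])
        a = fit_method_B(data)
        b = fit_method_B(shuffled)
        assert a.params["Ks"] == pytest.approx(b.params["Ks"], rel=1e-8)
        assert a.params["s"] == pytest.approx(b.params["s"], rel=1e-8)

    def test_method_E_noise_free_recovery(self):
        fr = fit_method_E(_series(2e-14, 1e9, 1e2), K_dim_fixed=1e2)
        assert fr.params["Ks"] == pytest.approx(2e-14, rel=5e-3)
        assert fr.params["K_IP"] == pytest.approx(1e9, rel=5e-3)

    def test_method_E_noisy_recovery(self, rng):
        # well-conditioned design: ionic and ion-pair contributions comparable
        # (at phosphate-preset constants the pair term dominates s and Ks is
        # barely identifiable under noise; see the methods note)
        ks, kip, kdim = 1e-8, 1e4, 1e2
        data = _series(ks, kip, kdim)
        noisy = SolubilitySeries(
            data.c_coion, data.s * (1 + 0.01 * rng.standard_normal(len(data.s)))
        )
        fr = fit_method_E(noisy, K_dim_fixed=kdim)
        assert fr.params["Ks"] == pytest.approx(ks, rel=0.2)
        assert fr.params["K_IP"] == pytest.approx(kip, rel=0.2)

    def test_method_E_degenerate_design_flagged(self):
        with pytest.raises(ValueError, match="non-identifiable"):
            fit_method_E(SolubilitySeries(np.zeros(3), np.full(3, 3e-6)), 1e2)

    def test_method_F_recovery_and_kip_round_trip(self):
        ks, kip, kdim = 2e-14, 1e9, 1e2
        s_true = phosphate_solubility_implicit(ks, kip, kdim, 0.0)
        model = salt_model(ks, kip, kdim)
        vad = np.cumsum(np.full(20, 25e-6))
        cna = 1e-4 * 25e-3 / (25e-3 + vad)
        ca = 1e-2 * vad / (25e-3 + vad)
        pna = np.array(
            [-math.log10(solve_speciation(model, [x, y]).free[0]) for x, y in zip(cna, ca)]
        )
        fr = fit_method_F(PnaTitrationData(cna, ca, pna), s_fixed=s_true, K_dim_fixed=kdim)
        assert fr.params["Ks"] == pytest.approx(ks, rel=0.01)
        assert fr.params["K_IP"] == pytest.approx(kip, rel=0.02)

    def test_method_F_unit_weights_reduce_to_ols(self):
        ks, kip, kdim = 2e-14, 1e9, 1e2
        s_true = phosphate_solubility_implicit(ks, kip, kdim, 0.0)
        model = salt_model(ks, kip, kdim)
        vad = np.cumsum(np.full(10, 25e-6))
        cna = 1e-4 * 25e-3 / (25e-3 + vad)
        ca = 1e-2 * vad / (25e-3 + vad)
        pna = np.array(
            [-math.log10(solve_speciation(model, [x, y]).free[0]) for x, y in zip(cna, ca)]
        )
        data = PnaTitrationData(cna, ca, pna)
        ones = fit_method_F(data, s_true, kdim, weights=np.ones(len(pna)))
        assert ones.params["Ks"] == pytest.approx(ks, rel=0.01)
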
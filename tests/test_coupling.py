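"""Karplus curves, pseudorotation algebra and torsion restraints."""

import numpy as np
import pytest

from ptdna.coupling import (
    KARPLUS_HH,
    KARPLUS_HP,
    CouplingSet,
    KarplusParams,
    SugarPucker,
    beta_classify,
    endocyclic_to_pucker,
    epsilon_from_j,
    estimate_pucker,
    karplus_j,
    predict_sugar_couplings,
    pucker_to_endocyclic,
    zeta_from_epsilon,
)


class TestKarplus:
    def test_ninety_degrees_gives_constant_term(self):
        p = KarplusParams(8.0, -1.3, 0.6)
        assert karplus_j(90.0, p) == pytest.approx(0.6, abs=1e-12)

    def test_trans_value_default_hh(self):
        assert karplus_j(180.0, KARPLUS_HH) == pytest.approx(11.0)

    @pytest.mark.parametrize("theta", [0.0, 33.0, 90.0, 121.4, 155.0])
    def test_even_function(self, theta):
        assert karplus_j(theta, KARPLUS_HH) == pytest.approx(
            karplus_j(-theta, KARPLUS_HH)
        )

    def test_positive_a_required(self):
        with pytest.raises(ValueError):
            KarplusParams(-1.0, 0.0, 0.0)


class TestPseudorotation:
    def test_nu2_at_phase_zero(self):
        nu = pucker_to_endocyclic(SugarPucker(0.0, 35.0))
        assert nu[2] == pytest.approx(35.0)

    def test_nu2_s_type(self):
        nu = pucker_to_endocyclic(SugarPucker(162.0, 35.0))
        assert nu[2] == pytest.approx(35.0 * np.cos(np.radians(162.0)))

    @pytest.mark.parametrize("P", list(range(0, 360, 10)))
    @pytest.mark.parametrize("phi", [25.0, 35.0, 45.0])
    def test_round_trip_machine_precision(self, P, phi):
        back = endocyclic_to_pucker(pucker_to_endocyclic(SugarPucker(P, phi)))
        dP = abs((back.P - P + 180.0) % 360.0 - 180.0)
        assert dP < 1e-9 and abs(back.phi_m - phi) < 1e-9

    def test_planar_ring_flagged_degenerate(self):
        p = endocyclic_to_pucker(np.zeros(5))
        assert p.degenerate

    def test_bad_input_rejected(self):
        with pytest.raises(ValueError):
            endocyclic_to_pucker([0.0, 1.0, np.nan, 0.0, 0.0])


class TestCouplingPrediction:
    def test_s_type_exceeds_n_type_h1h2(self):
        js = predict_sugar_couplings(SugarPucker(162.0, 35.0))
        jn = predict_sugar_couplings(SugarPucker(18.0, 38.0))
        assert js.J_H1p_H2p - jn.J_H1p_H2p >= 5.0
        assert js.J_H1p_H2p >= 8.0  # B-form S-type sugars couple strongly

    @pytest.mark.parametrize("phi", np.arange(26.0, 45.0, 2.0))
    def test_n_s_discrimination_over_amplitudes(self, phi):
        js = predict_sugar_couplings(SugarPucker(162.0, phi))
        jn = predict_sugar_couplings(SugarPucker(18.0, phi))
        assert js.J_H1p_H2p > jn.J_H1p_H2p

    def test_flat_ring_finite(self):
        j = predict_sugar_couplings(SugarPucker(0.0, 0.0))
        for _, v in j.hh_items():
            assert np.isfinite(v) and v >= 0


class TestPuckerEstimation:
    @pytest.mark.parametrize("P", list(range(0, 360, 10)))
    @pytest.mark.parametrize("phi", [30.0, 35.0, 40.0])
    def test_noiseless_recovery_to_grid_resolution(self, P, phi):
        js = predict_sugar_couplings(SugarPucker(float(P), phi))
        est, resid = estimate_pucker(js)
        dP = abs((est.P - P + 180.0) % 360.0 - 180.0)
        assert dP <= 1.0 and abs(est.phi_m - phi) <= 0.5
        assert resid < 1e-9

    def test_noisy_recovery_within_ten_degrees_on_average(self):
        # 0.5 Hz coupling noise: the P estimate wanders ~7 deg on average
        # (P and phi trade off); assert the seeded mean stays inside 10 deg
        for P in (140.0, 160.0, 180.0):
            errs = []
            for seed in range(20):
                rng = np.random.default_rng(seed)
                js = predict_sugar_couplings(SugarPucker(P, 36.0))
                noisy = CouplingSet(
                    **{k: max(0.0, v + rng.normal(0, 0.5)) for k, v in js.hh_items()}
                )
                est, _ = estimate_pucker(noisy)
                errs.append(abs((est.P - P + 180.0) % 360.0 - 180.0))
            assert np.mean(errs) <= 10.0

    def test_single_coupling_rejected(self):
        with pytest.raises(ValueError):
            estimate_pucker(CouplingSet(J_H1p_H2p=9.0))


class TestBackboneTorsions:
    def test_epsilon_at_curve_maximum_pre_branch(self):
        # theta = 180 is the only inversion at the maximum; eps = 180 - 120
        r = epsilon_from_j(KARPLUS_HP.jmax, KARPLUS_HP)
        assert r.center == pytest.approx(60.0, abs=1e-6)

    def test_epsilon_at_constant_term(self):
        # J = C -> theta in {90, arccos(B-free root)}; the branch nearest the
        # B-DNA trans region wins (eps ~ -186, i.e. +173.9 normalized)
        r = epsilon_from_j(KARPLUS_HP.C, KARPLUS_HP)
        assert r.center == pytest.approx(173.91, abs=0.05)

    def test_j_above_curve_maximum_rejected(self):
        with pytest.raises(ValueError):
            epsilon_from_j(25.0, KARPLUS_HP)
        with pytest.raises(ValueError):
            epsilon_from_j(-0.5, KARPLUS_HP)

    def test_bdna_compatible_j_inverts_inside_bdna_range(self):
        # the B-DNA eps branch covers theta in [-90, 0], i.e. J <= A + B + C
        for j in (2.0, 5.0, 8.0, 10.0):
            c = epsilon_from_j(j, KARPLUS_HP).center
            e = c if c < 0 else c - 360.0
            assert -210.0 - 1e-9 <= e <= -120.0 + 1e-9

    def test_zeta_from_epsilon_bi_offset(self):
        r = zeta_from_epsilon(-175.0)
        assert r.center == pytest.approx(-85.0)
        lo, hi = zeta_from_epsilon(-175.0, width=30.0).bounds
        assert (lo, hi) == (-115.0, -55.0)

    def test_zeta_outside_bdna_epsilon_rejected(self):
        with pytest.raises(ValueError):
            zeta_from_epsilon(0.0)

    def test_beta_classification(self):
        assert beta_classify(3.0).center == pytest.approx(180.0)
        assert beta_classify(10.0) is None
        with pytest.raises(ValueError):
            beta_classify(-1.0)

    def test_restraint_ranges_valid(self):
        for j in np.arange(0.5, 22.5, 1.0):
            r = epsilon_from_j(float(j), KARPLUS_HP)
            assert -180.0 < r.center <= 180.0 and r.width > 0
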
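"""Carbonate-system speciation, endmember regressions, error propagation.

The solver is cross-checked against an independently coded speciation oracle
(same published equilibrium-constant formulations, separately implemented
equations, scipy Brent root-finding on [H+]) and against frozen worked
values for typical bay water.
"""

import numpy as np
import pytest
from scipy.optimize import brentq

from baycarb import carbonate as cb


# ---------------------------------------------------------------------------
# independent speciation oracle (deliberately separate implementation)

def oracle_ph(ta_umol, dic_umol, t_c, s):
    """Total-scale pH from TA/DIC via an independently written balance."""
    tk = t_c + 273.15
    # Lueker et al. (2000)
    k1 = 10 ** -(3633.86 / tk - 61.2172 + 9.6777 * np.log(tk)
                 - 0.011555 * s + 0.0001152 * s ** 2)
    k2 = 10 ** -(471.78 / tk + 25.929 - 3.16967 * np.log(tk)
                 - 0.01781 * s + 0.0001122 * s ** 2)
    kb = np.exp((-8966.9 - 2890.53 * s ** 0.5 - 77.942 * s + 1.728 * s ** 1.5
                 - 0.0996 * s ** 2) / tk + 148.0248 + 137.1942 * s ** 0.5
                + 1.62142 * s - (24.4344 + 25.085 * s ** 0.5 + 0.2474 * s)
                * np.log(tk) + 0.053105 * s ** 0.5 * tk)
    kw = np.exp(148.9802 - 13847.26 / tk - 23.6521 * np.log(tk)
                + (118.67 / tk - 5.977 + 1.0495 * np.log(tk)) * s ** 0.5
                - 0.01615 * s)
    ion = 19.924 * s / (1000 - 1.005 * s)
    ks = np.exp(-4276.1 / tk + 141.328 - 23.093 * np.log(tk)
                + (-13856 / tk + 324.57 - 47.986 * np.log(tk)) * ion ** 0.5
                + (35474 / tk - 771.54 + 114.723 * np.log(tk)) * ion
                - 2698 / tk * ion ** 1.5 + 1776 / tk * ion ** 2
                + np.log(1 - 0.001005 * s))
    kf = np.exp(874 / tk - 9.68 + 0.111 * s ** 0.5)
    bt, st, ft = 0.0004157 * s / 35, 0.02824 * s / 35, 7e-5 * s / 35
    dic, ta = dic_umol * 1e-6, ta_umol * 1e-6

    def residual(ph):
        h = 10 ** -ph
        gamma = dic / (h * h + k1 * h + k1 * k2)
        hfree = h / (1 + st / ks)
        return (gamma * (k1 * h + 2 * k1 * k2) + bt / (1 + h / kb) + kw / h
                - hfree - ft / (1 + kf / hfree) - ta)

    return brentq(residual, 3.0, 12.0, xtol=1e-12)


# ---------------------------------------------------------------------------

class TestEndmemberRegressions:
    def test_ta_from_salinity_reproduces_typical_bay_water(self):
        assert cb.ta_from_salinity(30.0) == pytest.approx(2037.3, abs=0.05)
        assert cb.ta_from_salinity(0.0) == pytest.approx(477.62, abs=0.01)

    def test_dic_from_salinity_for_each_registered_model(self):
        assert cb.dic_from_salinity(30.0) == pytest.approx(1915.35, abs=0.05)
        assert cb.dic_from_salinity(0.0) == pytest.approx(397.65, abs=0.01)
        sensor = cb.ENDMEMBER_MODELS["sensor"]
        assert cb.dic_from_salinity(0.0, sensor) == pytest.approx(382.64)

    @pytest.mark.parametrize("s, expected", [(22.0, 17.0), (32.0, 32.0)])
    def test_sensor_vs_bottle_line_difference(self, s, expected):
        gap = (cb.dic_from_salinity(s, cb.ENDMEMBER_MODELS["sensor"])
               - cb.dic_from_salinity(s, cb.ENDMEMBER_MODELS["bottle"]))
        assert gap == pytest.approx(expected, abs=1.0)

    def test_affine_mixing_identity(self):
        ta = cb.ta_from_salinity
        assert ta(12.0) + ta(18.0) == pytest.approx(ta(30.0) + ta(0.0))

    def test_predictions_positive_over_estuarine_range(self):
        s = np.linspace(0, 35, 71)
        for model in cb.ENDMEMBER_MODELS.values():
            assert (model.ta(s) > 0).all() and (model.dic(s) > 0).all()


class TestSolver:
    def test_round_trip_closure_across_estuarine_envelope(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            t = rng.uniform(0, 30)
            s = rng.uniform(15, 35)
            ta = rng.uniform(1200, 2400)
            dic = rng.uniform(0.8, 0.97) * ta  # physical TA:DIC ratios
            ph = cb.solve_ph_from_ta_dic(ta, dic, t, s)
            dic_back = cb.dic_from_ta_ph(ta, ph, t, s)
            assert dic_back == pytest.approx(dic, abs=1e-4)
            ph_back = cb.solve_ph_from_ta_dic(ta, dic_back, t, s)
            assert abs(ph_back - ph) < 1e-6

    def test_agreement_with_independent_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            t = rng.uniform(0, 30)
            s = rng.uniform(15, 35)
            ta = rng.uniform(1200, 2400)
            dic = rng.uniform(0.82, 0.96) * ta
            mine = cb.solve_ph_from_ta_dic(ta, dic, t, s)
            ref = oracle_ph(ta, dic, t, s)
            assert abs(mine - ref) < 0.005

    def test_every_known_pair_reaches_the_same_state(self):
        base = cb.solve_carbonate({"TA": 2037.0, "DIC": 1915.0}, 17.0, 30.0)
        pairs = [{"TA": base.TA, "pH": base.pH},
                 {"DIC": base.DIC, "pH": base.pH},
                 {"pH": base.pH, "pCO2": base.pCO2},
                 {"TA": base.TA, "pCO2": base.pCO2},
                 {"DIC": base.DIC, "pCO2": base.pCO2}]
        for known in pairs:
            st = cb.solve_carbonate(known, 17.0, 30.0)
            assert st.TA == pytest.approx(base.TA, abs=0.01)
            assert st.DIC == pytest.approx(base.DIC, abs=0.01)
            assert st.pH == pytest.approx(base.pH, abs=1e-6)
            assert st.pCO2 == pytest.approx(base.pCO2, rel=1e-6)

    def test_bad_pair_is_rejected(self):
        with pytest.raises(ValueError):
            cb.solve_carbonate({"TA": 2000.0}, 17.0, 30.0)
        with pytest.raises(ValueError):
            cb.solve_carbonate({"TA": 2000.0, "DIC": 1900.0, "pH": 7.9},
                               17.0, 30.0)

    def test_constants_choice_is_recorded(self):
        st = cb.solve_carbonate({"TA": 2037.0, "DIC": 1915.0}, 17.0, 30.0)
        assert st.constants == cb.DEFAULT_CONSTANTS.name


class TestScaleOffset:
    def test_total_to_nbs_adds_the_constant(self):
        assert cb.ph_scale_offset(7.87, "total", "nbs") == pytest.approx(8.00)

    def test_identity_and_round_trip(self):
        assert cb.ph_scale_offset(8.1, "NBS", "nbs") == 8.1
        back = cb.ph_scale_offset(cb.ph_scale_offset(7.9, "total", "NBS"),
                                  "NBS", "total")
        assert back == pytest.approx(7.9)

    def test_unknown_scale_is_an_error(self):
        with pytest.raises(ValueError):
            cb.ph_scale_offset(8.0, "sws", "nbs")


@pytest.fixture(scope="module")
def typical():
    return cb.solve_carbonate({"TA": 2037.0, "DIC": 1915.0}, 17.0, 30.0)


class TestTemperatureSensitivities:

    def test_warming_lowers_ph_by_about_fifteen_millis(self, typical):
        drop = -cb.ph_temperature_sensitivity(typical)
        assert drop == pytest.approx(0.015, rel=0.05)

    def test_pco2_rises_a_few_percent_per_degree(self, typical):
        sens = cb.pco2_temperature_sensitivity(typical)
        assert sens > 0
        assert sens == pytest.approx(0.043, abs=0.005)

    def test_sensitivity_consistent_with_small_step(self, typical):
        coarse = cb.pco2_temperature_sensitivity(typical, dT=1.0)
        fine = cb.pco2_temperature_sensitivity(typical, dT=0.1) / 0.1
        assert coarse == pytest.approx(fine, rel=0.10)


class TestErrorPropagation:
    CONDITIONS = [(17.0, s, ph) for s in range(20, 33, 2)
                  for ph in (7.6, 7.9, 8.2)]

    def test_zero_input_error_gives_zero(self):
        mean, per = cb.propagate_dic_error(0.0, 0.0, self.CONDITIONS[:3],
                                           n_draws=100, seed=0)
        assert mean == pytest.approx(0.0, abs=1e-9)

    def test_deterministic_given_seed(self):
        a, _ = cb.propagate_dic_error(10, 0.1, self.CONDITIONS[:3], 500, seed=5)
        b, _ = cb.propagate_dic_error(10, 0.1, self.CONDITIONS[:3], 500, seed=5)
        assert a == b

    def test_small_error_linearity_in_ph_sigma(self):
        """Halving the pH error halves its DIC contribution (delta method)."""
        full, _ = cb.propagate_dic_error(0.0, 0.1, self.CONDITIONS[:6], 4000, seed=9)
        half, _ = cb.propagate_dic_error(0.0, 0.05, self.CONDITIONS[:6], 4000, seed=9)
        assert full / half == pytest.approx(2.0, rel=0.08)
        # cross-check the sigma against the analytic slope dDIC/dpH
        t, s, ph = self.CONDITIONS[0]
        ta = float(cb.ta_from_salinity(s))
        slope = (cb.dic_from_ta_ph(ta, ph + 0.005, t, s)
                 - cb.dic_from_ta_ph(ta, ph - 0.005, t, s)) / 0.01
        _, per = cb.propagate_dic_error(0.0, 0.05, [self.CONDITIONS[0]], 4000, seed=9)
        assert per[0] == pytest.approx(abs(slope) * 0.05, rel=0.10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            cb.propagate_dic_error(-1.0, 0.1, self.CONDITIONS[:1], 100, seed=0)
        with pytest.raises(ValueError):
            cb.propagate_dic_error(1.0, 0.1, self.CONDITIONS[:1], 0, seed=0)
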
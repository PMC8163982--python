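"""Curve fitting: logistic and kinetic models, kτ, Emax normalisation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gpcrbias import (LogisticModel, OnePhaseModel, RiseAndFallModel,
                      fit_logistic3, fit_onephase, fit_riseandfall,
                      normalise_emax, rate_vs_concentration,
                      SimTruth, NoiseModel, PlateDesign, simulate_panel,
                      process_panel)
from gridsearch_oracle import (logistic_oracle, onephase_oracle,
                               riseandfall_oracle)


def _logistic_data(bottom, top, pec50, x):
    return bottom + (top - bottom) / (1 + 10.0 ** (-pec50 - x))


class TestLogistic:
    def test_noiseless_recovery_to_1e6(self):
        conc = np.logspace(-9.5, -4.5, 10)
        y = _logistic_data(0.0, 100.0, 6.7, np.log10(conc))
        fit = fit_logistic3(conc, y)
        assert fit.converged
        assert fit.bottom == pytest.approx(0.0, abs=1e-6)
        assert fit.top == pytest.approx(100.0, abs=1e-4)
        assert fit.pec50 == pytest.approx(6.7, abs=1e-6)
        assert fit.hill == 1.0

    def test_midpoint_identity(self):
        conc = np.logspace(-9, -4, 8)
        y = _logistic_data(10.0, 90.0, 6.5, np.log10(conc))
        fit = fit_logistic3(conc, y, bottom_floor=None)
        assert fit.predict(10 ** -fit.pec50) == pytest.approx(
            (fit.bottom + fit.top) / 2, rel=1e-9)

    def test_decade_shift_reparameterisation_stability(self):
        conc = np.logspace(-9.5, -4.5, 10)
        y = _logistic_data(0.0, 1.0, 6.7, np.log10(conc))
        rng = np.random.default_rng(7)
        y = y + rng.normal(0, 0.02, y.size)
        f1 = fit_logistic3(conc, y)
        f2 = fit_logistic3(conc / 10.0, y)
        assert f2.pec50 == pytest.approx(f1.pec50 + 1.0, abs=1e-6)
        assert f2.rss == pytest.approx(f1.rss, rel=1e-8)

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError, match="4 distinct"):
            LogisticModel([1e-9, 1e-8, 1e-7], [0, 1, 2])

    def test_flat_responses_flagged_not_converged(self):
        fit = fit_logistic3(np.logspace(-9, -5, 5), np.full(5, 3.0))
        assert not fit.converged
        assert "identifiable" in fit.message

    def test_four_parameter_fit_recovers_hill(self):
        conc = np.logspace(-10, -4, 12)
        x = np.log10(conc)
        y = 5.0 + 95.0 / (1 + 10.0 ** (1.6 * (-7.0 - x)))
        fit = LogisticModel(conc, y).fit(n_params=4)
        assert fit.hill == pytest.approx(1.6, abs=1e-4)
        assert fit.pec50 == pytest.approx(7.0, abs=1e-5)

    def test_monte_carlo_pec50_recovery_within_tenth(self):
        # glucagon/arrestin profile: pEC50 6.1, Emax 100%, cv 5%
        rng = np.random.default_rng(11)
        conc = np.logspace(-8.1, -4.1, 10)
        truth = _logistic_data(0.0, 1.0, 6.1, np.log10(conc))
        fits = [fit_logistic3(conc, truth * (1 + rng.normal(0, 0.05,
                                                            conc.size)))
                for _ in range(60)]
        assert np.mean([f.pec50 for f in fits]) == pytest.approx(6.1,
                                                                 abs=0.1)


class TestOnePhase:
    def test_noiseless_recovery_and_ktau(self):
        t = np.arange(0, 30.5, 0.5)
        fit = fit_onephase(t, 1.0 * (1 - np.exp(-0.5 * t)))
        assert fit.ss == pytest.approx(1.0, abs=1e-9)
        assert fit.k == pytest.approx(0.5, abs=1e-9)
        assert fit.ktau == pytest.approx(0.5, abs=1e-8)

    def test_ktau_identity_percent_units(self):
        t = np.arange(0, 30.5, 0.5)
        fit = fit_onephase(t, 100.0 * (1 - np.exp(-0.30 * t)))
        assert fit.ktau == pytest.approx(30.0, rel=1e-8)  # %/min

    def test_deret_like_rate_recovery_median_within_15pct(self):
        # slow internalisation kinetics, cv 3%, median over seeds
        truth = SimTruth("SRB103H", "internalisation", 7.7, 1.0,
                         "one_phase", k=0.14)
        design = PlateDesign(concentration_grid=(10 ** -5.7,),
                             n_replicate_assays=1, technical_replicates=1)
        noise = NoiseModel(cv_multiplicative=0.03, seed=0)
        ks = []
        for child in np.random.SeedSequence(3).spawn(50):
            panel = simulate_panel([truth], design, noise,
                                   rng=np.random.default_rng(child))
            tr = [t for t in process_panel(panel) if t.role == "agonist"][0]
            ks.append(fit_onephase(tr.stim_times(), tr.stim_response()).k)
        assert abs(np.median(ks) - 0.14) / 0.14 < 0.15

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            OnePhaseModel([0, 1, 2], [0.0, 0.5, 0.7])  # too few points
        with pytest.raises(ValueError):
            OnePhaseModel([0, 1, 1, 2], [0, 1, 1, 1])  # non-increasing


class TestRiseAndFall:
    def test_noiseless_recovery_ktau_1p7(self):
        t = np.arange(0, 30.5, 0.5)
        y = 2.0 * (np.exp(-0.05 * t) - np.exp(-0.9 * t))
        fit = fit_riseandfall(t, y)
        assert fit.d == pytest.approx(2.0, abs=1e-8)
        assert fit.k1 == pytest.approx(0.05, abs=1e-9)
        assert fit.k2 == pytest.approx(0.9, abs=1e-8)
        assert fit.ktau == pytest.approx(1.7, abs=1e-7)
        assert not fit.degenerate

    def test_k1_zero_limit_matches_one_phase_identity(self):
        t = np.arange(0, 30.5, 0.5)
        y = 1.5 * (1 - np.exp(-0.4 * t))  # k1 = 0 limit
        fit = fit_riseandfall(t, y)
        assert fit.k1 == pytest.approx(0.0, abs=1e-6)
        assert fit.ktau == pytest.approx(1.5 * 0.4, rel=1e-4)
        assert fit.degenerate  # decline phase absent, flagged

    def test_canonical_ordering_k2_gt_k1_d_positive(self):
        t = np.arange(0, 30.5, 0.5)
        y = 2.0 * (np.exp(-0.05 * t) - np.exp(-0.9 * t))
        fit = fit_riseandfall(t, y)
        assert fit.k2 > fit.k1 >= 0
        assert fit.d > 0

    @pytest.mark.parametrize("params", [
        ("one_phase", {"ss": 1.3, "k": 0.27}),
        ("rise_and_fall", {"d": 2.0, "k1": 0.05, "k2": 0.9}),
    ])
    def test_ktau_equals_finite_difference_initial_slope(self, params):
        model, p = params
        t = np.arange(0, 30.5, 0.5)
        if model == "one_phase":
            y = p["ss"] * (1 - np.exp(-p["k"] * t))
            fit = fit_onephase(t, y)
        else:
            y = p["d"] * (np.exp(-p["k1"] * t) - np.exp(-p["k2"] * t))
            fit = fit_riseandfall(t, y)
        h = 1e-7
        slope = (fit.predict(h) - fit.predict(0.0)) / h
        assert fit.ktau == pytest.approx(float(slope), abs=1e-6)


class TestGridOracleEquivalence:
    """Fits agree with an exhaustive grid + polish oracle on tiny inputs."""

    def test_logistic_six_points(self):
        conc = np.logspace(-9, -5, 6)
        y = _logistic_data(0.1, 1.9, 6.9, np.log10(conc))
        fit = fit_logistic3(conc, y)
        oracle = logistic_oracle(conc, y)
        for name in ("bottom", "top", "pec50"):
            assert getattr(fit, name) == pytest.approx(oracle[name],
                                                       abs=1e-4)

    def test_onephase_six_points(self):
        t = np.array([0.0, 2.0, 5.0, 10.0, 20.0, 30.0])
        y = 1.2 * (1 - np.exp(-0.21 * t))
        fit = fit_onephase(t, y)
        oracle = onephase_oracle(t, y)
        assert fit.ss == pytest.approx(oracle["ss"], abs=1e-4)
        assert fit.k == pytest.approx(oracle["k"], abs=1e-4)

    def test_riseandfall_six_points(self):
        t = np.array([0.0, 1.5, 3.0, 6.0, 15.0, 30.0])
        y = 1.8 * (np.exp(-0.06 * t) - np.exp(-0.7 * t))
        fit = fit_riseandfall(t, y)
        oracle = riseandfall_oracle(t, y)
        for name in ("d", "k1", "k2"):
            assert fit.params[name] == pytest.approx(oracle[name], abs=1e-4)


class TestNormaliseEmax:
    def _fits(self, tops, pec50=6.5):
        conc = np.logspace(-9, -4, 8)
        out = {}
        for i, top in enumerate(tops):
            y = _logistic_data(0.0, top, pec50, np.log10(conc))
            out[f"L{i}"] = fit_logistic3(conc, y)
        return out

    def test_single_full_agonist_rule(self):
        fits = normalise_emax(self._fits([2.0, 1.0]), full_agonists=["L0"])
        assert fits["L0"].emax_pct == pytest.approx(100.0)
        assert fits["L1"].emax_pct == pytest.approx(50.0, abs=1e-6)

    def test_two_full_agonists_share_global_maximum(self):
        fits = normalise_emax(self._fits([1.98, 2.02]),
                              full_agonists=["L0", "L1"])
        # shared-top joint refit: both near 100, straddling it
        assert fits["L0"].emax_pct == pytest.approx(99.0, abs=0.5)
        assert fits["L1"].emax_pct == pytest.approx(101.0, abs=0.5)

    def test_partial_agonist_convention(self):
        # glucagon-analogue convention: truth fraction 0.54 reads as 54%
        fits = normalise_emax(self._fits([1.0, 0.54]), reference="L0")
        assert fits["L1"].emax_pct == pytest.approx(54.0, abs=1e-4)

    def test_auto_detection_picks_near_maximal_tops(self):
        fits = normalise_emax(self._fits([2.0, 1.95, 0.8]))
        assert fits["L2"].emax_pct == pytest.approx(40.0, abs=1.0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            normalise_emax({})


class TestRateVsConcentration:
    def test_constant_rate_mode_is_flat(self):
        truth = SimTruth("x", "p", 7.0, 1.0, "one_phase", k=0.4)
        design = PlateDesign.around_pec50(7.0, n_points=6,
                                          n_replicate_assays=1,
                                          technical_replicates=1)
        panel = simulate_panel([truth], design, NoiseModel.noiseless())
        traces = [t for t in process_panel(panel) if t.role == "agonist"]
        table = rate_vs_concentration(traces, min_conc=10 ** -8.0)
        fitted = table[~table.skipped]
        np.testing.assert_allclose(fitted["k"], 0.4, rtol=1e-6)

    def test_insufficient_concentrations_above_threshold(self):
        truth = SimTruth("x", "p", 7.0, 1.0, "one_phase", k=0.4)
        design = PlateDesign.around_pec50(7.0, n_points=5,
                                          n_replicate_assays=1,
                                          technical_replicates=1)
        panel = simulate_panel([truth], design, NoiseModel.noiseless())
        traces = [t for t in process_panel(panel) if t.role == "agonist"]
        with pytest.raises(ValueError, match="concentrations above"):
            rate_vs_concentration(traces, min_conc=1e-6)
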
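"""Internal-standard + RSF quantification: arithmetic oracles, closure
properties, LOD, precision and QC."""

import numpy as np
import pytest

import mgcalab.quantification as q
from mgcalab import (SignalScenario, macs3_scenario, reduce_spot,
                     simulate_session, simulate_spot)
from mgcalab.quantification import (MACS3, QCWarning, QuantificationConstants,
                                    RSFModel, compute_rsf,
                                    correct_concentration,
                                    limit_of_detection, mass_to_molar_ratio,
                                    qc_filter, quantify_session,
                                    replicate_precision, standard_rsf,
                                    uncorrected_concentration)

# direct-arithmetic oracle: 400400 * (0.02086/0.1000) * (24.305/40.078)
UNCORR_AT_UNIT_RATIO = 400_400 * (0.02086 / 0.1000) * (24.305 / 40.078)
# molar-ratio oracle for MACS-3: (1756/24.305)/(376900/40.078) * 1000
MACS3_MMOLMOL = (1756 / 24.305) / (376_900 / 40.078) * 1000


class TestEquationChain:
    def test_uncorrected_zero_ratio(self):
        assert uncorrected_concentration(0.0) == 0.0

    def test_uncorrected_unit_ratio_matches_hand_arithmetic(self):
        assert uncorrected_concentration(1.0) == pytest.approx(
            UNCORR_AT_UNIT_RATIO, rel=1e-12)

    def test_uncorrected_linear_in_ratio(self):
        assert uncorrected_concentration(0.4) == pytest.approx(
            2 * uncorrected_concentration(0.2), rel=1e-12)

    def test_uncorrected_negative_ratio_errors(self):
        with pytest.raises(ValueError):
            uncorrected_concentration(-0.1)

    @pytest.mark.parametrize("uncorr,expected", [(1756.0, 1.0), (3512.0, 2.0)])
    def test_rsf_definition(self, uncorr, expected):
        assert compute_rsf(uncorr, MACS3) == expected

    def test_rsf_nonpositive_errors(self):
        with pytest.raises(ValueError):
            compute_rsf(0.0, MACS3)

    def test_correct_concentration(self):
        assert correct_concentration(3512.0, 2.0) == 1756.0
        assert correct_concentration(5.0, 1.0) == 5.0
        with pytest.raises(ValueError):
            correct_concentration(5.0, 0.0)

    def test_molar_ratio_unit(self):
        c = QuantificationConstants()
        c_mg_equimolar = c.mass_el / c.mass_is * 1000.0
        assert mass_to_molar_ratio(c_mg_equimolar, 1000.0) == pytest.approx(
            1000.0, rel=1e-12)

    def test_molar_ratio_macs3(self):
        assert mass_to_molar_ratio(1756.0, 376_900.0) == pytest.approx(
            MACS3_MMOLMOL, rel=1e-12)

    def test_molar_ratio_scale_invariant(self):
        a = mass_to_molar_ratio(850.0, 400_400.0)
        b = mass_to_molar_ratio(8.5, 4004.0)
        assert a == pytest.approx(b, rel=1e-12)


class TestLODAndPrecision:
    def test_constant_blank(self):
        res = limit_of_detection([7.0, 7.0, 7.0])
        assert res.lod == res.blank_mean == 7.0

    def test_small_blank_arithmetic(self):
        res = limit_of_detection([1.0, 2.0, 3.0])
        assert res.blank_mean == 2.0
        assert res.blank_sd == pytest.approx(1.0)
        assert res.lod == pytest.approx(5.0)

    def test_too_few_readings(self):
        with pytest.raises(ValueError):
            limit_of_detection([1.0, 2.0])

    def test_poisson_blank_approaches_moments(self, rng):
        """Large-n Poisson blank: LOD tends to lambda + 3 sqrt(lambda)
        (oracle: Poisson mean = variance = lambda)."""
        lam = 40.0
        res = limit_of_detection(rng.poisson(lam, size=200_000))
        assert res.lod == pytest.approx(lam + 3 * np.sqrt(lam), rel=0.02)

    def test_lod_monotone_in_blank_sd(self, rng):
        base = rng.normal(100.0, 1.0, size=500)
        wide = 100.0 + (base - 100.0) * 5.0
        assert limit_of_detection(wide).lod > limit_of_detection(base).lod

    def test_rsd_identical_values(self):
        assert replicate_precision([4.0, 4.0, 4.0]) == 0.0

    def test_rsd_arithmetic(self):
        assert replicate_precision([9.0, 10.0, 11.0]) == pytest.approx(10.0)

    def test_rsd_scale_invariant(self, rng):
        x = rng.normal(10.0, 0.5, size=30)
        assert replicate_precision(x * 7.0) == pytest.approx(
            replicate_precision(x), rel=1e-12)

    def test_rsd_errors(self):
        with pytest.raises(ValueError):
            replicate_precision([5.0])
        with pytest.raises(ValueError):
            replicate_precision([-1.0, 1.0])

    def test_macs3_replicate_rsd_low_single_digit(self):
        """6-12 MACS-3 replicates under default counting statistics give a
        replicate RSD in the low single-digit-percent range."""
        # one bracketing standard defines the RSF; replicates are then
        # independent analyses against that common calibration
        cal = reduce_spot(simulate_spot(macs3_scenario(noise="poisson",
                                                       seed=99),
                                        target="standard"))
        rsf = standard_rsf(cal)
        values = []
        for seed in range(10):
            scn = macs3_scenario(noise="poisson", seed=seed)
            series = reduce_spot(simulate_spot(scn, target="standard"))
            res = q.quantify_spot(series, rsf, QuantificationConstants(
                c_is=MACS3.c_ca_true))
            values.append(res.mgca_mmolmol)
        rsd = replicate_precision(values)
        assert 0.3 < rsd < 5.0


class TestQCFilter:
    def test_typical_value_passes(self):
        assert qc_filter(3.74) == "pass"

    def test_above_20_rejected(self):
        assert qc_filter(25.0) == "rejected_gt20"

    def test_out_of_typical_range_warns_but_passes(self):
        with pytest.warns(QCWarning):
            assert qc_filter(0.5) == "pass"
        with pytest.warns(QCWarning):
            assert qc_filter(15.0) == "pass"


class TestRSFModel:
    def test_nearest_and_linear(self):
        m = RSFModel([0.0, 100.0], [1.0, 3.0], interpolation="linear")
        assert m.rsf_at(50.0) == pytest.approx(2.0)
        assert m.rsf_at(-10.0) == 1.0  # clamped at the session edge
        n = RSFModel([0.0, 100.0], [1.0, 3.0], interpolation="nearest")
        assert n.rsf_at(30.0) == 1.0
        assert n.rsf_at(70.0) == 3.0

    def test_validation(self):
        with pytest.raises(ValueError):
            RSFModel([0.0, 0.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            RSFModel([0.0], [-1.0])


class TestClosure:
    def test_end_to_end_noiseless_identity(self, contaminated_scenario,
                                           standard_scenario):
        """Simulate -> reduce -> RSF-quantify recovers the scenario's true
        Mg/Ca to float precision, despite contamination."""
        trains = simulate_session(2, 28, [contaminated_scenario],
                                  standard_scenario, seed=0)
        results, _ = quantify_session(trains)
        for res in results:
            assert res.qc == "pass"
            assert res.mgca_mmolmol == pytest.approx(3.5, rel=1e-9)

    def test_macs3_self_calibration_exact(self, standard_scenario):
        """Quantifying the calibrant against its own RSF reproduces the
        certified 1756 ug/g exactly."""
        series = reduce_spot(simulate_spot(standard_scenario,
                                           target="standard"))
        rsf = standard_rsf(series)
        res = q.quantify_spot(series, rsf, QuantificationConstants(
            c_is=MACS3.c_ca_true))
        assert res.c_mg == pytest.approx(1756.0, rel=1e-12)
        assert res.mgca_mmolmol == pytest.approx(MACS3_MMOLMOL, rel=1e-12)

    @pytest.mark.parametrize("bias", [0.7, 1.0, 4.0])
    def test_instrument_bias_removed_by_rsf(self, bias, standard_scenario):
        """The quantified Mg/Ca is invariant to a common instrument bias
        factor applied to the Mg channel sensitivity (RSF removes it), and
        the recovered RSF equals the constructed bias ratio."""
        scn = SignalScenario(true_mgca=3.5, mg_sensitivity=0.1 * bias)
        std = macs3_scenario(mg_sensitivity=0.1 * bias)
        trains = simulate_session(1, 28, [scn], std, seed=0)
        results, rsf_model = quantify_session(trains)
        assert results[0].mgca_mmolmol == pytest.approx(3.5, rel=1e-9)
        # oracle: RSF = (s_mg/s_ca) * (A_k/A_i) * (M_EL/M_IS)
        c = QuantificationConstants()
        expected_rsf = (0.1 * bias / 1.5) * (c.abundance_k / c.abundance_i) \
            * (c.mass_el / c.mass_is)
        assert rsf_model.rsf_values[0] == pytest.approx(expected_rsf,
                                                        rel=1e-9)

    def test_linear_drift_linear_interpolation_unbiased(self):
        """Differential (Mg-only) linear sensitivity drift is removed for a
        sample midway between brackets when the RSF is interpolated
        linearly, but not with nearest-standard RSF."""
        drift = 0.5  # fractional per hour, large to make the effect visible
        scn = SignalScenario(true_mgca=3.5)
        std = macs3_scenario()

        def with_mg_drift(trains):
            # impose Mg-only drift multiplicatively after simulation, from
            # the closed-form factor (Ca stays put so the ratio drifts)
            out = []
            for t in trains:
                f = 1 + drift * (t.acquired_at_s + t.times) / 3600
                bg = t.truth.background_mg
                t.mg25_cps = bg + (t.mg25_cps - bg) * f
                out.append(t)
            return out

        trains = with_mg_drift(simulate_session(3, 3, [scn], std, seed=0))
        results_lin, _ = quantify_session(trains, interpolation="linear")
        mid = results_lin[1]  # sample midway between the two standards
        assert mid.mgca_mmolmol == pytest.approx(3.5, rel=1e-6)

        trains = with_mg_drift(simulate_session(3, 3, [scn], std, seed=0))
        results_near, _ = quantify_session(trains, interpolation="nearest")
        assert abs(results_near[1].mgca_mmolmol - 3.5) > 1e-3

    def test_failed_spot_propagates(self, standard_scenario):
        """A sample too weak to pass the minimum-count rule comes back as a
        failed SpotResult, not a silent average."""
        weak = SignalScenario(true_mgca=3.5, mg_sensitivity=1e-4)
        trains = simulate_session(1, 28, [weak], standard_scenario, seed=0)
        results, _ = quantify_session(trains)
        assert len(results) == 1
        assert results[0].qc == "failed"
        assert np.isnan(results[0].mgca_mmolmol)

    def test_session_without_standards_errors(self, clean_scenario):
        trains = simulate_session(2, 28, [clean_scenario],
                                  macs3_scenario(), seed=0)
        samples_only = [t for t in trains if t.target == "sample"]
        with pytest.raises(ValueError, match="standard"):
            quantify_session(samples_only)
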
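"""In-silico stimulation paradigms and their published phenomenology."""

import numpy as np
import pytest

import seqpool as sp


class TestFlashExperiment:
    def test_spm_uncaging_kinetics(self, spm_flash):
        """The wild-type uncaging response: fast burst near 50 1/s with
        the slow burst roughly an order of magnitude slower."""
        fit = spm_flash.fit
        assert fit.rate_fast == pytest.approx(50.0, rel=0.25)
        assert 7.0 < fit.tau2 / fit.tau1 < 15.0
        assert fit.converged

    def test_ppm_uncaging_is_biphasic(self, ppm):
        fit = sp.flash_experiment(ppm).fit
        assert fit.A1 > 30 and fit.A2 > 30
        assert fit.tau2 > 3 * fit.tau1

    def test_no_step_gives_pure_sustained(self, spm):
        """With post = pre the response is the resting linear release:
        no burst components, slope equal to the steady flux."""
        res = sp.flash_experiment(spm, pre_ca=0.5, post_ca=0.5, window=2.0)
        _, flux = spm.steady_state(0.5)
        assert res.fit.onset_flagged  # no inflection to find
        assert res.fit.total_burst < 0.2
        assert res.fit.A3 == pytest.approx(flux, rel=0.05)

    def test_deterministic_rerun(self, spm, spm_flash):
        again = sp.flash_experiment(spm)
        assert again.fit.to_dict() == spm_flash.fit.to_dict()
        np.testing.assert_array_equal(again.trace.dCm, spm_flash.trace.dCm)


@pytest.fixture(scope="module")
def postflash_df(spm):
    return sp.postflash_scan(spm, [2.0, 10.0, 25.0, 100.0, 1000.0])


@pytest.fixture(scope="module")
def preflash_df(spm):
    return sp.preflash_scan(spm, [0.05, 0.2, 0.5, 0.7, 1.5])


@pytest.fixture(scope="module")
def depletion_df(spm):
    return sp.selective_depletion_recovery(spm, [0.0, 2.0, 10.0, 60.0])


class TestPostflashScan:
    def test_slow_rate_saturates_at_catalyzed_ceiling(self, postflash_df):
        """The slow-component rate approaches the catalyzed priming
        ceiling (~20 1/s) at very high Ca2+ and is near half of it at
        the catalyst K_D of 100 uM."""
        r1000 = postflash_df.set_index("post_ca").rate_slow_per_s[1000.0]
        r100 = postflash_df.set_index("post_ca").rate_slow_per_s[100.0]
        assert r1000 == pytest.approx(20.0, rel=0.15)
        assert r100 == pytest.approx(10.0, rel=0.15)

    def test_fast_rate_monotone_in_post_ca(self, postflash_df):
        assert postflash_df.rate_fast_per_s.is_monotonic_increasing

    def test_fast_fraction_stable_except_low_ca(self, postflash_df):
        frac = postflash_df.set_index("post_ca").fast_fraction
        high = frac[frac.index >= 10.0]
        assert high.max() - high.min() < 0.2
        assert frac[2.0] < 0.5 * high.mean()  # collapses at low post-flash Ca


class TestPreflashScan:
    def test_amplitudes_are_bell_shaped(self, preflash_df):
        """Burst amplitudes rise with resting Ca2+ (Ca2+-dependent
        recruitment) and fall again at higher resting Ca2+ (standing
        depletion): interior maximum."""
        a1 = preflash_df.A1_fF.to_numpy()
        imax = int(np.argmax(a1))
        assert 0 < imax < a1.size - 1
        assert a1[0] < 0.5 * a1[imax] and a1[-1] < 0.8 * a1[imax]

    def test_amplitudes_vanish_at_zero_resting_ca(self, spm):
        res = sp.flash_experiment(spm, pre_ca=1e-4, post_ca=25.0, window=2.0)
        assert res.fit.total_burst < 2.0

    def test_fast_fraction_nearly_constant(self, preflash_df):
        frac = preflash_df.set_index("pre_ca").fast_fraction.loc[0.2:0.7]
        assert (frac.max() - frac.min()) / frac.mean() < 0.2


class TestSelectiveDepletionRecovery:
    def test_pulse_selectively_empties_fast_component(self, depletion_df):
        d = depletion_df.attrs["pulse_duration"]
        assert 0.0 < d < 0.5
        row0 = depletion_df.set_index("isi").loc[0.0]
        assert row0.fast_of_control < 0.15
        assert row0.slow_of_control > 0.70

    def test_fast_recovers_with_interval(self, depletion_df):
        assert depletion_df.fast_of_control.is_monotonic_increasing
        assert depletion_df.set_index("isi").fast_of_control[60.0] > 0.7

    def test_fast_recovery_costs_the_slow_component(self, depletion_df):
        """The refilled RRP is drawn from the NRP: the slow amplitude
        dips below its immediate post-pulse level at intermediate
        intervals before recovering."""
        s = depletion_df.set_index("isi").slow_of_control
        assert min(s[2.0], s[10.0]) < s[0.0]
        assert s[60.0] > min(s[2.0], s[10.0])


class TestDoubleFlashRecovery:
    def test_spm_recovers_fast_component_at_8s_ppm_does_not(
            self, double_flash_isi8):
        spm_rec = double_flash_isi8["spm"].recovery_fast.iloc[0]
        ppm_rec = double_flash_isi8["ppm"].recovery_fast.iloc[0]
        assert spm_rec > 0.10  # experimental scale: 18 +- 4 %
        assert ppm_rec < 0.05
        assert ppm_rec < spm_rec

    def test_slow_component_recovers_faster_than_fast(self, double_flash_isi8):
        row = double_flash_isi8["spm"].iloc[0]
        assert row.recovery_slow > row.recovery_fast

    def test_long_interval_restores_both_components(self, spm):
        df = sp.double_flash_recovery(spm, [60.0])
        assert df.recovery_fast.iloc[0] > 0.75
        assert df.recovery_slow.iloc[0] > 0.75

    def test_catalyst_rescues_parallel_model(self, double_flash_isi8):
        """Adding the priming catalyst to the SRP->RRP step restores
        Ca2+-accelerated refilling in the parallel model."""
        cat = sp.build_model("ppm-cat")
        rec = sp.double_flash_recovery(cat, [8.0]).recovery_fast.iloc[0]
        assert rec > double_flash_isi8["ppm"].recovery_fast.iloc[0]

    def test_too_short_interval_rejected(self, spm):
        with pytest.raises(ValueError):
            sp.double_flash_recovery(spm, [1e-3])


class TestSytNull:
    def test_unclamped_phenotype(self):
        """Unclamping removes the fast burst and raises spontaneous
        release from 1.7 to 6.9 fF/s."""
        res = sp.syt_null_experiment("unclamped")
        assert round(res.resting_flux, 1) == 6.9
        assert round(res.wt_resting_flux, 1) == 1.7
        assert res.fit.fast_fraction < 0.1
        assert res.fit.A2 > 10  # slow burst persists
        assert res.fit.A3 > 0  # sustained component persists

    def test_destabilized_phenotype(self):
        """RRP destabilization (10x backward priming) leaves only a
        vestigial fast burst, an enlarged slow burst, and reduced
        spontaneous release."""
        res = sp.syt_null_experiment("destabilized")
        assert res.fit.fast_fraction < 0.15
        assert res.resting_flux < res.wt_resting_flux
        assert res.fit.A2 > 100  # large slow burst

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            sp.syt_null_experiment("knockdown")
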
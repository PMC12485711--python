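"""Generator contracts: closed forms, determinism, artifact sharing, behavior."""

import dataclasses

import numpy as np
import pytest

import fiberfeed as ff
from fiberfeed.io import ValidationError

NOISELESS = ff.PhotometryNoiseParams(
    bleach_halflife_ca=None,
    bleach_halflife_iso=None,
    artifact_sd=0.0,
    white_noise_sd=0.0,
)


class TestLatentState:
    def test_null_model_is_zero(self):
        p = ff.StateParams(
            circadian_amplitude=0.0, fast_rise_amplitude=0.0,
            food_fall_amplitude=0.0, transient_amplitude=0.0,
        )
        st = ff.simulate_latent_state(p, "fast", 10.0, 5.0, 0)
        np.testing.assert_allclose(st.s, 0.0, atol=1e-15)

    def test_saturating_exponential_closed_form(self):
        # onset ZT12 (t = 6 h from a ZT6 start); one time constant later the
        # rise reaches 1 - 1/e of its amplitude
        p = ff.StateParams(
            circadian_amplitude=0.0, fast_rise_amplitude=0.8, fast_rise_tau=1.0
        )
        st = ff.simulate_latent_state(p, "fast", 8.0, 10.0, 0)
        i = int(7.0 * 3600 * 10)  # ZT13
        assert st.s[i] == pytest.approx(0.8 * (1 - np.exp(-1.0)), rel=1e-3)

    def test_presets_carry_reported_time_constants(self):
        assert ff.PRESETS["agrp_fast"].fast_rise_tau == pytest.approx(1.78)
        assert ff.PRESETS["sim2_fast"].fast_rise_tau == pytest.approx(0.87)
        assert ff.PRESETS["food_trial"].food_fall_tau == pytest.approx(7.5)

    def test_bad_duration_names_parameter(self):
        with pytest.raises(ValidationError, match="duration"):
            ff.simulate_latent_state(ff.StateParams(), "fast", -1.0, 10.0, 0)

    def test_food_fall_shape(self):
        p = ff.StateParams(circadian_amplitude=0.0, food_fall_amplitude=0.4,
                           food_fall_tau=5.0)
        st = ff.simulate_latent_state(
            p, "food_presentation_trial", 0.2, 10.0, 0, event_time_s=100.0
        )
        i = int((100.0 + 5.0) * 10)  # one time constant after the drop
        assert st.s[i] == pytest.approx(-0.4 * (1 - np.exp(-1.0)), rel=1e-2)


class TestPhotometry:
    def test_noiseless_flat_state_gives_constant_channel(self):
        p = ff.StateParams(circadian_amplitude=0.0, fast_rise_amplitude=0.0)
        st = ff.simulate_latent_state(p, "ad_lib", 0.5, 10.0, 0)
        rec, _ = ff.simulate_photometry(st, NOISELESS, 0)
        np.testing.assert_allclose(rec.f_ca, NOISELESS.baseline_ca, atol=1e-12)
        np.testing.assert_allclose(rec.f_iso, NOISELESS.baseline_iso, atol=1e-12)

    def test_same_seed_identical_output(self):
        st = ff.simulate_latent_state(ff.StateParams(), "fast", 1.0, 10.0, 5)
        rec1, _ = ff.simulate_photometry(st, ff.PhotometryNoiseParams(), 5)
        rec2, _ = ff.simulate_photometry(st, ff.PhotometryNoiseParams(), 5)
        assert rec1.f_ca.tobytes() == rec2.f_ca.tobytes()
        assert rec1.f_iso.tobytes() == rec2.f_iso.tobytes()

    def test_channel_artifact_contract(self):
        # with white noise off, the ca-channel artifact equals
        # artifact_gain_iso^-1 times the iso-channel artifact component
        noise = dataclasses.replace(NOISELESS, artifact_sd=2.0)
        st = ff.simulate_latent_state(ff.StateParams(), "fast", 1.0, 10.0, 9)
        rec, truth = ff.simulate_photometry(st, noise, 9)
        ca_art = rec.f_ca - noise.baseline_ca * (1.0 + st.s)
        iso_art = rec.f_iso - noise.baseline_iso
        np.testing.assert_allclose(ca_art, truth.artifact_trace, atol=1e-10)
        np.testing.assert_allclose(
            ca_art, iso_art / noise.artifact_gain_iso, atol=1e-10
        )

    def test_square_pulse_round_trip_recovery(self):
        # motion_correct + dF/F0 recovers a known square pulse within 10%
        # at 1% white noise
        p = ff.StateParams(circadian_amplitude=0.0, fast_rise_amplitude=0.0)
        st = ff.simulate_latent_state(p, "ad_lib", 0.5, 10.0, 2)
        pulse = ((st.t > 900) & (st.t <= 1200)).astype(float) * 0.2
        st.s = st.s + pulse
        noise = ff.PhotometryNoiseParams(
            bleach_halflife_ca=None, bleach_halflife_iso=None, white_noise_sd=1.0
        )
        rec, _ = ff.simulate_photometry(st, noise, 2)
        corrected = ff.motion_correct(rec)
        dff = ff.compute_dff(corrected, ff.BaselineSpec(0.0, 900.0))
        recovered = np.mean(dff.y[(st.t > 950) & (st.t <= 1150)])
        assert recovered == pytest.approx(0.2, rel=0.1)


class TestOperantSession:
    def test_fr1_pairs_every_adlib_poke_with_a_drop(self):
        log, _ = ff.simulate_operant_session(
            ff.BehaviorParams(), 2.0, 1, condition="ad_lib"
        )
        assert len(log.times("pellet_drop")) == len(log.poke_times())

    def test_fast_covering_whole_session_has_no_drops(self):
        beh = ff.BehaviorParams(fast_window=(6.0, 6.0))  # wraps: full 24 h
        log, _ = ff.simulate_operant_session(beh, 3.0, 1, condition="fast",
                                             start_zt=6.0)
        assert len(log.times("pellet_drop")) == 0
        assert len(log.poke_times()) > 0

    def test_same_seed_identical_log(self):
        a, _ = ff.simulate_operant_session(ff.BehaviorParams(), 2.0, 4)
        b, _ = ff.simulate_operant_session(ff.BehaviorParams(), 2.0, 4)
        assert a.frame.equals(b.frame)

    def test_poisson_dispersion_at_constant_rate(self):
        # counts in disjoint 1-minute intervals across replicates are
        # Poisson: variance/mean within [0.8, 1.2]
        beh = ff.BehaviorParams(adlib_poke_rate_base=1.0, adlib_meal_cluster_rate=0.0)
        counts = []
        for rep in range(500):
            log, _ = ff.simulate_operant_session(
                beh, 10.0 / 60.0, 10_000 + rep, condition="ad_lib"
            )
            pokes = log.poke_times()
            counts.extend(np.histogram(pokes, bins=np.arange(0, 601, 60))[0])
        counts = np.asarray(counts, dtype=float)
        ratio = counts.var() / counts.mean()
        assert 0.8 < ratio < 1.2

    def test_extinction_burst_decays(self):
        # Monte-Carlo check of the intensity law: hour 1 after fast onset is
        # busier than hour 4 whenever burst_rate > 0
        beh = ff.BehaviorParams(burst_rate=3.0, floor_rate=0.2, extinction_tau=1.0)
        h1, h4 = [], []
        for rep in range(200):
            log, _ = ff.simulate_operant_session(
                beh, 11.0, 20_000 + rep, condition="fast", start_zt=6.0
            )
            pokes = log.poke_times()
            onset = 6 * 3600.0
            h1.append(np.sum((pokes >= onset) & (pokes < onset + 3600)))
            h4.append(np.sum((pokes >= onset + 3 * 3600) & (pokes < onset + 4 * 3600)))
        assert np.mean(h1) > np.mean(h4)


class TestFixtureSuite:
    def test_writes_paired_files_deterministically(self, tmp_path):
        dirs = ff.write_fixture_suite(
            tmp_path / "a", seed=1, n_mice=1, long_duration_h=13.0,
            long_sample_rate=1.0,
        )
        assert len(dirs) == 3
        for d in dirs:
            assert (d / "recording.csv").exists()
            assert (d / "events.csv").exists()
            assert (d / "truth.json").exists()
        ff.write_fixture_suite(
            tmp_path / "b", seed=1, n_mice=1, long_duration_h=13.0,
            long_sample_rate=1.0,
        )
        for d in dirs:
            rel = d.relative_to(tmp_path / "a")
            for name in ("recording.csv", "events.csv", "truth.json"):
                assert (d / name).read_bytes() == (
                    tmp_path / "b" / rel / name
                ).read_bytes()
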
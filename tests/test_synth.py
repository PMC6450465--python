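"""Synthetic-movie generator: transient shapes, fields, determinism."""

import numpy as np
import pytest

import cardalt as ca
from cardalt.mapping import AnalysisSettings, BeatWindow, transient_duration
from cardalt.synth import CONDITION_EFFECTS, _shape


class TestMakeTransient:
    def test_zero_amplitude_is_flat_baseline(self):
        tpl = ca.TransientTemplate(baseline=7.0)
        tr = ca.make_transient(tpl, 0.0, 200.0, 1000.0)
        assert np.allclose(tr, 7.0)

    def test_starts_at_baseline_and_peaks_at_amplitude(self):
        tpl = ca.TransientTemplate(time_to_peak=15.0, baseline=2.0)
        tr = ca.make_transient(tpl, 3.0, 200.0, 1000.0)
        assert tr[0] == pytest.approx(2.0)
        assert tr.max() == pytest.approx(5.0, abs=1e-6)
        assert np.argmax(tr) == 15
        assert tr[-1] == pytest.approx(2.0)  # tapered back to baseline

    def test_exponential_decay_closed_form(self):
        # near-instantaneous upstroke, tau 20 ms: peak-to-90%-recovery
        # equals 20 ln 10 ~ 46.05 ms
        tpl = ca.TransientTemplate(time_to_peak=1.0, decay_tau=20.0)
        tr = ca.make_transient(tpl, 1.0, 150.0, 1000.0)
        d, censored = transient_duration(tr, BeatWindow(0, 150, 0), 1000.0)
        assert not censored
        assert d - 1.0 == pytest.approx(20.0 * np.log(10.0), abs=1.0)

    def test_longer_decay_tau_gives_longer_catd(self):
        for lvl in (0.9, 0.8):
            d20 = ca.TransientTemplate(time_to_peak=10, decay_tau=20).catd(lvl)
            d30 = ca.TransientTemplate(time_to_peak=10, decay_tau=30).catd(lvl)
            assert d30 > d20

    @pytest.mark.parametrize("kwargs", [
        dict(beat_amplitude=-1.0), dict(duration=0.0), dict(frame_rate=0.0),
        dict(duration=5.0),  # shorter than time_to_peak
    ])
    def test_invalid_arguments_rejected(self, kwargs):
        args = dict(beat_amplitude=1.0, duration=100.0, frame_rate=1000.0)
        args.update(kwargs)
        with pytest.raises(ValueError):
            ca.make_transient(ca.TransientTemplate(), **args)

    def test_template_invariants_enforced(self):
        with pytest.raises(ValueError):
            ca.TransientTemplate(decay_tau=-1.0)
        with pytest.raises(ValueError):
            ca.TransientTemplate(amplitude=0.0)


class TestFields:
    def test_uniform_field_zones(self):
        mask = ca.make_bz_mask((32, 32), fraction=0.4)
        f = ca.make_uniform_field((32, 32), 0.3, 0.1, mask)
        assert np.all(f.signed_magnitude[mask] == 0.3)
        assert np.all(f.signed_magnitude[~mask] == 0.1)

    def test_discordant_field_sign_structure(self):
        f = ca.make_discordant_field((32, 32), 15.5, 0.3)
        s = f.signed_magnitude
        assert np.all(s[:, 0] < 0) and np.all(s[:, 31] > 0)
        # tapers continuously through zero at the line
        assert np.all(np.abs(s[:, 15:17]) < 0.05)

    def test_discordant_field_curved_line(self):
        f = ca.make_discordant_field((32, 32), lambda r: 10 + 0.3 * r, 0.5)
        assert f.nodal_geometry[0] == pytest.approx(10.0)
        assert f.nodal_geometry[31] == pytest.approx(19.3)

    @pytest.mark.parametrize("peak", [0.0, -0.2, 1.5])
    def test_degenerate_peak_rejected(self, peak):
        with pytest.raises(ValueError):
            ca.make_discordant_field((32, 32), 15.5, peak)

    def test_field_magnitude_bound_enforced(self):
        with pytest.raises(ValueError):
            ca.AlternansField(signed_magnitude=np.full((4, 4), 1.2),
                              bz_mask=np.zeros((4, 4), bool))


class TestSynthesizeMovie:
    def test_default_config_geometry(self, uniform_field):
        cfg = ca.SyntheticProtocolConfig(noise_sd=0.0)
        movie, _ = ca.synthesize_movie(cfg, uniform_field, bcl=100.0)
        assert movie.calcium.shape == (32, 32, 1000)
        assert movie.voltage.shape == (32, 32, 1000)
        assert movie.frame_rate == 1000.0
        assert len(movie.pacing_times) == 10

    def test_no_alternans_means_identical_beats(self):
        cfg = ca.SyntheticProtocolConfig(noise_sd=0.0)
        f = ca.make_uniform_field(cfg.grid, 0.0, 0.0)
        movie, truth = ca.synthesize_movie(cfg, f, bcl=100.0)
        px = movie.calcium[5, 5]
        assert np.allclose(px[:100], px[100:200])
        amap = ca.alternans_map(movie, AnalysisSettings.raw())
        assert np.nanmax(amap.nam) == pytest.approx(0.0, abs=1e-12)

    def test_same_seed_reproduces_bit_for_bit(self, uniform_field):
        cfg = ca.SyntheticProtocolConfig(noise_sd=0.05, seed=42)
        m1, _ = ca.synthesize_movie(cfg, uniform_field, bcl=100.0)
        m2, _ = ca.synthesize_movie(cfg, uniform_field, bcl=100.0)
        assert np.array_equal(m1.calcium, m2.calcium)
        assert np.array_equal(m1.voltage, m2.voltage)

    def test_different_seed_changes_only_noise(self, uniform_field):
        base = dict(noise_sd=0.05)
        m1, _ = ca.synthesize_movie(
            ca.SyntheticProtocolConfig(seed=1, **base), uniform_field, bcl=100.0)
        m2, _ = ca.synthesize_movie(
            ca.SyntheticProtocolConfig(seed=2, **base), uniform_field, bcl=100.0)
        assert not np.array_equal(m1.calcium, m2.calcium)
        diff = m1.calcium - m2.calcium
        # the difference of two same-signal realizations is pure noise
        assert abs(diff.mean()) < 1e-3
        assert diff.std() == pytest.approx(0.05 * np.sqrt(2), rel=0.05)

    def test_parity_shift_flips_phase_only(self, uniform_field, raw_settings):
        cfg = ca.SyntheticProtocolConfig(noise_sd=0.0)
        m0, _ = ca.synthesize_movie(cfg, uniform_field, bcl=100.0, parity=0)
        m1, _ = ca.synthesize_movie(cfg, uniform_field, bcl=100.0, parity=1)
        a0 = ca.alternans_map(m0, raw_settings)
        a1 = ca.alternans_map(m1, raw_settings)
        assert np.allclose(a0.signed, -a1.signed, atol=1e-12)
        assert np.allclose(a0.nam, a1.nam, atol=1e-12)

    def test_bz_pixels_have_longer_catd(self, uniform_field):
        cfg = ca.SyntheticProtocolConfig(noise_sd=0.0)
        movie, truth = ca.synthesize_movie(cfg, uniform_field, bcl=140.0,
                                           bz_decay_factor=1.3)
        bz = uniform_field.bz_mask
        assert np.nanmean(truth["catd90_ms"][bz]) > \
            np.nanmean(truth["catd90_ms"][~bz])
        catd = ca.catd_map(movie, AnalysisSettings.raw())
        assert np.nanmean(catd[bz]) > np.nanmean(catd[~bz])

    def test_norepinephrine_condition_attenuates_alternans(self, uniform_field):
        cfg = ca.SyntheticProtocolConfig(noise_sd=0.0)
        _, t_ctl = ca.synthesize_movie(cfg, uniform_field, bcl=100.0,
                                       condition="control")
        _, t_ne = ca.synthesize_movie(cfg, uniform_field, bcl=100.0,
                                      condition="NE")
        scale = CONDITION_EFFECTS["NE"][0]
        assert np.allclose(t_ne["nam"], scale * t_ctl["nam"])

    def test_grid_mismatch_rejected(self):
        cfg = ca.SyntheticProtocolConfig()
        f = ca.make_uniform_field((8, 8), 0.2, 0.1)
        with pytest.raises(ValueError):
            ca.synthesize_movie(cfg, f, bcl=100.0)


def test_protocol_config_invariants():
    with pytest.raises(ValueError):
        ca.SyntheticProtocolConfig(recorded_duration=11.0)
    with pytest.raises(ValueError):
        ca.SyntheticProtocolConfig(frame_rate=333.3)


def test_transient_shape_has_compact_support():
    # no residue in the pre-stimulus baseline window of the NEXT beat
    tpl = ca.TransientTemplate(decay_tau=30.0)
    t = np.arange(100) * 1.0
    y = _shape(tpl, t, 100.0)
    assert np.all(y[90:] == 0.0)
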
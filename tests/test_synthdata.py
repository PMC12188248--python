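"""Forward simulator: determinism, ground-truth fidelity, container round-trip."""

import h5py
import numpy as np
import pytest

from flyssvep import behavior as beh
from flyssvep import synthdata as sd
from flyssvep.stimgen import TrialType

from conftest import fast_config


class TestConfig:
    def test_reversal_channel_validated(self):
        with pytest.raises(sd.InvalidConfigError):
            sd.SimConfig(reversal_channel=0)
        with pytest.raises(sd.InvalidConfigError):
            sd.SimConfig(reversal_channel=17)

    def test_nonpositive_gain_rejected(self):
        cfg = fast_config()
        bad = dict(cfg.gains)
        bad[("central", "carrier", "wake")] = 0.0
        with pytest.raises(sd.InvalidConfigError):
            sd.SimConfig(gains=bad)

    def test_config_json_round_trip(self):
        cfg = fast_config()
        back = sd.SimConfig.from_json(cfg.to_json())
        assert back == cfg


class TestBehaviorSim:
    def test_single_wake_bout_when_wake_dominates(self, rng):
        cfg = fast_config()
        cfg.bout_model.wake_median_s = 1e7  # first wake bout covers everything
        movement, truth = sd.simulate_behavior(cfg, 600.0, rng)
        assert len(truth.bouts) == 1
        assert truth.bouts.iloc[0].state == "wake"
        assert movement.mean() > 0.5  # active throughout

    def test_bouts_tile_recording(self, rng):
        cfg = fast_config()
        _, truth = sd.simulate_behavior(cfg, 3600.0, rng)
        b = truth.bouts
        assert b.iloc[0].start_s == 0.0
        assert b.iloc[-1].end_s == pytest.approx(3600.0)
        assert np.allclose(b.end_s.to_numpy()[:-1], b.start_s.to_numpy()[1:])
        # states alternate
        states = list(b.state)
        assert all(a != c for a, c in zip(states, states[1:]))

    def test_deep_flag_excludes_bout_edges(self, rng):
        cfg = fast_config()
        _, truth = sd.simulate_behavior(cfg, 3600.0, rng)
        fs = cfg.fs
        sleep = truth.bouts[truth.bouts.state == "sleep"]
        for _, bout in sleep.iterrows():
            i0 = int(bout.start_s * fs)
            assert (truth.states[i0 : i0 + int(60 * fs)] != sd.STATE_DEEP).all()
            mid = int((bout.start_s + bout.end_s) / 2 * fs)
            if bout.end_s - bout.start_s > 180:
                assert truth.states[mid] == sd.STATE_DEEP

    def test_sleep_scoring_recovers_truth_boundaries(self, rng):
        """Round trip: noise-free-movement scoring matches truth to one bin."""
        cfg = fast_config()
        cfg.pe_model.sensor_noise_sd = 0.0
        movement, truth = sd.simulate_behavior(cfg, 2 * 3600.0, rng)
        active = beh.quantify_movement(movement, cfg.fs, bin_s=1.0)
        bouts = beh.score_bouts(active, bin_s=1.0, min_sleep_s=300.0)
        tb = truth.bouts
        got_sleep = [(b.start_s, b.end_s) for b in bouts if b.state == "sleep"]
        want_sleep = [
            (r.start_s, r.end_s) for r in tb.itertuples() if r.state == "sleep"
        ]
        assert len(got_sleep) == len(want_sleep)
        for (gs, ge), (ws, we) in zip(got_sleep, want_sleep):
            assert abs(gs - ws) <= 1.0 and abs(ge - we) <= 1.0

    def test_bout_medians_converge_to_targets(self):
        """Pooled bout-duration medians land within 5% of the configured
        wake 11.2 / sleep 12.8 min targets over hundreds of bouts."""
        cfg = fast_config()
        wake, sleep = [], []
        for seed in range(25):
            _, truth = sd.simulate_behavior(cfg, 6 * 3600.0, np.random.default_rng(seed))
            b = truth.bouts.iloc[:-1]  # last bout is truncated by the recording end
            d = b.end_s - b.start_s
            wake.extend(d[b.state == "wake"])
            sleep.extend(d[b.state == "sleep"])
        assert len(wake) >= 200 and len(sleep) >= 200
        assert np.median(wake) == pytest.approx(11.2 * 60, rel=0.05)
        assert np.median(sleep) == pytest.approx(12.8 * 60, rel=0.05)


class TestProboscisSim:
    def test_zero_rates_give_flat_trace(self, rng):
        cfg = fast_config()
        cfg.pe_model.spell_rate_deep = 0.0
        cfg.pe_model.spell_rate_light_sleep = 0.0
        cfg.pe_model.spell_rate_wake = 0.0
        cfg.pe_model.reach_rate_wake = 0.0
        cfg.pe_model.sensor_noise_sd = 0.0
        _, truth = sd.simulate_behavior(cfg, 1800.0, rng)
        trace = sd.simulate_proboscis(cfg, truth, rng)
        assert not trace.any()
        assert len(truth.pe_events) == 0

    def test_spells_concentrate_in_deep_sleep(self):
        cfg = fast_config()
        deep_spells, wake_spells, deep_min, wake_min = 0, 0, 0.0, 0.0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            _, truth = sd.simulate_behavior(cfg, 2 * 3600.0, rng)
            sd.simulate_proboscis(cfg, truth, rng)
            pe = truth.pe_events
            rhythmic = pe[pe.kind == "rhythmic_extension"]
            spell_starts = rhythmic.groupby("spell_id").start_s.min()
            fs = cfg.fs
            for t in spell_starts:
                code = truth.states[int(t * fs)]
                if code == sd.STATE_DEEP:
                    deep_spells += 1
                elif code == sd.STATE_WAKE:
                    wake_spells += 1
            deep_min += (truth.states == sd.STATE_DEEP).sum() / fs / 60
            wake_min += (truth.states == sd.STATE_WAKE).sum() / fs / 60
        # rate per deep minute far exceeds rate per wake minute
        assert deep_spells / max(deep_min, 1) > 3 * wake_spells / max(wake_min, 1)

    def test_reaches_longer_than_rhythmic_extensions(self, rng):
        cfg = fast_config()
        _, truth = sd.simulate_behavior(cfg, 2 * 3600.0, rng)
        sd.simulate_proboscis(cfg, truth, rng)
        pe = truth.pe_events
        if (pe.kind == "reach").any() and (pe.kind == "rhythmic_extension").any():
            assert (
                pe.loc[pe.kind == "reach", "duration_s"].min()
                > pe.loc[pe.kind == "rhythmic_extension", "duration_s"].max()
            )

    def test_negative_rate_rejected(self):
        cfg = fast_config()
        cfg.pe_model.spell_rate_deep = -1.0
        with pytest.raises(sd.InvalidConfigError):
            sd.SimConfig(fs=200.0, pe_model=cfg.pe_model)


class TestLFPSim:
    def test_same_seed_bitwise_identical(self):
        a = sd.simulate_recording(fast_config(), 60.0, TrialType.PHASIC, seed=5)
        b = sd.simulate_recording(fast_config(), 60.0, TrialType.PHASIC, seed=5)
        assert np.array_equal(a.lfp, b.lfp)
        assert a.events.equals(b.events)

    def test_noise_free_amplitudes_match_truth(self, noise_free_recording):
        """Measured peak-trough equals configured kernel x gain to 1e-6."""
        from flyssvep.ssvep import extract_epochs

        rec = noise_free_recording
        epochs, kept = extract_epochs(rec)
        measured = epochs.max(axis=2) - epochs.min(axis=2)
        truth = rec.truth.amplitudes[kept]
        nz = truth > 1e-12
        assert np.max(np.abs(measured[nz] - truth[nz]) / truth[nz]) < 1e-6
        # reversal channel carries no evoked signal
        rev_col = rec.channel_row(rec.config.reversal_channel)
        assert (truth[:, rev_col] == 0).all()

    def test_polarity_flips_across_reversal(self, phasic_recording):
        """Mean ERPs on opposite sides of the reversal are anticorrelated."""
        from flyssvep.ssvep import extract_epochs

        rec = phasic_recording
        epochs, _ = extract_epochs(rec, channels=[8, 15])
        erp_in = epochs[:, 0].mean(axis=0)
        erp_out = epochs[:, 1].mean(axis=0)
        r = np.corrcoef(erp_in, erp_out)[0, 1]
        assert r < -0.8

    def test_central_deviant_smaller_than_carrier_in_wake(self, noise_free_recording):
        rec = noise_free_recording
        central_col = rec.channel_row(4)  # reversal 12 - 8
        ev = rec.events
        wake = rec.truth.states[
            np.round(ev.onset_time_s.to_numpy() * rec.fs).astype(int)
        ] == sd.STATE_WAKE
        for color in ("green", "blue"):
            dev = (ev.role == "deviant") & (ev.color == color) & wake
            car = (ev.role == "carrier") & (ev.color == color) & wake
            if dev.any() and car.any():
                assert (
                    rec.truth.amplitudes[dev.to_numpy(), central_col].mean()
                    < rec.truth.amplitudes[car.to_numpy(), central_col].mean()
                )


class TestContainerIO:
    def test_lossless_round_trip(self, tmp_path, phasic_recording):
        path = tmp_path / "rec.h5"
        sd.write_recording(phasic_recording, path)
        back = sd.read_recording(path)
        assert np.array_equal(back.lfp, phasic_recording.lfp)
        assert np.array_equal(back.movement, phasic_recording.movement)
        assert back.events.equals(phasic_recording.events)
        assert np.array_equal(back.truth.states, phasic_recording.truth.states)
        assert np.array_equal(back.truth.amplitudes, phasic_recording.truth.amplitudes)
        assert back.config == phasic_recording.config

    def test_missing_truth_loads_as_real_data(self, tmp_path, phasic_recording):
        path = tmp_path / "rec.h5"
        sd.write_recording(phasic_recording, path)
        with h5py.File(path, "a") as f:
            del f["truth"]
        back = sd.read_recording(path)
        assert back.truth is None

    def test_version_mismatch_rejected(self, tmp_path, phasic_recording):
        path = tmp_path / "rec.h5"
        sd.write_recording(phasic_recording, path)
        with h5py.File(path, "a") as f:
            f.attrs["format_version"] = 99
        with pytest.raises(sd.UnsupportedVersionError):
            sd.read_recording(path)

    def test_missing_component_named_in_error(self, tmp_path, phasic_recording):
        path = tmp_path / "rec.h5"
        sd.write_recording(phasic_recording, path)
        with h5py.File(path, "a") as f:
            del f["traces"]
        with pytest.raises(sd.FormatError, match="traces"):
            sd.read_recording(path)
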
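"""Amplitude extraction, normalization/correction identities, history labels,
contrast selection and frequency tagging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flyssvep import ssvep
from flyssvep.behavior import PEEvent, PESpell
from flyssvep.preprocess import assign_regions, preprocess
from flyssvep.synthdata import simulate_recording

from conftest import fast_config


def toy_events(roles, colors=None, trial_id=0):
    n = len(roles)
    colors = colors or ["green"] * n
    return pd.DataFrame(
        {"trial_id": trial_id, "seq_index": np.arange(1, n + 1),
         "onset_time_s": np.arange(n) * 0.1, "duration_s": 0.05,
         "color": colors, "role": roles}
    )


class TestExtractEpochs:
    def test_epoch_counts_and_shape(self, phasic_recording):
        ev = phasic_recording.events
        one_trial = ev[ev.trial_id == 0]
        epochs, kept = ssvep.extract_epochs(
            phasic_recording, one_trial, channels=[4, 9, 15]
        )
        assert epochs.shape == (200, 3, 20)  # 0.1 s at 200 Hz
        assert kept.all()

    def test_window_longer_than_isi_rejected(self, phasic_recording):
        with pytest.raises(ValueError):
            ssvep.extract_epochs(phasic_recording, window_s=(0.0, 0.2))

    def test_events_past_recording_end_dropped(self, phasic_recording):
        ev = phasic_recording.events.copy()
        ev.loc[ev.index[-1], "onset_time_s"] = phasic_recording.duration_s + 1.0
        epochs, kept = ssvep.extract_epochs(phasic_recording, ev)
        assert kept.sum() == len(ev) - 1

    def test_noise_free_epoch_reproduces_kernel(self, noise_free_recording):
        from flyssvep.synthdata import evoked_kernel

        rec = noise_free_recording
        ev = rec.events
        first_green_carrier = ev[(ev.color == "green") & (ev.role == "carrier")].head(1)
        epochs, _ = ssvep.extract_epochs(rec, first_green_carrier, channels=[4])
        kern = evoked_kernel(rec.config.kernel, rec.fs, "green")
        truth_row = rec.truth.amplitudes[first_green_carrier.index[0]]
        scale = truth_row[rec.channel_row(4)] / (kern.max() - kern.min())
        want = np.zeros(epochs.shape[-1])
        want[: len(kern)] = kern * scale
        assert np.allclose(epochs[0, 0], want, atol=1e-6)


class TestAmplitude:
    def test_constant_epoch_zero(self):
        assert ssvep.amplitude(np.full(20, 3.3)) == 0.0

    def test_peak_trough_arithmetic(self):
        assert ssvep.amplitude(np.array([0.0, 3.0, -2.0, 1.0])) == 5.0

    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=50),
        st.floats(-100, 100),
        st.floats(0.01, 100),
    )
    @settings(max_examples=100, deadline=None)
    def test_shift_invariant_and_scale_linear(self, vals, shift, scale):
        x = np.array(vals)
        a = ssvep.amplitude(x)
        assert ssvep.amplitude(x + shift) == pytest.approx(a, abs=1e-6 * max(1, abs(shift)))
        assert ssvep.amplitude(x * scale) == pytest.approx(a * scale, rel=1e-9)


class TestLabelHistory:
    def test_phasic_trial_hand_enumeration(self):
        """10-event oracle: deviant at 5 and 10, carriers renumbered 1-4."""
        roles = ["carrier"] * 4 + ["deviant"] + ["carrier"] * 4 + ["deviant"]
        colors = ["blue"] * 4 + ["green"] + ["blue"] * 4 + ["green"]
        df = ssvep.label_history(toy_events(roles, colors))
        assert pd.isna(df.loc[0, "prev_role"])  # first event: no history
        # carriers before the first deviant carry no order
        assert df.loc[:3, "carrier_order"].isna().all()
        # positions 6-9 are carriers 1-4 after the deviant at 5
        assert list(df.loc[5:8, "carrier_order"]) == [1.0, 2.0, 3.0, 4.0]
        # the deviant at 10 has prev_role carrier and no order
        assert df.loc[9, "prev_role"] == "carrier"
        assert pd.isna(df.loc[9, "carrier_order"])
        assert df.loc[4, "prev_color"] == "blue"

    def test_jittered_gap_of_three_numbers_three_carriers(self):
        roles = ["deviant"] + ["carrier"] * 3 + ["deviant", "carrier"]
        df = ssvep.label_history(toy_events(roles))
        assert list(df.loc[1:3, "carrier_order"]) == [1.0, 2.0, 3.0]
        assert df.loc[5, "carrier_order"] == 1.0

    def test_orders_beyond_four_unlabeled(self):
        roles = ["deviant"] + ["carrier"] * 6
        df = ssvep.label_history(toy_events(roles))
        assert list(df.loc[1:4, "carrier_order"]) == [1.0, 2.0, 3.0, 4.0]
        assert df.loc[5:6, "carrier_order"].isna().all()


def records_from(rows):
    return pd.DataFrame(rows)


class TestNormalization:
    def test_two_amplitude_cell(self):
        df = records_from(
            [{"fly_id": 0, "channel": 4, "color": "green", "amp_raw": 2.0},
             {"fly_id": 0, "channel": 4, "color": "green", "amp_raw": 4.0}]
        )
        out = ssvep.normalize_amplitudes(df)
        assert list(out.amp_norm) == [pytest.approx(2 / 3), pytest.approx(4 / 3)]

    def test_roles_pooled_in_denominator(self):
        """Green deviants and carriers share one normalization mean."""
        df = records_from(
            [{"fly_id": 0, "channel": 4, "color": "green", "role": "carrier", "amp_raw": 3.0},
             {"fly_id": 0, "channel": 4, "color": "green", "role": "deviant", "amp_raw": 1.0}]
        )
        out = ssvep.normalize_amplitudes(df)
        assert list(out.amp_norm) == [1.5, 0.5]  # denominator 2.0 pools both roles

    def test_mean_norm_is_one_per_cell(self, phasic_recording):
        rec, cmap, _ = preprocess(
            __import__("copy").deepcopy(phasic_recording)
        )
        records = ssvep.build_amplitude_records(rec, cmap, fly_id=1)
        out = ssvep.normalize_amplitudes(records)
        cell_means = out.groupby(["fly_id", "channel", "color"]).amp_norm.mean()
        assert np.allclose(cell_means, 1.0)

    def test_zero_mean_rejected(self):
        df = records_from(
            [{"fly_id": 0, "channel": 4, "color": "green", "amp_raw": 0.0}]
        )
        with pytest.raises(ssvep.DegenerateNormalizationError):
            ssvep.normalize_amplitudes(df)


class TestCorrectedAmplitude:
    def groups(self, a_vals, b_vals, fly=0):
        mk = lambda vals: pd.DataFrame(
            {"fly_id": fly, "amp_norm": vals}
        )
        return {"a": mk(a_vals), "b": mk(b_vals)}

    def test_group_means_mirror_around_zero(self):
        out = ssvep.corrected_amplitude(self.groups([0.9], [1.1]))
        m = out.groupby("group").amp_corrected.mean()
        assert m["a"] == pytest.approx(-0.1)
        assert m["b"] == pytest.approx(0.1)

    def test_identical_groups_centered_at_zero(self):
        out = ssvep.corrected_amplitude(self.groups([1.0, 1.0], [1.0, 1.0]))
        assert np.allclose(out.amp_corrected, 0.0)

    def test_fly_missing_a_group_excluded(self):
        groups = {
            "a": pd.DataFrame({"fly_id": [0, 0, 1], "amp_norm": [0.9, 1.1, 2.0]}),
            "b": pd.DataFrame({"fly_id": [0, 0], "amp_norm": [1.0, 1.0]}),
        }
        out = ssvep.corrected_amplitude(groups)
        assert set(out.fly_id) == {0}

    def test_per_fly_group_mean_identity(self):
        rng = np.random.default_rng(0)
        groups = {
            "a": pd.DataFrame({"fly_id": np.repeat([0, 1], 10),
                               "amp_norm": rng.uniform(0.5, 1.5, 20)}),
            "b": pd.DataFrame({"fly_id": np.repeat([0, 1], 7),
                               "amp_norm": rng.uniform(0.5, 1.5, 14)}),
        }
        out = ssvep.corrected_amplitude(groups)
        gm = out.groupby(["fly_id", "group"]).amp_corrected.mean()
        assert np.allclose(gm.groupby("fly_id").mean(), 0.0)


class TestSelectContrast:
    def labeled_records(self):
        roles = ["carrier"] * 4 + ["deviant"] + ["carrier"] * 4 + ["deviant"]
        colors = ["blue"] * 4 + ["green"] + ["blue"] * 4 + ["green"]
        df = ssvep.label_history(toy_events(roles, colors))
        df["fly_id"] = 0
        df["channel"] = 4
        df["region"] = "central"
        df["state"] = "wake"
        df["segment"] = None
        df["pe_context"] = "none"
        df["trial_type"] = "phasic"
        df["amp_raw"] = 1.0
        return df

    def test_carrier_vs_deviant_history_matched(self):
        df = self.labeled_records()
        groups = ssvep.select_contrast(df, "carrier_vs_deviant", color="blue")
        assert list(groups["carrier"].seq_index) == [6]  # blue carrier order 1
        assert len(groups["deviant"]) == 0  # no blue deviants in this toy
        groups_g = ssvep.select_contrast(df, "carrier_vs_deviant", color="green")
        assert list(groups_g["deviant"].seq_index) == [5, 10]

    def test_carrier_order_groups(self):
        df = self.labeled_records()
        groups = ssvep.select_contrast(df, "carrier_order", color="blue")
        assert [list(groups[f"order_{k}"].seq_index) for k in (1, 2, 3, 4)] == [
            [6], [7], [8], [9]
        ]

    def test_unknown_contrast_rejected(self):
        with pytest.raises(ValueError):
            ssvep.select_contrast(self.labeled_records(), "bogus")

    def test_jitter_gap_selects_four_carrier_histories_only(self):
        # jittering trial with gaps 3 and 4: only the gap-4 deviant selected
        roles = (["carrier"] * 4 + ["deviant"] + ["carrier"] * 3 + ["deviant"]
                 + ["carrier"] * 4 + ["deviant"])
        df = ssvep.label_history(toy_events(roles))
        df["fly_id"] = 0
        df["channel"] = 4
        df["region"] = "central"
        df["state"] = "wake"
        df["segment"] = None
        df["pe_context"] = "none"
        df["trial_type"] = "jittering"
        df["amp_raw"] = 1.0
        groups = ssvep.select_contrast(df, "jitter_gap")
        # seq 14 follows carriers 10-13 (orders 1-4); the trial-opening deviant
        # at seq 5 has no preceding deviant to define a gap and is excluded
        assert list(groups["jittering"].seq_index) == [14]
        assert len(groups["phasic"]) == 0


class TestPEContextLabels:
    def test_events_between_spell_extensions_labeled(self, phasic_recording):
        import copy

        rec, cmap, _ = preprocess(copy.deepcopy(phasic_recording))
        spell = PESpell(
            events=[PEEvent(10.0, 0.2, 1.0), PEEvent(13.0, 0.2, 1.0)], state="sleep"
        )
        records = ssvep.build_amplitude_records(rec, cmap, spells=[spell])
        inside = records[(records.trial_id == 0)
                         & (records.seq_index.between(106, 125))]
        # onsets 10.5-12.4 s sit inside the guarded inter-extension window
        assert (inside.pe_context == "in_spell_window_sleep").all()
        outside = records[records.seq_index < 100]
        assert (outside.pe_context == "none").all()


class TestPowerSpectrum:
    def test_phasic_trial_peaks_at_f1_and_f2(self, preprocessed):
        rec, cmap, _ = preprocessed
        spec = ssvep.power_spectrum(rec, channel=cmap.intermediate)
        above = spec[spec.freq_hz >= 0.5]
        assert above.loc[above.power.idxmax(), "freq_hz"] == pytest.approx(10.0)
        band = spec[(spec.freq_hz >= 0.5) & (spec.freq_hz <= 5.0)]
        assert band.loc[band.power.idxmax(), "freq_hz"] == pytest.approx(2.0)
        # resolution fine enough to separate 2 Hz from neighbours
        assert np.diff(spec.freq_hz.to_numpy()[:2])[0] <= 0.25

    def test_carrier_only_trial_lacks_2hz_line(self):
        rec = simulate_recording(fast_config(), 10 * 23.0, "carrier_only", seed=21)
        spec = ssvep.power_spectrum(rec, channel=9)
        p2 = float(spec.loc[np.isclose(spec.freq_hz, 2.0), "power"].iloc[0])
        neighbours = spec[(spec.freq_hz >= 1.5) & (spec.freq_hz <= 2.5)
                          & ~np.isclose(spec.freq_hz, 2.0)]
        # 2 Hz is not a peak above the local 1/f background
        assert p2 < 2.0 * neighbours.power.mean()

    def test_short_selection_rejected(self, phasic_recording):
        with pytest.raises(ValueError):
            ssvep.power_spectrum(phasic_recording, trial_ids=[9999], channel=9)


class TestAverageERP:
    def test_identical_epochs_average_to_member(self):
        ep = np.tile(np.sin(np.linspace(0, 1, 20)), (5, 1))
        mean, counts = ssvep.average_erp(ep, np.zeros(5))
        assert np.allclose(mean, ep[0])
        assert counts.iloc[0] == 5

    def test_opposite_polarity_epochs_cancel(self):
        k = np.hanning(20)
        ep = np.vstack([k, -k])
        mean, _ = ssvep.average_erp(ep, np.array([0, 1]))
        assert np.allclose(mean, 0.0)

    def test_carrier_erp_state_invariant_on_simulation(self):
        """Wake and sleep carrier ERPs match (carrier gains are state-free)."""
        import copy

        from flyssvep import behavior as beh
        from flyssvep.synthdata import STATE_WAKE

        cfg = fast_config()
        rec = simulate_recording(cfg, 40 * 60.0, "phasic", seed=31)
        ev = rec.events
        states = rec.truth.states[np.round(ev.onset_time_s * rec.fs).astype(int)]
        carriers = (ev.role == "carrier").to_numpy()
        epochs, kept = ssvep.extract_epochs(rec, ev, channels=[4])
        states, carriers = states[kept], carriers[kept]
        wake = epochs[carriers & (states == STATE_WAKE), 0].mean(axis=0)
        sleep = epochs[carriers & (states != STATE_WAKE), 0].mean(axis=0)
        a_w, a_s = ssvep.amplitude(wake), ssvep.amplitude(sleep)
        assert abs(a_w - a_s) / a_w < 0.1
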
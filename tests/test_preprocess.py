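import numpy as np
import pandas as pd
import pytest
from scipy import signal

from tripletmmn import preprocess, synth_eeg
from tripletmmn.synth_eeg import ErpGroundTruth, NoiseSpec, RawRecording


def make_rec(montage, data, events=None, presses=None, ref="as_recorded"):
    n_ch = len(montage.channels)
    assert data.shape[0] == n_ch
    if events is None:
        events = pd.DataFrame(
            dict(onset_ms=[0.0], sample=[0], block=[1], triplet_index=[0],
                 position=["ending"], sound=["E"], side=["left"],
                 category=["standard"], is_target=[False])
        )
    if presses is None:
        presses = pd.DataFrame(columns=["press_time_ms", "target_onset_ms"])
    return RawRecording(data, montage, events, presses, ref)


def ending_events(onsets_ms, categories=None, targets=(), fs=500.0):
    """Annotation table of ending stimuli (plus optional target sounds)."""
    categories = categories or ["standard"] * len(onsets_ms)
    rows = [
        dict(onset_ms=t, sample=int(round(t * fs / 1000.0)), block=1,
             triplet_index=i, position="ending", sound="E", side="left",
             category=c, is_target=False)
        for i, (t, c) in enumerate(zip(onsets_ms, categories))
    ]
    rows += [
        dict(onset_ms=t, sample=int(round(t * fs / 1000.0)), block=1,
             triplet_index=-1, position="target", sound="TARGET", side="both",
             category="target", is_target=True)
        for t in targets
    ]
    return pd.DataFrame(sorted(rows, key=lambda r: r["onset_ms"])).reset_index(drop=True)


class TestLowpass:
    def test_designed_response(self):
        h = preprocess.design_lowpass()
        w, resp = signal.freqz(h, worN=8192, fs=500.0)
        mag_db = 20 * np.log10(np.abs(resp) + 1e-300)
        assert mag_db[w >= 60.0].max() < -40.0
        passband = mag_db[w <= 25.0]
        assert passband.max() < 0.5 and passband.min() > -0.5

    def test_passband_and_stopband_on_signals(self, montage):
        fs = 500.0
        t = np.arange(int(20 * fs)) / fs
        n_ch = len(montage.channels)
        data = np.zeros((n_ch, len(t)), dtype=np.float32)
        data[0] = np.sin(2 * np.pi * 10 * t)  # passband
        data[1] = np.sin(2 * np.pi * 100 * t)  # stopband
        data[2] = 3.0  # DC
        rec = make_rec(montage, data)
        out = preprocess.lowpass_fir(rec)
        mid = slice(4000, 6000)
        assert np.abs(out.data[0, mid]).max() == pytest.approx(1.0, rel=0.01)
        assert np.abs(out.data[1, mid]).max() < 0.01  # > 40 dB down
        assert out.data[2, mid] == pytest.approx(3.0, rel=0.01)

    def test_record_shorter_than_filter_rejected(self, montage):
        data = np.zeros((len(montage.channels), 1000), dtype=np.float32)
        with pytest.raises(ValueError, match="shorter"):
            preprocess.lowpass_fir(make_rec(montage, data))


class TestRereference:
    def test_constant_mastoid_difference_shifts_all_channels(self, montage):
        n_ch = len(montage.channels)
        data = np.zeros((n_ch, 100), dtype=np.float32)
        data[montage.index("M2")] = 2.0  # recorded M2 − M1 = 2 µV
        out = preprocess.rereference_mastoid_mean(make_rec(montage, data))
        assert out.reference_state == "mastoid_mean"
        np.testing.assert_allclose(out.data[montage.index("FZ")], -1.0)
        np.testing.assert_allclose(out.data[montage.index("M2")], 1.0)

    def test_zero_mastoids_identity(self, montage):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(len(montage.channels), 50)).astype(np.float32)
        data[montage.index("M2")] = 0.0
        out = preprocess.rereference_mastoid_mean(make_rec(montage, data))
        np.testing.assert_array_equal(out.data, data)

    def test_double_rereference_guarded(self, montage):
        data = np.zeros((len(montage.channels), 50), dtype=np.float32)
        out = preprocess.rereference_mastoid_mean(make_rec(montage, data))
        with pytest.raises(ValueError, match="already"):
            preprocess.rereference_mastoid_mean(out)


class TestGlidingWindowRejection:
    def _direct_mask(self, data, fs, threshold, windows_ms):
        """Independent oracle: explicit SD per window position."""
        n = data.shape[1]
        mask = np.zeros(n, dtype=bool)
        for wms in windows_ms:
            w = int(round(wms * fs / 1000.0))
            for start in range(0, n - w + 1):
                seg = data[:, start : start + w]
                if np.std(seg, axis=1, ddof=1).max() > threshold:
                    mask[start : start + w] = True
        return mask

    def test_matches_direct_computation_on_spike_fixture(self, montage):
        rng = np.random.default_rng(4)
        n_ch = len(montage.channels)
        data = rng.normal(0, 3, size=(n_ch, 3000)).astype(np.float32)
        data[5, 1500:1520] += 200.0  # blink-like spike on one channel
        data[monindex := montage.index("VEOG_UP"), 700:760] += 120.0
        rec = make_rec(montage, data)
        got = preprocess.gliding_window_reject(rec, 25.0, (200.0, 800.0))
        want = self._direct_mask(data, 500.0, 25.0, (200.0, 800.0))
        np.testing.assert_array_equal(got, want)
        assert got[1500] and got[1519]  # spike samples rejected
        assert not got.all()

    def test_all_zero_record_empty_mask(self, montage):
        data = np.zeros((len(montage.channels), 2000), dtype=np.float32)
        assert not preprocess.gliding_window_reject(make_rec(montage, data)).any()

    def test_threshold_endpoints(self, montage):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(len(montage.channels), 2000)).astype(np.float32)
        rec = make_rec(montage, data)
        assert not preprocess.gliding_window_reject(rec, np.inf).any()
        assert preprocess.gliding_window_reject(rec, 0.0).all()

    def test_monotone_in_threshold(self, montage):
        rng = np.random.default_rng(2)
        data = rng.normal(0, 10, size=(len(montage.channels), 4000)).astype(np.float32)
        data[3, 2000:2050] += 150.0
        rec = make_rec(montage, data)
        loose = preprocess.gliding_window_reject(rec, 40.0)
        tight = preprocess.gliding_window_reject(rec, 20.0)
        assert (tight | loose == tight).all()  # lower threshold ⇒ superset

    def test_invariant_under_channel_permutation(self, montage, rng):
        data = rng.normal(0, 5, size=(len(montage.channels), 2500)).astype(np.float32)
        data[7, 1000:1040] += 300.0
        rec = make_rec(montage, data)
        perm = rng.permutation(data.shape[0])
        rec_p = make_rec(montage, data[perm])
        np.testing.assert_array_equal(
            preprocess.gliding_window_reject(rec),
            preprocess.gliding_window_reject(rec_p),
        )


class TestEpochExtraction:
    def test_press_within_three_seconds_excluded(self, montage):
        ev = ending_events([5000.0, 9000.0])
        presses = pd.DataFrame({"press_time_ms": [2100.0], "target_onset_ms": [np.nan]})
        data = np.zeros((len(montage.channels), 6000), dtype=np.float32)
        rec = make_rec(montage, data, ev, presses)
        ep = preprocess.extract_epochs(rec, np.zeros(6000, dtype=bool))
        # first ending is 2.9 s after the press → excluded; second survives
        assert ep.exclusions["after_target_or_press"] == 1
        assert ep.exclusions["included"] == 1

    def test_target_sound_triggers_exclusion(self, montage):
        ev = ending_events([5000.0, 9500.0], targets=[4000.0])
        data = np.zeros((len(montage.channels), 6000), dtype=np.float32)
        rec = make_rec(montage, data, ev)
        ep = preprocess.extract_epochs(rec, np.zeros(6000, dtype=bool))
        assert ep.exclusions["after_target_or_press"] == 1  # 1 s after target
        assert ep.exclusions["included"] == 1

    def test_adjacent_trigger_rule(self, montage):
        # neighbours at 210 ms before and 250 ms after → included;
        # neighbour at 150 ms → excluded
        ev = ending_events([4790.0, 5000.0, 5250.0, 9000.0, 9150.0])
        data = np.zeros((len(montage.channels), 6000), dtype=np.float32)
        rec = make_rec(montage, data, ev)
        ep = preprocess.extract_epochs(rec, np.zeros(6000, dtype=bool))
        assert ep.exclusions["adjacent"] == 2  # the 9000/9150 pair kills both
        assert ep.exclusions["included"] == 3

    def test_artifact_overlap_excluded_and_precedence(self, montage):
        ev = ending_events([5000.0, 9000.0])
        data = np.zeros((len(montage.channels), 6000), dtype=np.float32)
        mask = np.zeros(6000, dtype=bool)
        mask[2500:2520] = True  # overlaps the first epoch window only
        rec = make_rec(montage, data, ev)
        ep = preprocess.extract_epochs(rec, mask)
        assert ep.exclusions == {
            "included": 1, "after_target_or_press": 0, "adjacent": 0, "artifact": 1,
        }

    def test_baseline_zero_and_bookkeeping(self, montage, rng):
        onsets = [3000.0 + 600.0 * k for k in range(8)]
        cats = ["standard", "stat_deviant"] * 4
        ev = ending_events(onsets, cats)
        data = rng.normal(0, 5, size=(len(montage.channels), 5000)).astype(np.float32)
        rec = make_rec(montage, data, ev)
        mask = np.zeros(5000, dtype=bool)
        ep = preprocess.extract_epochs(rec, mask)
        assert sum(ep.exclusions.values()) == len(onsets)
        base = ep.data[:, :, :50].mean(axis=2)
        np.testing.assert_allclose(base, 0.0, atol=1e-9)
        assert ep.data.shape[2] == 250  # [−100, 400) ms at 2 ms

    def test_widened_exclusion_categories(self, montage):
        # location deviants may optionally trigger the 3 s rule; the
        # triggering event never excludes itself
        ev = ending_events([5000.0, 7000.0], ["phys_deviant", "standard"])
        data = np.zeros((len(montage.channels), 6000), dtype=np.float32)
        rec = make_rec(montage, data, ev)
        default = preprocess.extract_epochs(rec, np.zeros(6000, dtype=bool))
        assert default.exclusions["included"] == 2
        widened = preprocess.extract_epochs(
            rec, np.zeros(6000, dtype=bool),
            exclude_after_categories=("target", "phys_deviant", "double_deviant"),
        )
        assert widened.exclusions == {
            "included": 1, "after_target_or_press": 1, "adjacent": 0, "artifact": 0,
        }

    def test_warns_when_condition_empty(self, montage):
        ev = ending_events([5000.0], ["double_deviant"])
        data = np.zeros((len(montage.channels), 6000), dtype=np.float32)
        rec = make_rec(montage, data, ev)
        with pytest.warns(UserWarning, match="no surviving epochs"):
            preprocess.extract_epochs(rec, np.ones(6000, dtype=bool))


class TestRoiWaveforms:
    def _epochs(self, montage, data, cats):
        info = pd.DataFrame(
            dict(category=cats, block=[1] * len(cats),
                 block_group=[1] * len(cats), onset_ms=np.arange(len(cats)) * 1000.0)
        )
        return preprocess.EpochSet(data, info, montage)

    def test_single_channel_contribution(self, montage):
        n_ch = len(montage.channels)
        data = np.zeros((1, n_ch, 250))
        data[0, montage.channels.index("F3"), :] = 1.0
        ep = self._epochs(montage, data, ["standard"])
        wf = preprocess.roi_waveforms(ep)
        fl = wf.loc[("standard", 1, "frontal_left")]
        np.testing.assert_allclose(fl.to_numpy(), 1.0 / 6.0)
        fm = wf.loc[("standard", 1, "frontal_middle")]
        np.testing.assert_allclose(fm.to_numpy(), 0.0)

    def test_single_epoch_equals_roi_mean(self, montage, rng):
        n_ch = len(montage.channels)
        data = rng.normal(size=(1, n_ch, 250))
        ep = self._epochs(montage, data, ["standard"])
        wf = preprocess.roi_waveforms(ep)
        sel = [montage.channels.index(c) for c in montage.roi_map["central_middle"]]
        np.testing.assert_allclose(
            wf.loc[("standard", 1, "central_middle")].to_numpy(),
            data[0, sel].mean(axis=0),
        )

    def test_missing_electrode_named(self, montage, rng):
        data = rng.normal(size=(2, len(montage.channels), 250))
        ep = self._epochs(montage, data, ["standard", "standard"])
        import dataclasses
        bad_map = dict(montage.roi_map)
        bad_map["frontal_left"] = ("F99",) + bad_map["frontal_left"][1:]
        bad_montage = dataclasses.replace(
            montage,
            scalp_channels=tuple(
                ch if ch != "F7" else "F99" for ch in montage.scalp_channels
            ),
            roi_map=bad_map,
        )
        with pytest.raises(KeyError, match="F99"):
            preprocess.roi_waveforms(ep, montage=bad_montage)


class TestBadChannelScreen:
    def test_flags_flat_and_outlier_channels(self, montage, rng):
        data = rng.normal(0, 5, size=(len(montage.channels), 2000)).astype(np.float32)
        data[montage.index("C3")] = 0.0
        data[montage.index("PZ")] *= 50.0
        rec = make_rec(montage, data)
        bad = preprocess.screen_bad_channels(rec)
        assert set(bad) == {"C3", "PZ"}
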
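import numpy as np
import pytest

from eegmci import (
    CANONICAL_CHANNELS,
    EEGRecording,
    Label,
    ShortRecordingWarning,
    bandpass_filter,
    read_eeg,
    segment,
    write_csv,
)

from conftest import make_recording


class TestEEGRecording:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="finite"):
            EEGRecording(np.full((2, 10), np.nan), 128.0, ("Fp1", "Fp2"))
        with pytest.raises(ValueError, match="unique"):
            EEGRecording(np.zeros((2, 10)), 128.0, ("Fp1", "Fp1"))
        with pytest.raises(ValueError, match="positive"):
            EEGRecording(np.zeros((1, 10)), -1.0, ("Fp1",))
        with pytest.raises(ValueError, match="labels"):
            EEGRecording(np.zeros((2, 10)), 128.0, ("Fp1",))

    def test_channel_lookup_and_reorder(self, rng):
        rec = make_recording(rng.standard_normal((19, 32)))
        scrambled = rec.reordered(tuple(reversed(CANONICAL_CHANNELS)))
        restored = scrambled.reordered()
        assert restored.channels == CANONICAL_CHANNELS
        np.testing.assert_array_equal(restored.data, rec.data)
        np.testing.assert_array_equal(rec.channel("Cz"), rec.data[9])


class TestReadEEG:
    def test_csv_roundtrip_and_shape(self, tmp_path, rng):
        rec = make_recording(rng.standard_normal((19, 256)), fs=256.0)
        path = write_csv(rec, tmp_path / "rec.csv")
        back = read_eeg(path, fs=256.0)
        assert back.data.shape == (19, 256)
        assert back.duration == pytest.approx(1.0)
        np.testing.assert_allclose(back.data, rec.data, atol=1e-9)

    def test_scrambled_columns_canonicalised(self, tmp_path, rng):
        rec = make_recording(rng.standard_normal((19, 64)))
        scrambled = rec.reordered(tuple(reversed(CANONICAL_CHANNELS)))
        path = write_csv(scrambled, tmp_path / "scr.csv")
        back = read_eeg(path, fs=128.0)
        assert back.channels == CANONICAL_CHANNELS
        np.testing.assert_allclose(back.data, rec.data, atol=1e-9)

    def test_error_cases(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("Fp1,Fp2\n1.0,oops\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_eeg(bad, fs=128.0)
        ok = tmp_path / "ok.csv"
        ok.write_text("Fp1,Fp2\n1.0,2.0\n3.0,4.0\n")
        with pytest.raises(ValueError, match="fs"):
            read_eeg(ok)
        with pytest.raises(FileNotFoundError):
            read_eeg(tmp_path / "absent.csv", fs=128.0)


def _write_minimal_edf(path, data, fs):
    """Hand-rolled single-record EDF writer (test helper only)."""
    n_ch, n_samp = data.shape
    header = "0".ljust(8) + "X".ljust(80) + "X".ljust(80)
    header += "01.01.00" + "00.00.00"
    header += str(256 * (1 + n_ch)).ljust(8) + "".ljust(44)
    header += "1".ljust(8) + str(n_samp / fs).ljust(8) + str(n_ch).ljust(4)
    labels = [f"ch{i}" for i in range(n_ch)]
    header += "".join(lab.ljust(16) for lab in labels)
    header += "".ljust(80 * n_ch)
    header += "".join("uV".ljust(8) for _ in range(n_ch))
    header += "".join("-1000".ljust(8) for _ in range(n_ch))
    header += "".join("1000".ljust(8) for _ in range(n_ch))
    header += "".join("-32768".ljust(8) for _ in range(n_ch))
    header += "".join("32767".ljust(8) for _ in range(n_ch))
    header += "".ljust(80 * n_ch)
    header += "".join(str(n_samp).ljust(8) for _ in range(n_ch))
    header += "".ljust(32 * n_ch)
    scale = 65535 / 2000  # digital span over physical span
    dig = np.round((data + 1000) * scale - 32768).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(dig.tobytes())


def test_edf_reading_recovers_microvolt_amplitudes(tmp_path, rng):
    data = rng.uniform(-100, 100, (2, 128))
    path = tmp_path / "tiny.edf"
    _write_minimal_edf(path, data, fs=128.0)
    rec = read_eeg(path)
    assert rec.fs == 128.0
    assert rec.data.shape == (2, 128)
    # EDF stores 16-bit integers; agreement is limited by quantization
    np.testing.assert_allclose(rec.data, data, atol=0.05)


class TestBandpassFilter:
    # the 0.5 Hz high-pass edge rings for seconds, so steady-state checks
    # (the designed magnitude response) are made away from the boundaries
    MID = slice(4 * 256, -4 * 256)

    def _sine(self, freq, fs=256.0, dur=16.0):
        t = np.arange(int(dur * fs)) / fs
        return make_recording(np.sin(2 * np.pi * freq * t)[None, :], fs=fs)

    def test_inband_tone_preserved(self):
        rec = self._sine(10.0)
        out = bandpass_filter(rec)
        rms_in = np.sqrt(np.mean(rec.data[:, self.MID] ** 2))
        rms_out = np.sqrt(np.mean(out.data[:, self.MID] ** 2))
        assert abs(rms_out - rms_in) / rms_in < 0.05

    def test_outofband_tone_suppressed(self):
        rec = self._sine(60.0)
        out = bandpass_filter(rec)
        rms_in = np.sqrt(np.mean(rec.data[:, self.MID] ** 2))
        assert np.sqrt(np.mean(out.data[:, self.MID] ** 2)) < 0.1 * rms_in

    def test_zero_in_zero_out(self):
        rec = make_recording(np.zeros((3, 1024)), fs=256.0)
        out = bandpass_filter(rec)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_idempotent_on_passband_signal(self):
        rec = self._sine(10.0)
        once = bandpass_filter(rec)
        twice = bandpass_filter(once)
        np.testing.assert_allclose(
            twice.data[:, self.MID], once.data[:, self.MID], atol=0.01
        )

    def test_invalid_cutoffs(self):
        rec = self._sine(10.0, fs=64.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(rec, hi=32.0)
        short = make_recording(np.zeros((1, 10)), fs=256.0)
        with pytest.raises(ValueError, match="warm-up"):
            bandpass_filter(short)


class TestSegment:
    def test_nonoverlapping_window_arithmetic(self, rng):
        rec = make_recording(
            rng.standard_normal((2, 120 * 256)), fs=256.0, label=Label.MCI
        )
        segs = segment(rec, 60.0)
        assert len(segs) == 2
        assert all(s.n_samples == 15360 for s in segs)
        assert all(s.label == Label.MCI and s.subject_id == "s0" for s in segs)

    def test_partial_tail_discarded_and_concat_identity(self, rng):
        rec = make_recording(rng.standard_normal((2, 90 * 256)), fs=256.0)
        segs = segment(rec, 60.0)
        assert len(segs) == 1
        joined = np.concatenate([s.data for s in segs], axis=1)
        np.testing.assert_array_equal(joined, rec.data[:, : joined.shape[1]])

    def test_too_short_warns_and_returns_empty(self, rng):
        rec = make_recording(rng.standard_normal((2, 59 * 256)), fs=256.0)
        with pytest.warns(ShortRecordingWarning):
            assert segment(rec, 60.0) == []

    def test_invalid_window(self, one_segment):
        with pytest.raises(ValueError):
            segment(one_segment, 0.0)
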
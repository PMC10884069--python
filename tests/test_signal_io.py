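"""File round trips, montage references, zero-phase filters, resampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from covmap import (ChannelInfo, FormatError, InvalidMontageError, Recording,
                    bandpass, bipolar_montage, common_average, lowpass, notch,
                    read_recording, resample, write_recording)
from covmap._edf import quantization_step
from covmap.signal_io import read_channel_table, write_channel_table


def _rec(data, sfreq=500.0, kind="scalp", group="scalp"):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    chans = [ChannelInfo(f"ch{i}", kind, group) for i in range(data.shape[0])]
    return Recording(data, sfreq, chans)


class TestEdfRoundTrip:
    def test_write_read_preserves_data_within_quantization(self, tmp_path):
        rng = np.random.default_rng(1)
        rec = _rec(rng.normal(0, 30, (4, 10240)), sfreq=1024.0)
        path = tmp_path / "r.edf"
        write_recording(rec, path)
        back = read_recording(path)
        assert back.sfreq == 1024.0
        assert back.ch_names == rec.ch_names
        assert back.n_samples == rec.n_samples
        step = quantization_step(rec.data).max()
        assert np.abs(back.data - rec.data).max() < step

    def test_malformed_edf_raises_format_error(self, tmp_path):
        bad = tmp_path / "bad.edf"
        bad.write_bytes(b"this is not an edf header")
        with pytest.raises(FormatError):
            read_recording(bad)

    def test_missing_file_raises_format_error(self, tmp_path):
        with pytest.raises(FormatError):
            read_recording(tmp_path / "absent.vhdr")

    def test_channel_table_round_trip(self, tmp_path):
        chans = [ChannelInfo("g1", "grid", "GA", "STG"),
                 ChannelInfo("d1", "depth", "DH"),
                 ChannelInfo("Fz", "scalp")]
        path = tmp_path / "channels.tsv"
        write_channel_table(chans, path)
        assert read_channel_table(path) == chans


class TestBrainVision:
    def _write_triplet(self, tmp_path, data, sfreq):
        n_ch, n_samp = data.shape
        vhdr = tmp_path / "t.vhdr"
        lines = [
            "Brain Vision Data Exchange Header File Version 1.0",
            "[Common Infos]", "DataFile=t.eeg", "MarkerFile=t.vmrk",
            "DataFormat=BINARY", "DataOrientation=MULTIPLEXED",
            f"NumberOfChannels={n_ch}",
            f"SamplingInterval={1e6 / sfreq:.0f}",
            "[Binary Infos]", "BinaryFormat=IEEE_FLOAT_32",
            "[Channel Infos]",
        ] + [f"Ch{i + 1}=c{i + 1},,1,µV" for i in range(n_ch)]
        vhdr.write_text("\n".join(lines), encoding="latin-1")
        (tmp_path / "t.vmrk").write_text(
            "Brain Vision Data Exchange Marker File, Version 1.0\n"
            "[Common Infos]\nDataFile=t.eeg\n[Marker Infos]\n"
            "Mk1=New Segment,,1,1,0,20000101000000000000\n",
            encoding="latin-1")
        data.astype("<f4").T.tofile(tmp_path / "t.eeg")
        return vhdr

    def test_reads_float_triplet(self, tmp_path):
        rng = np.random.default_rng(2)
        data = rng.normal(0, 10, (2, 512))
        vhdr = self._write_triplet(tmp_path, data, 500.0)
        rec = read_recording(vhdr)
        assert rec.sfreq == 500.0
        np.testing.assert_allclose(rec.data, data, atol=1e-3)

    def test_missing_data_file_raises_format_error(self, tmp_path):
        vhdr = self._write_triplet(tmp_path, np.zeros((2, 16)), 500.0)
        (tmp_path / "t.eeg").unlink()
        with pytest.raises(FormatError):
            read_recording(vhdr)


class TestMontages:
    def test_common_average_zeroes_group_means(self):
        rng = np.random.default_rng(3)
        data = rng.normal(0, 5, (6, 100))
        data[:3] += 10.0
        data[3:] -= 10.0
        chans = ([ChannelInfo(f"a{i}", "grid", "A") for i in range(3)]
                 + [ChannelInfo(f"b{i}", "grid", "B") for i in range(3)])
        rec = Recording(data, 500.0, chans)
        out = common_average(rec, within_group=True)
        np.testing.assert_allclose(out.data[:3].mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.data[3:].mean(axis=0), 0.0, atol=1e-12)
        # the two groups are referenced independently
        np.testing.assert_allclose(
            out.data[:3], data[:3] - data[:3].mean(axis=0), atol=1e-12)

    def test_common_average_is_idempotent(self, small_recording):
        once = common_average(small_recording)
        twice = common_average(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)

    def test_singleton_group_rejected(self):
        rec = Recording(np.zeros((1, 10)), 500.0, [ChannelInfo("a", "grid", "A")])
        with pytest.raises(InvalidMontageError):
            common_average(rec, within_group=True)

    def test_bipolar_ten_contacts_give_nine_channels(self):
        rng = np.random.default_rng(4)
        rec = _rec(rng.normal(size=(10, 50)), kind="depth", group="DH")
        out = bipolar_montage(rec, "DH")
        assert out.n_channels == 9
        assert out.ch_names[0] == "ch0-ch1"

    def test_bipolar_values_are_neighbor_differences(self):
        data = np.array([[3.0], [1.0], [0.0]])
        rec = _rec(data, kind="depth", group="DH")
        out = bipolar_montage(rec, "DH")
        np.testing.assert_allclose(out.data[:, 0], [2.0, 1.0])

    def test_bipolar_identical_signals_cancel(self):
        rec = _rec(np.ones((2, 40)), kind="strip", group="S")
        assert np.all(bipolar_montage(rec, "S").data == 0.0)

    def test_bipolar_single_channel_rejected(self):
        rec = _rec(np.zeros((1, 10)), kind="strip", group="S")
        with pytest.raises(InvalidMontageError):
            bipolar_montage(rec, "S")

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**32 - 1), st.floats(-3, 3), st.floats(-3, 3))
    def test_common_average_is_linear(self, data_seed, a, b):
        rng = np.random.default_rng(data_seed)
        x, y = rng.normal(size=(2, 3, 40))
        lhs = common_average(_rec(a * x + b * y)).data
        rhs = a * common_average(_rec(x)).data + b * common_average(_rec(y)).data
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)


class TestFilters:
    def test_notch_removes_line_frequency(self):
        t = np.arange(5000) / 500.0
        rec = _rec(np.sin(2 * np.pi * 50.0 * t))
        out = notch(rec, 50.0)
        # fit the residual 50 Hz amplitude away from the filter edges
        mid = slice(1000, 4000)
        basis = np.column_stack([np.sin(2 * np.pi * 50 * t[mid]),
                                 np.cos(2 * np.pi * 50 * t[mid])])
        coef, *_ = np.linalg.lstsq(basis, out.data[0, mid], rcond=None)
        assert np.hypot(*coef) < 0.05

    def test_bandpass_kills_dc(self):
        rec = _rec(np.full(4000, 7.0))
        out = bandpass(rec, 2.0, 20.0)
        assert np.abs(out.data).max() < 1e-6

    def test_filters_are_zero_phase(self):
        t = np.arange(4000) / 500.0
        x = np.sin(2 * np.pi * 10.0 * t)
        out = bandpass(_rec(x), 2.0, 20.0).data[0]
        lags = np.arange(-25, 26)
        xc = [np.dot(out[1000:3000], x[1000 + l:3000 + l]) for l in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_lowpass_preserves_mean(self):
        rec = _rec(np.full(2000, 3.0))
        np.testing.assert_allclose(lowpass(rec, 10.0).data, 3.0, atol=1e-6)

    def test_cutoff_above_nyquist_rejected(self, small_recording):
        with pytest.raises(ValueError):
            bandpass(small_recording, 2.0, 300.0)
        with pytest.raises(ValueError):
            lowpass(small_recording, 256.0)

    def test_resample_sample_count_and_duration(self):
        rng = np.random.default_rng(5)
        rec = _rec(rng.normal(size=(2, 10240)), sfreq=1024.0)
        out = resample(rec, 500.0)
        assert out.n_samples == round(10240 * 500 / 1024)
        assert abs(out.duration - rec.duration) <= 1.0 / 500.0

    def test_resample_preserves_slow_content(self):
        t = np.arange(10240) / 1024.0
        rec = _rec(np.sin(2 * np.pi * 5.0 * t), sfreq=1024.0)
        out = resample(rec, 500.0)
        expected = np.sin(2 * np.pi * 5.0 * np.arange(out.n_samples) / 500.0)
        mid = slice(100, -100)
        assert np.abs(out.data[0, mid] - expected[mid]).max() < 0.01
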
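"""Record reading, segmentation and annotation-based labeling."""

import struct

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gasfnet.signal_io import (
    DataError,
    ECGRecord,
    Segment,
    label_segments,
    read_csv_record,
    read_wfdb_record,
    segment_record,
    write_csv_record,
)


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

class TestCsv:
    def test_minimal_file(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("0.1\n0.2\n")
        rec = read_csv_record(p, fs=360)
        assert len(rec) == 2 and rec.fs == 360
        np.testing.assert_allclose(rec.samples, [0.1, 0.2])

    def test_duration_is_samples_over_fs(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("\n".join(str(i * 0.001) for i in range(3600)))
        rec = read_csv_record(p, fs=360)
        assert rec.duration_s == pytest.approx(10.0)

    def test_round_trip_preserves_values(self, tmp_path, rng):
        rec = ECGRecord(rng.normal(size=257), fs=250, record_id="x")
        out = tmp_path / "w.csv"
        write_csv_record(rec, out)
        back = read_csv_record(out, fs=250)
        np.testing.assert_allclose(back.samples, rec.samples, atol=1e-9)

    def test_header_and_index_column_autodetected(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("sample,mV\n0,0.5\n1,0.7\n")
        rec = read_csv_record(p, fs=100)
        np.testing.assert_allclose(rec.samples, [0.5, 0.7])

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(DataError, match="empty record"):
            read_csv_record(p, fs=360)

    def test_non_numeric_row_reports_row_number(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("0.1\noops\n0.3\n")
        with pytest.raises(DataError, match="row 2"):
            read_csv_record(p, fs=360)


# ---------------------------------------------------------------------------
# WFDB
# ---------------------------------------------------------------------------

def _write_wfdb_16(tmp_path, name, adc, fs=360, gain=200.0, n_sig=1):
    """Hand-written format-16 fixture (little-endian int16, interleaved)."""
    adc = np.asarray(adc, dtype="<i2")
    n_samp = adc.shape[0]
    hea = [f"{name} {n_sig} {fs} {n_samp}"]
    for s in range(n_sig):
        hea.append(f"{name}.dat 16 {gain:g}(0)/mV 12 0 0 0 0 sig{s}")
    (tmp_path / f"{name}.hea").write_text("\n".join(hea) + "\n")
    (tmp_path / f"{name}.dat").write_bytes(adc.tobytes())
    return tmp_path / name


class TestWfdb:
    def test_format16_round_trip(self, tmp_path, rng):
        adc = rng.integers(-2000, 2000, size=1000)
        prefix = _write_wfdb_16(tmp_path, "rec16", adc)
        rec = read_wfdb_record(prefix)
        assert len(rec) == 1000 and rec.fs == 360 and rec.record_id == "rec16"
        np.testing.assert_allclose(rec.samples, adc / 200.0)

    def test_format212_hand_packed_oracle(self, tmp_path):
        # 12-bit packing: b0 = s1 & 0xFF; b1 = (s2 >> 8) << 4 | (s1 >> 8);
        # b2 = s2 & 0xFF, with two's-complement 12-bit samples
        samples = [100, -200, 3, 4]
        raw = bytearray()
        for s1, s2 in zip(samples[0::2], samples[1::2]):
            u1, u2 = s1 & 0xFFF, s2 & 0xFFF
            raw += bytes([u1 & 0xFF, ((u2 >> 8) << 4) | (u1 >> 8), u2 & 0xFF])
        (tmp_path / "r212.hea").write_text("r212 1 360 4\nr212.dat 212 100(0)/mV 12 0 0 0 0 sig0\n")
        (tmp_path / "r212.dat").write_bytes(bytes(raw))
        rec = read_wfdb_record(tmp_path / "r212")
        np.testing.assert_allclose(rec.samples, np.array(samples) / 100.0)

    def test_annotations_round_trip(self, tmp_path):
        prefix = _write_wfdb_16(tmp_path, "ann", np.zeros(1000, dtype=int) + 5)
        # MIT annotation words: little-endian 16-bit, code in the high 6
        # bits, time delta in the low 10; terminated by a zero word
        words = []
        for code, delta in ((1, 500), (8, 100)):  # 'N' at 500, 'A' at 600
            words.append(struct.pack("<H", (code << 10) | delta))
        words.append(struct.pack("<H", 0))
        (tmp_path / "ann.atr").write_bytes(b"".join(words))
        rec = read_wfdb_record(prefix)
        assert (500, "N") in rec.annotations
        assert (600, "A") in rec.annotations

    def test_two_channel_uses_channel_zero(self, tmp_path):
        ch0 = np.arange(10) * 10
        ch1 = -np.arange(10) * 10
        inter = np.empty(20, dtype="<i2")
        inter[0::2], inter[1::2] = ch0, ch1
        (tmp_path / "two.hea").write_text(
            "two 2 250 10\ntwo.dat 16 200(0)/mV 12 0 0 0 0 a\ntwo.dat 16 200(0)/mV 12 0 0 0 0 b\n"
        )
        (tmp_path / "two.dat").write_bytes(inter.tobytes())
        rec = read_wfdb_record(tmp_path / "two")
        np.testing.assert_allclose(rec.samples, ch0 / 200.0)

    def test_missing_header_errors(self, tmp_path):
        with pytest.raises(DataError, match="header"):
            read_wfdb_record(tmp_path / "nope")

    def test_unsupported_format_names_code(self, tmp_path):
        (tmp_path / "f8.hea").write_text("f8 1 360 4\nf8.dat 8 200(0)/mV 12 0 0 0 0 s\n")
        (tmp_path / "f8.dat").write_bytes(b"\x00" * 8)
        with pytest.raises(DataError, match="8"):
            read_wfdb_record(tmp_path / "f8")


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def _record(n, fs=360):
    return ECGRecord(np.arange(n, dtype=float), fs=fs, record_id="r")


class TestSegmentRecord:
    @pytest.mark.parametrize(
        "n,window,stride,expected",
        [
            (6000, 2000, 2000, 3),
            (1999, 2000, 2000, 0),
            (5000, 2000, 1000, 4),
            (2000, 2000, 2000, 1),
        ],
    )
    def test_segment_counts(self, n, window, stride, expected):
        segs = segment_record(_record(n), window, stride)
        assert len(segs) == expected

    def test_starts_are_stride_multiples(self):
        segs = segment_record(_record(5000), 2000, 1000)
        assert [s.start_index for s in segs] == [0, 1000, 2000, 3000]

    @settings(max_examples=200, deadline=None)
    @given(
        n=st.integers(0, 10_000),
        window=st.integers(2, 10_000),
        stride=st.integers(1, 10_000),
    )
    def test_count_matches_bruteforce_enumeration(self, n, window, stride):
        if n == 0:
            return
        rec = _record(n)
        segs = segment_record(rec, window, stride)
        brute = [s for s in range(0, n, stride) if s + window <= n]
        # also the closed form
        closed = (n - window) // stride + 1 if n >= window else 0
        assert len(segs) == len(brute) == closed
        for seg, start in zip(segs, brute):
            assert seg.start_index == start
            assert start + len(seg) <= n  # never indexes outside the record

    def test_window_values_are_views_of_record(self):
        rec = _record(100)
        seg = segment_record(rec, 10, 90)[0]
        np.testing.assert_array_equal(seg.values, rec.samples[:10])


class TestLabelSegments:
    def _segments(self):
        return [Segment(np.zeros(100), start_index=0, source_record="r")]

    def test_unanimous_window(self):
        out = label_segments(self._segments(), [(10, "N"), (50, "N")])
        assert out[0].label == "N"

    def test_majority_rule(self):
        anns = [(10, "N"), (20, "N"), (30, "N"), (40, "V")]
        out = label_segments(self._segments(), anns)
        assert out[0].label == "N"

    def test_tie_breaks_by_class_order(self):
        anns = [(10, "N"), (20, "N"), (30, "V"), (40, "V")]
        out = label_segments(self._segments(), anns)
        assert out[0].label == "N"  # N precedes PVC in the canonical order

    def test_unmapped_only_segment_is_dropped(self, caplog):
        out = label_segments(self._segments(), [(10, "Z")])
        assert out == []

    def test_annotations_outside_window_ignored(self):
        out = label_segments(self._segments(), [(150, "N")])
        assert out == []
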
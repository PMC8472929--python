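"""Reading single-lead ECG records and cutting them into fixed windows.

Supports two on-disk formats: plain CSV (one amplitude per row, optional
index column and header) and the PhysioNet WFDB family (``.hea`` header,
``.dat`` signal in format 16 or 212, optional ``.atr`` beat annotations).
Records are held as :class:`ECGRecord`; classification operates on
fixed-length :class:`Segment` windows (2000 samples by default).
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ECGRecord",
    "Segment",
    "DataError",
    "CLASSES",
    "DEFAULT_SYMBOL_MAP",
    "read_csv_record",
    "write_csv_record",
    "read_wfdb_record",
    "segment_record",
    "label_segments",
]

log = logging.getLogger(__name__)

#: The seven rhythm classes, in canonical order.  The order is also the
#: tie-break order used by :func:`label_segments`.
CLASSES = ("AF", "AT", "N", "PAC", "PVC", "SBR", "VT")

#: Default mapping from annotation symbols to rhythm classes.  Beat symbols
#: follow MIT-BIH conventions ('A' atrial premature, 'V' ventricular
#: premature, 'N' normal); rhythm-change auxiliary labels map the remaining
#: classes.  The table is intentionally editable: databases differ in the
#: symbols they use and no single mapping is authoritative.
DEFAULT_SYMBOL_MAP: Mapping[str, str] = {
    "N": "N",
    "A": "PAC",
    "V": "PVC",
    "AF": "AF",
    "AFIB": "AF",
    "AT": "AT",
    "SBR": "SBR",
    "VT": "VT",
}


class DataError(ValueError):
    """Raised for malformed or unreadable ECG data."""


@dataclass
class ECGRecord:
    """A sampled single-lead voltage trace.

    Attributes
    ----------
    samples : numpy.ndarray
        Voltage samples in millivolts, in acquisition order.
    fs : float
        Sampling frequency in Hz; strictly positive.
    record_id : str
        Opaque identifier (file stem, database record name, ...).
    annotations : list of (int, str)
        Optional ``(sample_index, symbol)`` pairs, e.g. beat labels.
    """

    samples: np.ndarray
    fs: float
    record_id: str = ""
    annotations: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise DataError("record must hold a non-empty 1-D sample array")
        if not self.fs > 0:
            raise DataError(f"sampling frequency must be > 0, got {self.fs}")
        for idx, _sym in self.annotations:
            if not 0 <= idx < self.samples.size:
                raise DataError(
                    f"annotation index {idx} outside record of length {self.samples.size}"
                )

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class Segment:
    """A fixed-length window cut from an :class:`ECGRecord`."""

    values: np.ndarray
    label: str | None = None
    source_record: str = ""
    start_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise DataError("segment needs at least two samples")

    def __len__(self) -> int:
        return self.values.size


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def read_csv_record(path: str | Path, fs: float, record_id: str | None = None) -> ECGRecord:
    """Read a CSV of one amplitude per row into an :class:`ECGRecord`.

    An optional leading index column (``i,value``) and a single header row
    are autodetected.  No resampling takes place; ``fs`` is taken on trust.
    """
    path = Path(path)
    rows: list[str] = [
        ln.strip() for ln in path.read_text().splitlines() if ln.strip()
    ]
    if not rows:
        raise DataError(f"empty record: {path}")

    def parse(line: str) -> float:
        parts = [p for p in line.replace("\t", ",").split(",") if p.strip()]
        # last column is the amplitude; a leading column is an index
        return float(parts[-1])

    start = 0
    try:
        parse(rows[0])
    except ValueError:
        start = 1  # header row
        if len(rows) == 1:
            raise DataError(f"empty record: {path}") from None

    samples = np.empty(len(rows) - start)
    for i, line in enumerate(rows[start:]):
        try:
            samples[i] = parse(line)
        except ValueError:
            raise DataError(
                f"non-numeric value at row {i + start + 1} of {path}: {line!r}"
            ) from None
    return ECGRecord(samples, fs, record_id or path.stem)


def write_csv_record(record: ECGRecord, path: str | Path) -> None:
    """Write one amplitude per row (no header, no index column)."""
    np.savetxt(Path(path), record.samples, fmt="%.9g")


# ---------------------------------------------------------------------------
# WFDB (.hea / .dat / .atr)
# ---------------------------------------------------------------------------
# Minimal reader for the PhysioNet waveform-database format: space-separated
# header, interleaved binary signal (format 16 = little-endian int16,
# format 212 = 12-bit packed pairs), and the MIT annotation byte code.

_ANN_SYMBOLS = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "[", 33: "]", 34: "e", 35: "n",
    36: "@", 37: "x", 38: "f", 39: "(", 40: ")", 41: "r",
}


def _parse_header(hea_path: Path) -> tuple[str, int, float, int, list[dict]]:
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise DataError(f"empty WFDB header: {hea_path}")
    head = lines[0].split()
    name = head[0].split("/")[0]
    n_sig = int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    n_samp = int(head[3]) if len(head) > 3 else 0
    signals = []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        fmt_tok = tok[1].split("x")[0].split(":")[0].split("+")[0]
        gain_tok = tok[2] if len(tok) > 2 else "200"
        gain_part = gain_tok.split("/")[0]
        if "(" in gain_part:
            g, b = gain_part.split("(")
            gain, baseline = float(g), int(b.rstrip(")"))
        else:
            gain, baseline = float(gain_part), None
        if gain == 0:
            gain = 200.0
        adc_zero = int(tok[4]) if len(tok) > 4 else 0
        signals.append(
            {
                "file": tok[0],
                "fmt": int(fmt_tok),
                "gain": gain,
                "baseline": baseline if baseline is not None else adc_zero,
            }
        )
    return name, n_sig, fs, n_samp, signals


def _read_dat(dat_path: Path, fmt: int, n_sig: int, n_samp: int) -> np.ndarray:
    """Return the raw ADC matrix (n_samp, n_sig)."""
    raw = dat_path.read_bytes()
    if fmt == 16:
        flat = np.frombuffer(raw, dtype="<i2")
        flat = flat[: (flat.size // n_sig) * n_sig]
        adc = flat.reshape(-1, n_sig)
    elif fmt == 212:
        b = np.frombuffer(raw, dtype=np.uint8)
        b = b[: (b.size // 3) * 3].reshape(-1, 3).astype(np.int32)
        first = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        second = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        first = np.where(first > 2047, first - 4096, first)
        second = np.where(second > 2047, second - 4096, second)
        flat = np.empty(b.shape[0] * 2, dtype=np.int32)
        flat[0::2], flat[1::2] = first, second
        flat = flat[: (flat.size // n_sig) * n_sig]
        adc = flat.reshape(-1, n_sig)
    else:
        raise DataError(f"unsupported WFDB signal format code {fmt}")
    if n_samp:
        adc = adc[:n_samp]
    return adc


def _read_atr(atr_path: Path) -> list[tuple[int, str]]:
    data = atr_path.read_bytes()
    anns: list[tuple[int, str]] = []
    t = 0
    i = 0
    while i + 1 < len(data):
        lo, hi = data[i], data[i + 1]
        i += 2
        code = hi >> 2
        delta = ((hi & 0x03) << 8) | lo
        if code == 0 and delta == 0:  # EOF
            break
        if code == 59:  # SKIP: 4-byte time follows
            if i + 3 < len(data):
                t += struct.unpack("<i", bytes([data[i + 2], data[i + 3], data[i], data[i + 1]]))[0]
                i += 4
            continue
        if code in (60, 61, 62):  # NUM / SUBTYP / CHAN modifiers
            continue
        if code == 63:  # AUX: delta bytes of text follow (padded even)
            i += delta + (delta & 1)
            continue
        t += delta
        anns.append((t, _ANN_SYMBOLS.get(code, "?")))
    return anns


def read_wfdb_record(path_prefix: str | Path, channel: int = 0) -> ECGRecord:
    """Read a WFDB record (``<prefix>.hea`` + ``.dat`` [+ ``.atr``]).

    When the record has several channels, ``channel`` (default 0) selects
    the lead.  Annotation symbols are preserved verbatim.  Only signal
    formats 16 and 212 are supported.
    """
    prefix = Path(path_prefix)
    hea = prefix.with_suffix(".hea")
    if not hea.exists():
        raise DataError(f"missing WFDB header: {hea}")
    name, n_sig, fs, n_samp, signals = _parse_header(hea)
    sig = signals[channel]
    dat_path = prefix.parent / sig["file"]
    if not dat_path.exists():
        raise DataError(f"missing WFDB signal file: {dat_path}")
    adc = _read_dat(dat_path, sig["fmt"], n_sig, n_samp)
    physical = (adc[:, channel] - sig["baseline"]) / sig["gain"]
    annotations: list[tuple[int, str]] = []
    atr = prefix.with_suffix(".atr")
    if atr.exists():
        annotations = [(t, s) for t, s in _read_atr(atr) if t < physical.size]
    return ECGRecord(physical.astype(float), fs, name, annotations)


# ---------------------------------------------------------------------------
# Segmentation and labeling
# ---------------------------------------------------------------------------

def segment_record(record: ECGRecord, window: int = 2000, stride: int | None = None) -> list[Segment]:
    """Cut ``record`` into windows of ``window`` samples every ``stride``.

    Windows are half-open ``[start, start+window)`` at starts 0, stride,
    2*stride, ...; a record shorter than ``window`` yields no segments.
    ``stride`` defaults to ``window`` (non-overlapping).
    """
    if window < 2:
        raise ValueError(f"window must be >= 2, got {window}")
    stride = window if stride is None else stride
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    n = len(record)
    out: list[Segment] = []
    for start in range(0, n - window + 1, stride):
        out.append(
            Segment(
                record.samples[start : start + window],
                source_record=record.record_id,
                start_index=start,
            )
        )
    return out


def label_segments(
    segments: Sequence[Segment],
    annotations: Sequence[tuple[int, str]],
    symbol_map: Mapping[str, str] | None = None,
    class_order: Sequence[str] = CLASSES,
) -> list[Segment]:
    """Assign each segment the majority class of its in-window annotations.

    Symbols are first mapped to classes through ``symbol_map``; unmapped
    symbols do not vote.  Ties go to the class earlier in ``class_order``.
    Segments with no mapped annotation are dropped (the count is logged).
    """
    symbol_map = DEFAULT_SYMBOL_MAP if symbol_map is None else symbol_map
    rank = {c: i for i, c in enumerate(class_order)}
    labeled: list[Segment] = []
    dropped = 0
    unmapped: set[str] = set()
    for seg in segments:
        lo, hi = seg.start_index, seg.start_index + len(seg)
        votes: dict[str, int] = {}
        for idx, sym in annotations:
            if lo <= idx < hi:
                cls = symbol_map.get(sym)
                if cls is None:
                    unmapped.add(sym)
                else:
                    votes[cls] = votes.get(cls, 0) + 1
        if not votes:
            dropped += 1
            continue
        best = min(votes, key=lambda c: (-votes[c], rank.get(c, len(rank))))
        labeled.append(
            Segment(seg.values, label=best, source_record=seg.source_record, start_index=seg.start_index)
        )
    if dropped:
        log.warning(
            "label_segments: dropped %d unlabeled segment(s); unmapped symbols: %s",
            dropped,
            sorted(unmapped) or "-",
        )
    return labeled
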
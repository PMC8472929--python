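"""Synthetic single-lead rhythm strips for the seven arrhythmia classes.

Beats are sums of Gaussian bumps (P, QRS with an S-dip, T) placed at fixed
phase fractions of each cardiac cycle; rhythms differ in heart-rate band,
RR-interval variability, QRS width, P-wave presence, premature-beat
(ectopy) statistics and fibrillatory baseline activity:

* ``N``   — regular narrow-complex rhythm at 60–100 bpm with P waves;
* ``SBR`` — the same morphology below 60 bpm;
* ``AT``  — rapid regular narrow-complex rhythm above 150 bpm;
* ``VT``  — rapid wide-complex rhythm, no P waves;
* ``AF``  — irregularly irregular RR, absent P waves, fibrillatory baseline;
* ``PAC`` — normal rhythm with interspersed early narrow beats;
* ``PVC`` — normal rhythm with interspersed early wide, large beats.

This is a phenomenological generator, not a physiological model: it
exercises every pipeline stage (segmentation, GASF encoding, training,
evaluation) with learnable, honestly labeled data.  Strips of the ectopic
classes always contain at least one ectopic beat, mirroring how labeled
excerpts are selected from annotated databases.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_widths

from .signal_io import CLASSES, ECGRecord, Segment

__all__ = [
    "Morphology",
    "Ectopy",
    "FibrillatoryBaseline",
    "RhythmSpec",
    "DEFAULT_SPECS",
    "REFERENCE_CLASS_COUNTS",
    "scaled_counts",
    "beat_template",
    "generate_rhythm",
    "make_dataset",
    "rhythm_features",
    "rule_based_classifier",
]

#: Wave-center delays after the beat onset, in seconds, at reference cycle
#: length.  The P-QRS-T complex sits at the start of the cycle (fixed PR
#: and QT timing); RR variability lives in the diastolic pause, so QRS
#: peak-to-peak intervals reproduce the drawn cycle lengths exactly.
P_OFFSET_S, QRS_OFFSET_S, T_OFFSET_S = 0.12, 0.25, 0.45
#: Cycles shorter than this compress the wave offsets proportionally.
REF_CYCLE_S = 0.6


def wave_compression(rr_s: float) -> float:
    """Offset compression factor for fast rhythms (1 at normal rates)."""
    return min(1.0, rr_s / REF_CYCLE_S)


@dataclass(frozen=True)
class Morphology:
    """Gaussian-bump beat template parameters (amplitudes in mV-like units,
    widths are full widths at half maximum in milliseconds)."""

    p_amp: float = 0.20
    p_width_ms: float = 90.0
    qrs_amp: float = 1.0
    qrs_width_ms: float = 80.0
    t_amp: float = 0.30
    t_width_ms: float = 180.0


@dataclass(frozen=True)
class Ectopy:
    """Premature-beat statistics: per-cycle probability, the ectopic beat's
    own morphology, and prematurity (ectopic coupling interval as a
    fraction of the normal RR; the following pause is compensatory)."""

    probability: float = 0.0
    morphology: Morphology | None = None
    prematurity: float = 0.62


@dataclass(frozen=True)
class FibrillatoryBaseline:
    """Band-limited baseline oscillation (f-waves) for AF."""

    amplitude: float = 0.0
    band_hz: tuple[float, float] = (4.0, 9.0)


@dataclass(frozen=True)
class RhythmSpec:
    """Complete parameter set for one synthetic rhythm class."""

    cls: str
    rate_bpm: tuple[float, float]
    rr_cv: float
    morphology: Morphology = field(default_factory=Morphology)
    ectopy: Ectopy = field(default_factory=Ectopy)
    baseline: FibrillatoryBaseline = field(default_factory=FibrillatoryBaseline)


_NARROW = Morphology()
_WIDE = Morphology(p_amp=0.0, qrs_amp=1.2, qrs_width_ms=150.0, t_amp=0.35)

DEFAULT_SPECS: Mapping[str, RhythmSpec] = {
    "N": RhythmSpec("N", (62, 98), 0.03),
    "SBR": RhythmSpec("SBR", (40, 57), 0.03),
    "AT": RhythmSpec("AT", (155, 215), 0.02, morphology=replace(_NARROW, p_amp=0.12)),
    "VT": RhythmSpec("VT", (150, 200), 0.03, morphology=_WIDE),
    "AF": RhythmSpec(
        "AF", (95, 135), 0.22,
        morphology=replace(_NARROW, p_amp=0.0),
        baseline=FibrillatoryBaseline(amplitude=0.06),
    ),
    "PAC": RhythmSpec(
        "PAC", (62, 98), 0.03,
        ectopy=Ectopy(probability=0.18, morphology=replace(_NARROW, p_amp=0.15)),
    ),
    "PVC": RhythmSpec(
        "PVC", (62, 98), 0.03,
        ectopy=Ectopy(probability=0.18, morphology=_WIDE),
    ),
}

#: Per-class sample counts of the reference study dataset; the generator's
#: default class balance mirrors these proportions.
REFERENCE_CLASS_COUNTS: Mapping[str, int] = {
    "AF": 1841, "AT": 500, "N": 4800, "PAC": 328, "PVC": 2106, "SBR": 1855, "VT": 294,
}


def scaled_counts(scale: float, counts: Mapping[str, int] | None = None) -> dict[str, int]:
    """Scale a class-count table, keeping at least one sample per class."""
    counts = REFERENCE_CLASS_COUNTS if counts is None else counts
    return {c: max(1, round(n * scale)) for c, n in counts.items()}


def _gauss(t: np.ndarray, center: float, fwhm_s: float) -> np.ndarray:
    sd = fwhm_s / 2.3548200450309493  # FWHM = 2 sqrt(2 ln 2) sd
    return np.exp(-0.5 * ((t - center) / sd) ** 2)


def beat_template(morph: Morphology, fs: float, rr_s: float = 0.8) -> np.ndarray:
    """Render one cardiac complex for a cycle of length ``rr_s`` seconds.

    P, QRS and T are Gaussian bumps at fixed onset delays (compressed
    proportionally for cycles shorter than the reference); the QRS complex
    adds a small S-dip whose offset and width scale with the QRS width, so
    doubling ``qrs_width_ms`` doubles the full width at half maximum of
    the central bump exactly.  The rendered window covers the T wave even
    when the cycle is shorter, so premature beats overlap-add naturally.
    """
    if fs <= 0:
        raise ValueError("fs must be > 0")
    for name in ("p_width_ms", "qrs_width_ms", "t_width_ms"):
        if getattr(morph, name) <= 0:
            raise ValueError(f"{name} must be > 0")
    c = wave_compression(rr_s)
    t_fwhm = morph.t_width_ms / 1000.0
    length_s = max(rr_s, c * T_OFFSET_S + 1.5 * t_fwhm)
    n = max(2, int(round(length_s * fs)))
    t = np.arange(n) / fs
    qrs_fwhm = morph.qrs_width_ms / 1000.0
    qrs_c = c * QRS_OFFSET_S
    wave = morph.p_amp * _gauss(t, c * P_OFFSET_S, morph.p_width_ms / 1000.0)
    wave += morph.qrs_amp * _gauss(t, qrs_c, qrs_fwhm)
    wave -= 0.18 * morph.qrs_amp * _gauss(t, qrs_c + 0.8 * qrs_fwhm, 0.6 * qrs_fwhm)
    wave += morph.t_amp * _gauss(t, c * T_OFFSET_S, t_fwhm)
    return wave


def _beat_schedule(spec: RhythmSpec, duration_s: float, rng, force_at: int | None):
    """Sequence of (onset_s, cycle_s, is_ectopic) beat events."""
    lo, hi = spec.rate_bpm
    if lo > hi:
        raise ValueError(f"infeasible rate band ({lo}, {hi}) for class {spec.cls}")
    base_rr = 60.0 / rng.uniform(lo, hi)
    events: list[tuple[float, float, bool]] = []
    t = 0.05
    k = 0
    forced = False
    while t < duration_s + base_rr:
        rr = base_rr * max(0.4, 1.0 + spec.rr_cv * rng.standard_normal())
        u = rng.random()
        force_now = force_at is not None and k >= force_at and not forced
        ect = spec.ectopy.probability > 0 and (u < spec.ectopy.probability or force_now)
        forced = forced or (ect and force_now)
        if ect:
            coupling = spec.ectopy.prematurity * rr
            pause = (2.0 - spec.ectopy.prematurity) * rr
            events.append((t, coupling, False))
            events.append((t + coupling, pause, True))
            t += coupling + pause
            k += 2
        else:
            events.append((t, rr, False))
            t += rr
            k += 1
    return events, base_rr


def generate_rhythm(
    spec: RhythmSpec,
    duration_s: float,
    fs: float = 250.0,
    seed: int = 0,
    noise_sd: float = 0.02,
) -> ECGRecord:
    """Generate one labeled rhythm strip, fully seed-reproducible.

    RR intervals are drawn around a strip-level mean rate from the spec's
    band with the spec's coefficient of variation; ectopic beats arrive
    early and are followed by a compensatory pause; AF adds band-limited
    baseline oscillation; white Gaussian measurement noise (``noise_sd``
    relative to unit QRS amplitude) is added last.  Beat annotations carry
    'N'/'A'/'V' symbols for the ectopic classes and the rhythm label
    itself for the rhythm classes.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    rng = np.random.default_rng(seed)
    events, base_rr = _beat_schedule(spec, duration_s, rng, force_at=None)
    if spec.ectopy.probability > 0 and not any(
        e[2] and e[0] < duration_s for e in events
    ):
        # labeled ectopic strips must show at least one ectopic beat
        rng = np.random.default_rng(seed)
        events, base_rr = _beat_schedule(spec, duration_s, rng, force_at=len(events) // 2)

    n = int(round(duration_s * fs))
    y = np.zeros(n)
    annotations: list[tuple[int, str]] = []
    rhythm_symbol = spec.cls if spec.cls in ("AF", "AT", "SBR", "VT") else "N"
    ect_morph = spec.ectopy.morphology or spec.morphology
    ect_symbol = "V" if ect_morph.qrs_width_ms >= 120 else "A"
    # wave offsets are anchored on the strip's base cycle so QRS-to-QRS
    # intervals reproduce the drawn RR sequence exactly
    templates = {
        False: beat_template(spec.morphology, fs, base_rr),
        True: beat_template(ect_morph, fs, base_rr),
    }
    qrs_delay = wave_compression(base_rr) * QRS_OFFSET_S
    for onset, _cycle, ect in events:
        tpl = templates[ect]
        i0 = int(round(onset * fs))
        i1 = min(n, i0 + tpl.size)
        if i0 >= n:
            break
        y[i0:i1] += tpl[: i1 - i0]
        qrs_idx = int(round((onset + qrs_delay) * fs))
        if 0 <= qrs_idx < n:
            annotations.append((qrs_idx, ect_symbol if ect else rhythm_symbol))

    if spec.baseline.amplitude > 0:
        t = np.arange(n) / fs
        f_lo, f_hi = spec.baseline.band_hz
        comp = np.zeros(n)
        n_comp = 6
        for _ in range(n_comp):
            comp += np.sin(2 * np.pi * rng.uniform(f_lo, f_hi) * t + rng.uniform(0, 2 * np.pi))
        y += spec.baseline.amplitude * comp / np.sqrt(n_comp)

    y += rng.normal(0.0, noise_sd * spec.morphology.qrs_amp, size=n)
    return ECGRecord(y, fs, record_id=f"synth-{spec.cls}-{seed}", annotations=annotations)


def make_dataset(
    class_counts: Mapping[str, int],
    segment_len: int = 2000,
    fs: float = 250.0,
    seed: int = 0,
    specs: Mapping[str, RhythmSpec] | None = None,
    noise_sd: float = 0.02,
) -> tuple[list[Segment], pd.DataFrame]:
    """Generate exactly the requested number of labeled segments per class.

    Returns the segments (each a fresh strip cut to ``segment_len``
    samples) and a (class, n) manifest.  Classes are generated in
    canonical order, so the output is deterministic in ``seed`` alone.
    """
    specs = DEFAULT_SPECS if specs is None else specs
    rng = np.random.default_rng(seed)
    segments: list[Segment] = []
    rows = []
    # generate exactly the window so the guaranteed ectopic beat (for the
    # ectopic classes) falls inside the cut
    duration = segment_len / fs
    order = sorted(class_counts, key=lambda c: (CLASSES.index(c) if c in CLASSES else len(CLASSES), c))
    for cls in order:
        count = int(class_counts[cls])
        if count < 0:
            raise ValueError(f"negative count for class {cls}")
        for _ in range(count):
            child = int(rng.integers(0, 2**31 - 1))
            rec = generate_rhythm(specs[cls], duration, fs=fs, seed=child, noise_sd=noise_sd)
            segments.append(
                Segment(rec.samples[:segment_len], label=cls, source_record=rec.record_id)
            )
        rows.append({"class": cls, "n": count})
    manifest = pd.DataFrame(rows, columns=["class", "n"])
    return segments, manifest


# ---------------------------------------------------------------------------
# Simple rhythm statistics (sanity baseline, not part of the classifier)
# ---------------------------------------------------------------------------

def rhythm_features(values: np.ndarray, fs: float) -> dict[str, float]:
    """Crude per-strip rhythm statistics from half-height QRS detection.

    Returns heart rate, RR coefficient of variation, the fraction of wide
    (>= 115 ms) beats, the shortest RR relative to the median, and a P-wave
    amplitude estimate from the pre-QRS window.
    """
    x = np.asarray(values, dtype=float)
    height = 0.5 * x.max()
    peaks, _ = find_peaks(x, height=height, distance=max(1, int(0.18 * fs)))
    out = {"n_beats": float(peaks.size), "heart_rate": np.nan, "rr_cv": np.nan,
           "frac_wide": np.nan, "min_rr_ratio": np.nan, "frac_deviant": np.nan,
           "p_amp": np.nan}
    if peaks.size < 3:
        return out
    widths_ms = peak_widths(x, peaks, rel_height=0.5)[0] / fs * 1000.0
    rr = np.diff(peaks) / fs
    med = float(np.median(rr))
    out["heart_rate"] = 60.0 / med
    out["rr_cv"] = float(rr.std() / rr.mean())
    out["frac_wide"] = float(np.mean(widths_ms >= 115.0))
    out["min_rr_ratio"] = float(rr.min() / med)
    out["frac_deviant"] = float(np.mean(np.abs(rr / med - 1.0) > 0.12))
    p_est = []
    qrs_amp = float(np.median(x[peaks]))
    # search a window centered on the expected P location (fixed PR timing,
    # compressed at fast rates); only beats preceded by at least the median
    # RR are measured, so the previous beat's T wave stays clear of the window
    p_gap = (QRS_OFFSET_S - P_OFFSET_S) * wave_compression(med)
    for prev_rr, pk in zip(rr, peaks[1:]):
        if prev_rr < med:
            continue
        # keep the near edge >= 85 ms from the peak, clear of the QRS upstroke
        lo = pk - int((p_gap + 0.05) * fs)
        hi = pk - int(max(p_gap - 0.04, 0.085) * fs)
        if lo >= 0 and hi > lo:
            p_est.append(x[lo:hi].max())
    out["p_amp"] = float(np.median(p_est) / qrs_amp) if p_est else np.nan
    return out


def rule_based_classifier(values: np.ndarray, fs: float) -> str:
    """Tiny hand-written rule classifier over :func:`rhythm_features`.

    Exists to certify that the generated classes are separable from
    first-principles rhythm statistics (QRS width, RR variability, rate,
    P-wave presence) — i.e. that a learning model has signal to find.
    """
    f = rhythm_features(values, fs)
    if f["n_beats"] < 3:
        return "N"
    if f["frac_wide"] >= 0.6:
        return "VT" if f["heart_rate"] >= 100 else "PVC"
    if f["frac_wide"] > 0.08:
        return "PVC"
    if f["rr_cv"] > 0.12:
        # AF is irregularly irregular (most intervals deviate, no P waves);
        # occasional early beats with preserved P point to PAC instead
        if f["p_amp"] > 0.12 and f["frac_deviant"] < 0.45:
            return "PAC"
        return "AF"
    if f["min_rr_ratio"] < 0.80:
        return "PAC"
    if f["heart_rate"] < 60:
        return "SBR"
    if f["heart_rate"] > 140:
        return "AT"
    return "N"
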
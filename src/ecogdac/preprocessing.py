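"""Downsampling, the six-band FIR filter bank, artifact exclusion, windowing.

The filter bank covers six non-overlapping bands of roughly 0.6 octave that
avoid 60 Hz and track conventional physiological bands (theta through high
gamma).  All filtering is zero-phase (forward-backward FIR), which matters
here because the quantity under study is instantaneous inter-channel
correlation: any phase distortion differing across channels or bands would
contaminate it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import NamedTuple

import numpy as np
from scipy.signal import filtfilt, firwin, resample_poly

from .recording import Recording


class BandDefinition(NamedTuple):
    name: str
    low: float   # Hz
    high: float  # Hz


#: Six non-overlapping ~0.6-octave bands avoiding 60 Hz.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("6-9", 6.0, 9.0),
    BandDefinition("10-15", 10.0, 15.0),
    BandDefinition("20-30", 20.0, 30.0),
    BandDefinition("35-50", 35.0, 50.0),
    BandDefinition("70-110", 70.0, 110.0),
    BandDefinition("130-200", 130.0, 200.0),
)

#: Artifact-exclusion defaults: reference excursion (µV), absolute channel
#: excursion (µV), highest-band RMS multiple, pre/post exclusion margins (s)
#: and the minimum surviving clean-segment length (s).
REFERENCE_THRESHOLD_UV = 35.0
CHANNEL_THRESHOLD_UV = 4000.0
RMS_MULTIPLE = 20.0
PRE_MARGIN_S = 0.75
POST_MARGIN_S = 1.25
MIN_SEGMENT_S = 6.0


@dataclass
class WindowSet:
    """Fixed-length analysis windows cut from the clean part of a recording."""

    data: np.ndarray                 # (n_windows, n_samples, n_channels)
    starts: np.ndarray               # window start times, s
    window_length: float             # s
    fs: float
    band: BandDefinition | None = None
    channel_ids: list[str] = field(default=None)

    @property
    def n_windows(self) -> int:
        return self.data.shape[0]


def design_bandpass(band: BandDefinition, fs: float,
                    max_taps: int | None = None) -> np.ndarray:
    """Windowed-sinc FIR band-pass for zero-phase application.

    The tap count is set so the (Hamming-window) transition width is 20% of
    the lower band edge, giving >= 40 dB at band edges ± 20% after the
    forward-backward pass.
    """
    if band.high >= fs / 2:
        raise ValueError(f"band {band} exceeds Nyquist ({fs / 2} Hz)")
    trans = 0.2 * band.low
    numtaps = int(np.ceil(3.3 * fs / trans)) | 1
    if max_taps is not None and numtaps > max_taps:
        numtaps = max(int(max_taps) | 1, 3)
        warnings.warn(
            f"band {band.name}: tap count capped at {numtaps}; "
            "transition band is wider than designed"
        )
    return firwin(numtaps, [band.low, band.high], pass_zero=False, fs=fs)


def _zero_phase(taps: np.ndarray, x: np.ndarray) -> np.ndarray:
    padlen = min(3 * len(taps), x.shape[0] - 1)
    return filtfilt(taps, 1.0, x, axis=0, padlen=padlen)


def bandpass_recording(rec: Recording, band: BandDefinition) -> Recording:
    """Zero-phase band-pass of every channel (reference passed through raw)."""
    max_taps = (rec.n_samples - 1) // 3
    taps = design_bandpass(band, rec.fs, max_taps=max_taps)
    return Recording(_zero_phase(taps, rec.data), rec.fs,
                     list(rec.channel_ids), rec.reference)


def downsample(rec: Recording, target_rate: float) -> Recording:
    """Anti-aliased rate reduction (low-pass at 0.45 × target rate)."""
    if target_rate >= rec.fs:
        raise ValueError("target rate must be below the current rate")
    frac = Fraction(target_rate / rec.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    cutoff = 0.45 * target_rate
    taps = firwin(int(np.ceil(3.3 * rec.fs / (0.1 * target_rate))) | 1,
                  cutoff, fs=rec.fs)
    data = _zero_phase(taps, rec.data)
    data = resample_poly(data, up, down, axis=0)
    ref = None
    if rec.reference is not None:
        ref = resample_poly(_zero_phase(taps, rec.reference[:, None])[:, 0],
                            up, down)
    return Recording(data, rec.fs * up / down, list(rec.channel_ids), ref)


def apply_filter_bank(
    rec: Recording,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    working_rate: float | None = None,
) -> dict[str, Recording]:
    """Band-pass the recording into each band at the working rate."""
    if working_rate is not None and working_rate != rec.fs:
        rec = downsample(rec, working_rate)
    for band in bands:
        if band.high >= rec.fs / 2:
            raise ValueError(f"band {band} above Nyquist at {rec.fs} S/s")
    return {band.name: bandpass_recording(rec, band) for band in bands}


def _mask_to_intervals(mask: np.ndarray, fs: float) -> list[tuple[float, float]]:
    """Runs of True in a boolean sample mask, as [start, end) times in s."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2]
    return [(s / fs, e / fs) for s, e in zip(starts, ends)]


def detect_artifacts(
    rec: Recording,
    highest_band: BandDefinition = DEFAULT_BANDS[-1],
    reference_threshold_uv: float = REFERENCE_THRESHOLD_UV,
    channel_threshold_uv: float = CHANNEL_THRESHOLD_UV,
    rms_multiple: float = RMS_MULTIPLE,
    pre_margin_s: float = PRE_MARGIN_S,
    post_margin_s: float = POST_MARGIN_S,
    min_segment_s: float = MIN_SEGMENT_S,
) -> list[tuple[float, float]]:
    """Intervals to exclude from analysis, merged and sorted (seconds).

    A sample is marked when the reference strays more than 35 µV from zero,
    any channel leaves ±4 mV, or the highest-band signal exceeds 20× that
    band's per-channel RMS; each marked sample drags 750 ms before and
    1.25 s after it into the exclusion.  Surviving clean segments shorter
    than 6 s are excluded as well.
    """
    n, fs = rec.n_samples, rec.fs
    mask = np.zeros(n, dtype=bool)

    if rec.reference is not None:
        mask |= np.abs(rec.reference) > reference_threshold_uv
    else:
        warnings.warn("no reference trace recorded; reference artifact rule skipped")

    mask |= (np.abs(rec.data) > channel_threshold_uv).any(axis=1)

    hb = bandpass_recording(rec, highest_band).data
    rms = np.sqrt((hb**2).mean(axis=0))
    mask |= (np.abs(hb) > rms_multiple * rms[None, :]).any(axis=1)

    # dilate each marked sample by the pre/post margins
    if mask.any():
        pre = int(round(pre_margin_s * fs))
        post = int(round(post_margin_s * fs))
        idx = np.flatnonzero(mask)
        dil = np.zeros(n + 1, dtype=int)
        lo = np.clip(idx - pre, 0, n)
        hi = np.clip(idx + post + 1, 0, n)
        np.add.at(dil, lo, 1)
        np.add.at(dil, hi, -1)
        mask = np.cumsum(dil[:-1]) > 0

    # drop clean segments shorter than the minimum
    min_len = int(round(min_segment_s * fs))
    clean = ~mask
    padded = np.concatenate([[False], clean, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    for s, e in zip(edges[::2], edges[1::2]):
        if e - s < min_len:
            mask[s:e] = True

    return _mask_to_intervals(mask, fs)


def clean_segments(
    duration: float, excluded: list[tuple[float, float]]
) -> list[tuple[float, float]]:
    """Complement of the excluded intervals within [0, duration]."""
    segs, t = [], 0.0
    for s, e in sorted(excluded):
        if s > t:
            segs.append((t, min(s, duration)))
        t = max(t, e)
    if t < duration:
        segs.append((t, duration))
    return [(s, e) for s, e in segs if e > s]


def segment_windows(
    rec: Recording,
    excluded: list[tuple[float, float]] | None = None,
    window_length: float = 2.0,
    band: BandDefinition | None = None,
) -> WindowSet:
    """Cut non-overlapping windows, left-aligned within each clean segment.

    Partial trailing windows are discarded; no window overlaps an excluded
    interval.
    """
    if not window_length > 0:
        raise ValueError("window_length must be positive")
    excluded = excluded or []
    fs = rec.fs
    wlen = int(round(window_length * fs))
    chunks, starts = [], []
    for s, e in clean_segments(rec.duration, excluded):
        i0 = int(np.ceil(s * fs - 1e-9))
        i1 = int(np.floor(e * fs + 1e-9))
        for k in range((i1 - i0) // wlen):
            a = i0 + k * wlen
            chunks.append(rec.data[a:a + wlen])
            starts.append(a / fs)
    if not chunks:
        warnings.warn("no clean data: empty window set")
        data = np.zeros((0, wlen, rec.n_channels))
    else:
        data = np.stack(chunks)
    return WindowSet(data, np.array(starts), window_length, fs, band,
                     list(rec.channel_ids))
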
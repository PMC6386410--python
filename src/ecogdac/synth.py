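"""Synthetic micro-ECoG recordings with known spatially coherent structure.

The generator emulates what the analysis assumes about surface potentials on
a dense electrode grid: a handful of band-limited temporal sources, each
projected onto the channels through a radially symmetric 2D Gaussian weight
profile (the signature of a compact source seen through volume conduction),
plus independent per-channel sensor noise and a spatially uniform common
reference signal.  The ground-truth mixing matrix is returned alongside the
recording so every downstream stage (DAC, decomposition, weight-map fitting)
can be validated against known structure.

Two temporal waveforms are available per source:

``am_oscillation`` (default)
    A sinusoidal carrier at a random frequency inside the source's band,
    multiplied by a slowly varying rectified-noise envelope — a bursty
    narrowband oscillation.  Its marginal distribution is strongly
    non-Gaussian, which is what makes the sources identifiable by ICA
    (mixtures of Gaussian processes are not separable by any ICA contrast).

``bandpass_noise``
    Gaussian white noise band-passed to the source band and standardized.
    Same second-order structure, but Gaussian, hence useful for covariance
    tests and as an explicit ICA-unidentifiable control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .grid import ElectrodeGrid
from .recording import Recording


@dataclass
class SourceSpec:
    """One spatially coherent source.

    center : (x, y) mm — peak of its Gaussian weight profile
    width_sigma : spatial standard deviation, mm
    amplitude : peak channel weight, microvolts (per unit-variance component)
    band : (low, high) Hz temporal passband
    waveform : "am_oscillation" or "bandpass_noise"
    """

    center: tuple[float, float]
    width_sigma: float
    amplitude: float
    band: tuple[float, float]
    waveform: str = "am_oscillation"

    def validate(self, fs: float) -> None:
        if not self.width_sigma > 0:
            raise ValueError("width_sigma must be positive")
        lo, hi = self.band
        if not (0 < lo < hi < fs / 2):
            raise ValueError(f"band {self.band} must satisfy 0 < low < high < Nyquist")
        if self.waveform not in ("am_oscillation", "bandpass_noise"):
            raise ValueError(f"unknown waveform {self.waveform!r}")


@dataclass
class SyntheticRecordingSpec:
    """Full description of a synthetic recording; reproducible from seed."""

    grid: ElectrodeGrid
    sources: list[SourceSpec]
    noise_sd: float = 0.0            # microvolts, per-channel white noise
    reference_amplitude: float = 0.0  # microvolts, common reference weight
    sampling_rate: float = 1000.0
    duration: float = 20.0
    seed: int = 0
    reference_band: tuple[float, float] = field(default=(2.0, 100.0))

    def validate(self) -> None:
        if self.duration * self.sampling_rate < 2:
            raise ValueError("need at least 2 samples")
        if self.noise_sd < 0 or self.reference_amplitude < 0:
            raise ValueError("noise_sd and reference_amplitude must be >= 0")
        for s in self.sources:
            s.validate(self.sampling_rate)


def bandpass_noise(n: int, band: tuple[float, float], fs: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to ``band`` (zero-phase)."""
    x = rng.standard_normal(n)
    sos = butter(4, band, btype="band", fs=fs, output="sos")
    y = sosfiltfilt(sos, x)
    sd = y.std()
    return (y - y.mean()) / sd if sd > 0 else y


def am_oscillation(n: int, band: tuple[float, float], fs: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Unit-variance bursty narrowband oscillation.

    Carrier frequency is drawn uniformly from the central 70% of the band;
    the envelope is low-passed Gaussian noise rectified at zero (cutoff
    min(4 Hz, bandwidth/3)), so the source waxes and wanes on a timescale
    slow relative to its oscillation.
    """
    t = np.arange(n) / fs
    lo, hi = band
    bw = hi - lo
    f = rng.uniform(lo + 0.15 * bw, hi - 0.15 * bw)
    carrier = np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    env_cut = min(4.0, bw / 3)
    sos = butter(2, env_cut, btype="low", fs=fs, output="sos")
    env = np.maximum(sosfiltfilt(sos, rng.standard_normal(n)), 0.0)
    y = carrier * env
    sd = y.std()
    return (y - y.mean()) / sd if sd > 0 else y


def gaussian_weights(grid: ElectrodeGrid, center: tuple[float, float],
                     width_sigma: float, amplitude: float) -> np.ndarray:
    """Per-channel weights of a circular Gaussian spatial profile."""
    d2 = ((grid.positions - np.asarray(center, dtype=float)) ** 2).sum(1)
    return amplitude * np.exp(-d2 / (2.0 * width_sigma**2))


def generate_recording(
    spec: SyntheticRecordingSpec,
) -> tuple[Recording, np.ndarray]:
    """Synthesize a recording; return it with the ground-truth mixing matrix.

    The returned weight matrix has one column per source, ordered by
    descending spatial amplitude, plus (if ``reference_amplitude > 0``) a
    final constant reference column.  Channel signals are
    ``W @ z + noise_sd * white`` with unit-variance component time courses
    ``z``; the sample covariance therefore converges to
    ``W W^T + noise_sd**2 * I`` as the duration grows.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.sampling_rate))
    n_ch = spec.grid.n_channels

    order = np.argsort([-s.amplitude for s in spec.sources], kind="stable")
    sources = [spec.sources[k] for k in order]

    cols, comps = [], []
    for src in sources:
        cols.append(gaussian_weights(spec.grid, src.center, src.width_sigma,
                                     src.amplitude))
        gen = am_oscillation if src.waveform == "am_oscillation" else bandpass_noise
        comps.append(gen(n, src.band, spec.sampling_rate, rng))

    reference = None
    if spec.reference_amplitude > 0:
        ref_tc = bandpass_noise(n, spec.reference_band, spec.sampling_rate, rng)
        cols.append(np.full(n_ch, spec.reference_amplitude))
        comps.append(ref_tc)
        reference = spec.reference_amplitude * ref_tc

    if cols:
        W = np.column_stack(cols)
        Z = np.stack(comps, axis=1)            # samples × components
        data = Z @ W.T
    else:
        W = np.zeros((n_ch, 0))
        data = np.zeros((n, n_ch))

    if spec.noise_sd > 0:
        data = data + spec.noise_sd * rng.standard_normal((n, n_ch))

    rec = Recording(data, spec.sampling_rate, list(spec.grid.channel_ids),
                    reference=reference)
    return rec, W


def five_source_study_spec(
    seed: int = 0,
    width_sigma_pitches: float = 1.5,
    noise_sd: float = 0.05,
    reference_amplitude: float = 0.0,
    duration: float = 20.0,
    pitch: float = 0.4,
    band: tuple[float, float] = (20.0, 30.0),
    sampling_rate: float = 500.0,
    waveform: str = "am_oscillation",
) -> SyntheticRecordingSpec:
    """Canonical five-source recording on a 56-channel (7 × 8) grid.

    Five equally wide Gaussian sources with gently decreasing amplitudes
    (1.0 down to 0.8 µV) sit at spread-out locations covering the grid —
    four off-center quadrant positions and one central — so their weight
    maps overlap but remain distinguishable.  With the default
    ``noise_sd = 0.05`` the per-channel SNR is far above 10.  This is the
    reference configuration for source-recovery and attribution validation;
    vary ``width_sigma_pitches`` to study width recovery.
    """
    grid = ElectrodeGrid.rectangular(7, 8, pitch)
    centers_pitch = [(1.5, 1.5), (5.5, 1.5), (1.5, 5.0), (5.5, 5.0), (3.5, 3.2)]
    amplitudes = [1.0, 0.95, 0.9, 0.85, 0.8]
    sources = [
        SourceSpec(center=(cx * pitch, cy * pitch),
                   width_sigma=width_sigma_pitches * pitch,
                   amplitude=a, band=band, waveform=waveform)
        for (cx, cy), a in zip(centers_pitch, amplitudes)
    ]
    return SyntheticRecordingSpec(
        grid=grid, sources=sources, noise_sd=noise_sd,
        reference_amplitude=reference_amplitude,
        sampling_rate=sampling_rate, duration=duration, seed=seed,
    )


def write_ground_truth_csv(W: np.ndarray, grid: ElectrodeGrid,
                           path: str | Path) -> None:
    """Ground-truth mixing matrix as channels × components CSV."""
    df = pd.DataFrame(
        W, index=grid.channel_ids,
        columns=[f"component_{k}" for k in range(W.shape[1])],
    )
    df.index.name = "channel"
    df.to_csv(path)
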
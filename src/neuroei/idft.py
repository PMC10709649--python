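"""Frequency-domain construction of power-law surrogate signals.

Signals are built by prescribing a one-sided amplitude spectrum that follows
a power law P(f) = O * f**-s between a knee frequency ``f0`` and a cutoff
``ff``, drawing random phases for every positive-frequency bin, and applying
an inverse real FFT.  Below ``f0`` the amplitude is held at its value at
``f0`` (flattening the spectrum, which keeps the signal stationary); above
``ff`` the amplitude is zero, so ``ff`` acts as an ideal low-pass cutoff.

Conventions
-----------
* Amplitude is the square root of power, ``A(f) = sqrt(P(f))``.
* The DC bin is zero, so every synthesized signal has exactly zero mean.
* The Nyquist bin is zeroed as well: it carries no phase freedom for a real
  signal, and excluding it makes the discrete Parseval identity
  ``var(x) = sum_f A(f)**2 / 2`` exact over the positive bins.
* The inverse transform is scaled so that a single nonzero bin with
  amplitude ``A`` and phase ``theta`` yields ``A * cos(2*pi*f*t + theta)``.

Phases are the only source of randomness.  They are drawn either uniformly
on (-pi, pi] or from a von Mises distribution; the uniform case is realized
as von Mises with concentration ``kappa = 0`` so that both kinds consume the
random stream identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "SpectralSpec",
    "PhaseSpec",
    "AmplitudeSpectrum",
    "TimeSeries",
    "build_amplitude_spectrum",
    "sample_phases",
    "synthesize",
    "generate",
    "generate_grid",
]


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled real signal."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("a time series needs at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("time series contains non-finite samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.fs


@dataclass(frozen=True)
class SpectralSpec:
    """Prescription of a one-sided power-law spectrum.

    Parameters
    ----------
    offset : float
        Power at 1 Hz (``O`` in ``P(f) = O * f**-s``), arbitrary units, > 0.
    slope : float
        Power-law exponent ``s`` (dimensionless, >= 0).
    f0 : float
        Knee frequency in Hz; amplitudes below it are flattened to ``A(f0)``.
    ff : float
        Final frequency in Hz; amplitudes above it are zero.
    fs : float
        Sampling rate, Hz.
    duration : float
        Length of the signal in seconds; ``fs * duration`` must be a whole
        number of samples.
    """

    offset: float = 1.0
    slope: float = 1.0
    f0: float = 1.0
    ff: float | None = None
    fs: float = 1000.0
    duration: float = 5.0

    def __post_init__(self) -> None:
        ff = self.ff if self.ff is not None else self.fs / 2.0
        object.__setattr__(self, "ff", float(ff))
        if self.offset <= 0:
            raise ValueError("offset must be > 0")
        if self.slope < 0:
            raise ValueError("slope must be >= 0")
        if self.f0 <= 0:
            raise ValueError("f0 must be > 0")
        if self.f0 > self.ff:
            raise ValueError("f0 must not exceed ff")
        if self.ff > self.fs / 2.0 + 1e-12:
            raise ValueError("ff must not exceed the Nyquist frequency")
        n = self.fs * self.duration
        if n <= 0 or abs(n - round(n)) > 1e-9:
            raise ValueError("fs * duration must be a positive integer")

    @property
    def n(self) -> int:
        """Number of samples."""
        return int(round(self.fs * self.duration))

    @property
    def df(self) -> float:
        """Frequency resolution of the one-sided grid, Hz."""
        return 1.0 / self.duration


@dataclass(frozen=True)
class PhaseSpec:
    """How initial phases are drawn.

    ``kind='uniform'`` is equivalent to (and implemented as) a von Mises
    distribution with ``kappa = 0``.
    """

    kind: str = "uniform"
    kappa: float = 0.0
    mu: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "von_mises"):
            raise ValueError("kind must be 'uniform' or 'von_mises'")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")

    @property
    def effective_kappa(self) -> float:
        return 0.0 if self.kind == "uniform" else self.kappa


@dataclass(frozen=True)
class AmplitudeSpectrum:
    """One-sided amplitude spectrum on the rFFT grid of a SpectralSpec."""

    freqs: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        amps = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "amplitudes", amps)
        if freqs.shape != amps.shape:
            raise ValueError("freqs and amplitudes must have equal length")
        if np.any(amps < 0):
            raise ValueError("amplitudes must be non-negative")

    @property
    def n_positive(self) -> int:
        """Number of positive-frequency bins (excluding DC)."""
        return self.freqs.size - 1


def build_amplitude_spectrum(spec: SpectralSpec) -> AmplitudeSpectrum:
    """Amplitude spectrum ``A(f) = sqrt(O * f**-s)`` with knee and cutoff.

    ``A(f) = A(f0)`` for ``0 < f < f0``; ``A(f) = 0`` for ``f > ff``; the DC
    and Nyquist bins are zero (see module docstring).
    """
    n = spec.n
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.fs)
    amps = np.zeros_like(freqs)
    pos = freqs > 0
    f_eff = np.maximum(freqs[pos], spec.f0)  # flatten below the knee
    amps[pos] = np.sqrt(spec.offset * f_eff ** (-spec.slope))
    amps[freqs > spec.ff + 1e-12] = 0.0
    if n % 2 == 0:
        amps[-1] = 0.0  # Nyquist bin carries no phase freedom
    return AmplitudeSpectrum(freqs=freqs, amplitudes=amps)


def sample_phases(
    n_freqs: int,
    phase: PhaseSpec | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n_freqs`` initial phases in (-pi, pi].

    A generator may be passed explicitly (it takes precedence over
    ``phase.seed``), which lets callers thread one seeded stream through a
    whole experiment.
    """
    if n_freqs < 1:
        raise ValueError("n_freqs must be >= 1")
    phase = phase or PhaseSpec()
    if rng is None:
        rng = np.random.default_rng(phase.seed)
    theta = rng.vonmises(phase.mu, phase.effective_kappa, size=n_freqs)
    # numpy returns values in [-pi, pi]; fold the closed lower end.
    theta[theta <= -np.pi] = np.pi
    return theta


def synthesize(
    amps: AmplitudeSpectrum,
    phases: np.ndarray,
    spec: SpectralSpec,
) -> TimeSeries:
    """Inverse-transform an amplitude spectrum plus phases into a signal.

    ``phases`` must have one entry per positive-frequency bin (including the
    Nyquist bin, whose amplitude is zero by construction).
    """
    phases = np.asarray(phases, dtype=float)
    if phases.size != amps.n_positive:
        raise ValueError(
            f"expected {amps.n_positive} phases "
            f"(one per positive-frequency bin), got {phases.size}"
        )
    n = spec.n
    spectrum = np.zeros(amps.freqs.size, dtype=complex)
    spectrum[1:] = amps.amplitudes[1:] * np.exp(1j * phases)
    # scale so a lone bin of amplitude A yields A*cos(2 pi f t + theta)
    spectrum *= n / 2.0
    samples = np.fft.irfft(spectrum, n=n)
    return TimeSeries(samples=samples, fs=spec.fs)


def generate(
    spec: SpectralSpec,
    phase: PhaseSpec | None = None,
    rng: np.random.Generator | None = None,
) -> TimeSeries:
    """Convenience one-shot: spectrum -> phases -> signal."""
    amps = build_amplitude_spectrum(spec)
    phases = sample_phases(amps.n_positive, phase, rng=rng)
    return synthesize(amps, phases, spec)


def generate_grid(
    slopes: Sequence[float] | np.ndarray | None = None,
    spec: SpectralSpec | None = None,
    phase: PhaseSpec | None = None,
    seed: int = 0,
) -> list[tuple[float, TimeSeries]]:
    """One seeded signal per slope, sharing every other spectral parameter.

    The default grid is 256 slopes uniform on [0, 2] with ``f0 = 1`` Hz,
    5 s at 1 kHz.  Each slope gets its own child seed derived from ``seed``,
    so the output is reproducible bit for bit and independent of grid order.
    """
    if slopes is None:
        slopes = np.linspace(0.0, 2.0, 256)
    slopes = np.asarray(slopes, dtype=float)
    if slopes.size == 0:
        raise ValueError("slope grid is empty")
    if np.any(~np.isfinite(slopes)) or np.any(slopes < 0):
        raise ValueError("slopes must be finite and >= 0")
    spec = spec or SpectralSpec()
    phase = phase or PhaseSpec()
    out: list[tuple[float, TimeSeries]] = []
    for i, s in enumerate(slopes):
        child = np.random.default_rng(np.random.SeedSequence([seed, i]))
        spec_i = SpectralSpec(
            offset=spec.offset, slope=float(s), f0=spec.f0, ff=spec.ff,
            fs=spec.fs, duration=spec.duration,
        )
        out.append((float(s), generate(spec_i, phase, rng=child)))
    return out
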
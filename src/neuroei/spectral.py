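"""Welch spectral estimation and aperiodic (1/f) parameterization.

The aperiodic fit models ``log10 P(f)`` as a straight line in ``log10 f``
over a fixed band (30-80 Hz by default, where inhibitory tone most clearly
shapes the spectral decay of cortical field potentials).  Narrowband
oscillatory peaks are removed iteratively: after an ordinary least-squares
fit, points whose *positive* residual exceeds ``k`` standard deviations are
masked (peaks only add power) and the line is refit, until the mask is
stable or ``max_iter`` is reached.  The slope is reported as the positive
steepness ``s`` of ``P(f) ~ f**-s`` and the offset as the log10-power
intercept at 1 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .idft import TimeSeries

__all__ = ["PSDEstimate", "AperiodicFit", "welch_psd", "fit_aperiodic"]

DEFAULT_BAND = (30.0, 80.0)


@dataclass(frozen=True)
class PSDEstimate:
    """One-sided Welch power spectral density (units^2 / Hz)."""

    freqs: np.ndarray
    power: np.ndarray
    segment_length_s: float
    overlap_fraction: float
    taper_name: str = "hann"

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        power = np.asarray(self.power, dtype=float)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "power", power)
        if freqs.size != power.size:
            raise ValueError("freqs and power must have equal length")
        if np.any(np.diff(freqs) <= 0) or freqs[0] < 0:
            raise ValueError("freqs must be strictly increasing and >= 0")
        if np.any(power < 0):
            raise ValueError("power must be non-negative")


@dataclass(frozen=True)
class AperiodicFit:
    """Result of the iterative peak-masked log-log line fit."""

    offset: float
    slope: float
    band: tuple[float, float]
    n_points_used: int
    n_points_masked: int
    fit_r2: float

    @property
    def exponent(self) -> float:
        """Signed exponent of ``P(f) ~ f**exponent`` (i.e. ``-slope``)."""
        return -self.slope

    def predict_log10(self, freqs: np.ndarray) -> np.ndarray:
        return self.offset - self.slope * np.log10(np.asarray(freqs, dtype=float))


def welch_psd(
    ts: TimeSeries,
    segment_length_s: float = 1.0,
    overlap_fraction: float = 0.5,
    taper: str = "hann",
) -> PSDEstimate:
    """Averaged-periodogram PSD with tapered, overlapping segments.

    Frequency resolution is ``1 / segment_length_s``.
    """
    nperseg = int(round(segment_length_s * ts.fs))
    if nperseg < 2:
        raise ValueError("segment length too short for the sampling rate")
    if nperseg > ts.n:
        raise ValueError(
            f"segment of {nperseg} samples exceeds signal length {ts.n}"
        )
    if not (0 <= overlap_fraction < 1):
        raise ValueError("overlap_fraction must be in [0, 1)")
    freqs, power = sps.welch(
        ts.samples,
        fs=ts.fs,
        window=taper,
        nperseg=nperseg,
        noverlap=int(round(overlap_fraction * nperseg)),
        detrend="constant",
    )
    return PSDEstimate(
        freqs=freqs,
        power=power,
        segment_length_s=segment_length_s,
        overlap_fraction=overlap_fraction,
        taper_name=taper,
    )


def fit_aperiodic(
    psd: PSDEstimate,
    band: tuple[float, float] = DEFAULT_BAND,
    mask_threshold_sd: float = 2.0,
    max_iter: int = 5,
) -> AperiodicFit:
    """Iterative peak-masked line fit of log10 power on log10 frequency.

    Parameters
    ----------
    psd : PSDEstimate
    band : (fmin, fmax)
        Frequency band used for the fit, Hz.  Default 30-80 Hz.
    mask_threshold_sd : float
        Points with positive residual above this many SDs of the residuals
        are treated as oscillatory peaks and excluded on the next iteration.
    max_iter : int
        Maximum number of mask-and-refit passes.
    """
    fmin, fmax = band
    if not fmin < fmax:
        raise ValueError("band must satisfy fmin < fmax")
    in_band = (psd.freqs >= fmin) & (psd.freqs <= fmax) & (psd.power > 0)
    f = psd.freqs[in_band]
    p = psd.power[in_band]
    if f.size < 3:
        raise ValueError("need at least 3 in-band frequency points with power > 0")
    logf = np.log10(f)
    logp = np.log10(p)

    keep = np.ones(f.size, dtype=bool)
    coeffs = np.polyfit(logf, logp, 1)
    for _ in range(max_iter):
        resid = logp - np.polyval(coeffs, logf)
        sd = np.std(resid[keep])
        if sd == 0:
            break
        new_keep = ~(resid > mask_threshold_sd * sd)
        # never let the mask swallow the whole band
        if not new_keep.any():
            raise RuntimeError("band fully occupied by peaks")
        if np.array_equal(new_keep, keep):
            break
        keep = new_keep
        coeffs = np.polyfit(logf[keep], logp[keep], 1)

    pred = np.polyval(coeffs, logf[keep])
    ss_res = float(np.sum((logp[keep] - pred) ** 2))
    ss_tot = float(np.sum((logp[keep] - np.mean(logp[keep])) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return AperiodicFit(
        offset=float(coeffs[1]),
        slope=float(-coeffs[0]),
        band=(float(fmin), float(fmax)),
        n_points_used=int(keep.sum()),
        n_points_masked=int((~keep).sum()),
        fit_r2=r2,
    )
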
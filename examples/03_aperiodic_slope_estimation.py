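"""Estimate the 30-80 Hz aperiodic exponent of a noisy, peaky spectrum.

Builds a 1/f^1.5 surrogate, adds a strong 55 Hz oscillation, and shows
that the iterative peak-masked fit still recovers the background slope.
"""

import numpy as np

from neuroei import PhaseSpec, SpectralSpec, fit_aperiodic, generate, welch_psd
from neuroei.idft import TimeSeries

ts = generate(SpectralSpec(slope=1.5), PhaseSpec(seed=4))
osc = 0.4 * np.std(ts.samples) * np.sin(2 * np.pi * 55.0 * ts.times)
noisy = TimeSeries(samples=ts.samples + osc, fs=ts.fs)

for label, sig in [("clean", ts), ("with 55 Hz oscillation", noisy)]:
    fit = fit_aperiodic(welch_psd(sig))
    print(
        f"{label:>24}: slope = {fit.slope:.3f}, offset = {fit.offset:+.3f}, "
        f"masked points = {fit.n_points_masked}"
    )
print(
    "\nBoth estimates sit near the true exponent 1.5; the oscillation is"
    " removed by residual masking instead of biasing the fit."
)
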
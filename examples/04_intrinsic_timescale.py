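"""Intrinsic timescale (tau) from the autocorrelation function.

The timescale is the lag where the ACF decays to half its lag-0 value,
read off a quadratic fitted to the initial ACF segment.  Raising the knee
frequency f0 shortens the slowest power-law component and shrinks tau.
"""

from neuroei import tau_grids

table = tau_grids(
    slopes=(1.0, 2.0),
    f0_values=(1.0, 2.0, 5.0, 10.0),
    n_repetitions=10,
    seed=0,
)
print(table[["slope", "f0", "tau", "lzc"]].to_string(index=False))
print(
    "\ntau scales with the period 1/f0 of the slowest power-law component"
    " and grows with the spectral slope; LZc moves the opposite way."
)
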
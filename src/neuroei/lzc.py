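"""Median binarization and Lempel-Ziv-76 complexity.

A signal is reduced to a binary symbolic sequence (1 where a sample exceeds
the median of the whole analysis window, 0 otherwise) and parsed with the
exhaustive-history production rule of Lempel & Ziv (1976): the sequence is
scanned left to right, extending the current word for as long as it can be
reproduced by copying from earlier in the sequence (overlapping copies
allowed); each time the word becomes non-reproducible the production counter
``c`` increases and a new word starts.  The final word is counted whether or
not it is reproducible.

The normalized complexity is ``LZc = c * log2(n) / n``, which for long
random binary sequences approaches 1 (slightly exceeding it at finite
``n``; no clipping is applied) and approaches 0 for constant or strictly
periodic sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .idft import TimeSeries

__all__ = ["BinarySequence", "LZCResult", "binarize", "lz76_complexity", "lzc_normalized"]


@dataclass(frozen=True)
class BinarySequence:
    """An ordered sequence over {0, 1}."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.uint8)
        object.__setattr__(self, "bits", bits)
        if bits.size < 2:
            raise ValueError("binary sequence needs length >= 2")
        if not np.all((bits == 0) | (bits == 1)):
            raise ValueError("alphabet must be exactly {0, 1}")

    @property
    def n(self) -> int:
        return self.bits.size

    def to_string(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)


@dataclass(frozen=True)
class LZCResult:
    """LZ76 production count and its normalized value."""

    c: int
    lzc: float
    n: int


def binarize(ts: TimeSeries | np.ndarray) -> BinarySequence:
    """1 where the sample is strictly greater than the window median, else 0.

    Ties at the median map to 0.  The median is taken over the entire window
    passed in, so the result is invariant under any strictly increasing
    transform of the samples.
    """
    samples = ts.samples if isinstance(ts, TimeSeries) else np.asarray(ts, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least 2 samples")
    if not np.all(np.isfinite(samples)):
        raise ValueError("non-finite samples cannot be binarized")
    med = np.median(samples)
    return BinarySequence(bits=(samples > med).astype(np.uint8))


def lz76_complexity(b: BinarySequence | str) -> int:
    """Exhaustive-history LZ76 production count.

    The sequence is parsed word by word: the word starting at position
    ``l`` is extended while it remains reproducible, i.e. while it occurs
    somewhere starting before ``l`` (equivalently, while it is a substring
    of ``s[: l + k - 1]``, which allows overlapping self-copies); when the
    extension by one symbol breaks reproducibility a production ends and
    the next word starts after it.  The final, possibly still reproducible,
    word is counted.  Substring search runs at C speed via ``bytes.find``.
    """
    if isinstance(b, BinarySequence):
        s = b.bits.tobytes()
    else:
        s = str(b).encode("ascii")
        if len(s) == 0:
            raise ValueError("empty sequence")
        if set(s) - {ord("0"), ord("1")}:
            raise ValueError("alphabet must be exactly {0, 1}")
    n = len(s)
    c = 0
    l = 0
    while l < n:
        # k = length of the longest prefix of s[l:] copyable from a start < l
        # (the end bound l+k on find forces the occurrence to start at <= l-1
        # while still letting the copy overlap the word itself)
        k = 0
        while l + k + 1 <= n and s.find(s[l : l + k + 1], 0, l + k) != -1:
            k += 1
        c += 1
        l += k + 1  # the word includes its innovation symbol (if any)
    return c


def lzc_normalized(ts: TimeSeries | np.ndarray) -> LZCResult:
    """Normalized Lempel-Ziv complexity ``c * log2(n) / n`` of a signal."""
    seq = binarize(ts)
    n = seq.n
    if n < 100:
        import warnings

        warnings.warn(
            f"LZc on n={n} samples is strongly biased; use n >= 100",
            stacklevel=2,
        )
    c = lz76_complexity(seq)
    return LZCResult(c=c, lzc=c * np.log2(n) / n, n=n)
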
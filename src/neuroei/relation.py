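"""The empirical LZc-versus-slope law and its least-squares fit.

Across power-law surrogate signals, normalized Lempel-Ziv complexity falls
with the spectral exponent ``s`` along an x-inverted asymmetric sigmoid:

    LZc(s) = a1 * exp(-b * ln^2(s^c + 1))                     (variant "eq3")
    LZc(s) = a2 + (1 - a2) * exp(-b * ln^2(s^c + 1))          (variant "eq4")

``b`` and ``c`` shape the curve; ``a1`` scales its range down from [0, 1]
to [0, a1] (appropriate when a spectral cutoff ``ff`` compresses complexity
from above), while ``a2`` lifts the floor to (a2, 1] (appropriate when a
knee ``f0 > 1`` Hz keeps complexity away from zero).  With ``a2 = 0`` the
second form reduces to the first with ``a1 = 1``.  The logarithm inside the
law is natural; base-2 logs appear only in the LZc normalization itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "RelationParams",
    "default_variant",
    "eq3_lzc",
    "eq4_lzc",
    "fit_relation",
    "r_squared",
]


def default_variant(f0: float) -> str:
    """Which form fits a grid generated with knee frequency ``f0``.

    A knee above 1 Hz keeps complexity away from zero, so the floored form
    is appropriate; otherwise the scaled form is used.
    """
    return "eq4" if f0 > 1.0 else "eq3"


@dataclass(frozen=True)
class RelationParams:
    """Fitted parameters of the LZc(s) law."""

    variant: str
    a1: float | None
    a2: float | None
    b: float
    c: float
    r2: float

    def __post_init__(self) -> None:
        if self.variant not in ("eq3", "eq4"):
            raise ValueError("variant must be 'eq3' or 'eq4'")
        if (self.variant == "eq3") != (self.a1 is not None) or (
            self.variant == "eq4"
        ) != (self.a2 is not None):
            raise ValueError("exactly one of a1/a2 must be set, matching variant")
        if self.b <= 0 or self.c <= 0:
            raise ValueError("b and c must be > 0")

    def predict(self, slopes: np.ndarray) -> np.ndarray:
        if self.variant == "eq3":
            return eq3_lzc(slopes, self.a1, self.b, self.c)
        return eq4_lzc(slopes, self.a2, self.b, self.c)


def _core(s: np.ndarray, b: float, c: float) -> np.ndarray:
    return np.exp(-b * np.log(s**c + 1.0) ** 2)


def _check_slopes(s) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("slopes must be >= 0")
    return s


def eq3_lzc(s, a1: float, b: float, c: float):
    """Scaled form: range (0, a1]; LZc(0) = a1."""
    s = _check_slopes(s)
    if not (0 < a1 <= 1):
        raise ValueError("a1 must be in (0, 1]")
    if b <= 0 or c <= 0:
        raise ValueError("b and c must be > 0")
    return a1 * _core(s, b, c)


def eq4_lzc(s, a2: float, b: float, c: float):
    """Floored form: range (a2, 1]; LZc(0) = 1."""
    s = _check_slopes(s)
    if not (0 <= a2 < 1):
        raise ValueError("a2 must be in [0, 1)")
    if b <= 0 or c <= 0:
        raise ValueError("b and c must be > 0")
    return a2 + (1.0 - a2) * _core(s, b, c)


def r_squared(observed, predicted) -> float:
    """Coefficient of determination ``1 - SS_res / SS_tot``."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.size != p.size or o.size < 2:
        raise ValueError("observed and predicted must have equal length >= 2")
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed values have zero variance")
    ss_res = float(np.sum((o - p) ** 2))
    return 1.0 - ss_res / ss_tot


def fit_relation(
    slopes,
    lzcs,
    variant: str = "eq3",
    n_restarts: int = 3,
    seed: int = 0,
) -> RelationParams:
    """Bounded nonlinear least squares of the LZc(s) law.

    Starts from (a, b, c) = (1 or 0, 1, 2) and, to dodge the local minima a
    bounded fit can hit, retries from ``n_restarts`` jittered (b, c) starts,
    keeping the solution with the smallest residual sum of squares.
    """
    s = _check_slopes(slopes)
    y = np.asarray(lzcs, dtype=float)
    if s.size != y.size or s.size < 5:
        raise ValueError("need at least 5 paired (slope, lzc) points")
    if variant not in ("eq3", "eq4"):
        raise ValueError("variant must be 'eq3' or 'eq4'")

    if variant == "eq3":
        model = lambda x, a, b, c: eq3_lzc(x, a, b, c)  # noqa: E731
        bounds = ([1e-9, 1e-9, 1e-9], [1.0, np.inf, np.inf])
        p0_base = [1.0, 1.0, 2.0]
    else:
        model = lambda x, a, b, c: eq4_lzc(x, a, b, c)  # noqa: E731
        bounds = ([0.0, 1e-9, 1e-9], [1.0 - 1e-9, np.inf, np.inf])
        p0_base = [0.0, 1.0, 2.0]

    rng = np.random.default_rng(seed)
    starts = [p0_base]
    for _ in range(n_restarts):
        starts.append(
            [
                p0_base[0],
                float(np.exp(rng.uniform(np.log(0.2), np.log(5.0)))),
                float(np.exp(rng.uniform(np.log(0.5), np.log(4.0)))),
            ]
        )

    best, best_sse = None, np.inf
    errors = []
    for p0 in starts:
        try:
            popt, _ = curve_fit(
                model, s, y, p0=p0, bounds=bounds, maxfev=20000
            )
        except RuntimeError as exc:  # pragma: no cover - rare non-convergence
            errors.append(str(exc))
            continue
        sse = float(np.sum((y - model(s, *popt)) ** 2))
        if sse < best_sse:
            best, best_sse = popt, sse
    if best is None:
        raise RuntimeError(
            "relation fit failed to converge from any start: " + "; ".join(errors)
        )
    r2 = r_squared(y, model(s, *best))
    a, b, c = (float(v) for v in best)
    if variant == "eq3":
        return RelationParams(variant="eq3", a1=a, a2=None, b=b, c=c, r2=r2)
    return RelationParams(variant="eq4", a1=None, a2=a, b=b, c=c, r2=r2)
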
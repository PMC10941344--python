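"""Symbolic dynamics of RR-interval series.

An RR series is coarse-grained into integer symbols by one of three
quantization schemes, and every overlapping word of three consecutive
symbols is classified into one of four families:

* ``0V``  — no variation: all three symbols equal;
* ``1V``  — one variation: exactly one of the two successive differences
  is zero;
* ``2LV`` — two like variations: both differences nonzero with the same
  sign (an increasing or decreasing ramp);
* ``2UV`` — two unlike variations: both differences nonzero with opposite
  signs (a peak or a valley).

The 0V rate tracks sympathetic modulation and the 2UV rate vagal
modulation; the remaining families are computed for completeness.

Quantization schemes
--------------------
sigma
    Three levels around the series mean ``mu``: below ``(1-a)*mu``, within
    the inclusive band ``[(1-a)*mu, (1+a)*mu]``, and above ``(1+a)*mu``.
    The sigma rate ``a`` defaults to 0.05.  A four-level variant that
    additionally splits the middle band at ``mu`` is available behind
    ``four_level=True``.
max-min
    Uniform quantization of the observed range into ``levels`` equal bins
    (default 6), half-open lower-inclusive, with the maximum assigned to
    the top bin.  A constant series maps to symbol 0 everywhere.
equal probability
    Rank-based bins of (as near as possible) equal occupancy; level sizes
    differ by at most one, and ties are broken by original position so the
    output is deterministic.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core_io import RRISeries
from .errors import InsufficientDataError

SIGMA = "sigma"
MAXMIN = "maxmin"
EQUAL_PROBABILITY = "equal_probability"

FAMILIES = ("0V", "1V", "2LV", "2UV")


@dataclass(frozen=True)
class SymbolSeries:
    """Integer symbols produced by one quantization method."""

    symbols: np.ndarray
    method: str
    n_levels: int
    params: Mapping[str, float]

    def __post_init__(self) -> None:
        symbols = np.asarray(self.symbols, dtype=int)
        if symbols.size and (symbols.min() < 0 or symbols.max() >= self.n_levels):
            raise ValueError("symbols out of range for n_levels")
        object.__setattr__(self, "symbols", symbols)

    def __len__(self) -> int:
        return int(self.symbols.size)


@dataclass(frozen=True)
class WordFamilyRates:
    """Percentages of the four families among overlapping 3-symbol words."""

    p0v: float
    p1v: float
    p2lv: float
    p2uv: float
    n_words: int

    def as_dict(self) -> dict[str, float]:
        return {"0V": self.p0v, "1V": self.p1v, "2LV": self.p2lv, "2UV": self.p2uv}


def _values(series) -> np.ndarray:
    if isinstance(series, RRISeries):
        return series.values
    return np.asarray(series, dtype=float)


def symbolize_sigma(series, a: float = 0.05, four_level: bool = False) -> SymbolSeries:
    """Quantize around the mean with band half-width ``a * mu`` (sigma method)."""
    values = _values(series)
    if values.size == 0:
        raise InsufficientDataError("empty series")
    if a <= 0:
        raise ValueError("sigma rate a must be positive")
    mu = values.mean()
    lo, hi = (1.0 - a) * mu, (1.0 + a) * mu
    if four_level:
        symbols = np.select(
            [values < lo, values < mu, values <= hi], [0, 1, 2], default=3
        )
        n_levels = 4
    else:
        symbols = np.select([values < lo, values <= hi], [0, 1], default=2)
        n_levels = 3
    return SymbolSeries(symbols, SIGMA, n_levels, {"a": a})


def symbolize_maxmin(series, levels: int = 6) -> SymbolSeries:
    """Uniform quantization of the range [min, max] into ``levels`` bins."""
    values = _values(series)
    if values.size == 0:
        raise InsufficientDataError("empty series")
    if levels < 2:
        raise ValueError("levels must be >= 2")
    vmin, vmax = values.min(), values.max()
    if vmax == vmin:
        symbols = np.zeros(values.size, dtype=int)
    else:
        width = (vmax - vmin) / levels
        symbols = np.minimum((values - vmin) // width, levels - 1).astype(int)
    return SymbolSeries(symbols, MAXMIN, levels, {"xi": levels})


def symbolize_equal_probability(series, levels: int) -> SymbolSeries:
    """Rank-based quantization into ``levels`` near-equal-occupancy bins.

    With L points the level sizes are floor(L/levels) or ceil(L/levels);
    ties are broken by original position (stable sort).
    """
    values = _values(series)
    L = values.size
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if L < levels:
        raise InsufficientDataError(f"need at least {levels} beats, got {L}")
    order = np.argsort(values, kind="stable")
    ranks = np.empty(L, dtype=int)
    ranks[order] = np.arange(L)
    symbols = (ranks * levels) // L
    return SymbolSeries(symbols, EQUAL_PROBABILITY, levels, {"q": levels})


def classify_word(s1: int, s2: int, s3: int) -> str:
    """Classify one 3-symbol word into its variation family."""
    d1 = s2 - s1
    d2 = s3 - s2
    if d1 == 0 and d2 == 0:
        return "0V"
    if d1 == 0 or d2 == 0:
        return "1V"
    return "2LV" if d1 * d2 > 0 else "2UV"


def word_family_rates(symbols) -> WordFamilyRates:
    """Rates (%) of the four variation families over overlapping words.

    Accepts a :class:`SymbolSeries` or a plain integer sequence; a series
    of N symbols yields N-2 words.
    """
    s = symbols.symbols if isinstance(symbols, SymbolSeries) else np.asarray(symbols, dtype=int)
    if s.size < 3:
        raise InsufficientDataError(f"need at least 3 symbols, got {s.size}")
    d = np.diff(s)
    d1, d2 = d[:-1], d[1:]
    n_words = s.size - 2
    zero1, zero2 = d1 == 0, d2 == 0
    n0v = np.count_nonzero(zero1 & zero2)
    n1v = np.count_nonzero(zero1 ^ zero2)
    prod = d1 * d2
    n2lv = np.count_nonzero(prod > 0)
    n2uv = np.count_nonzero(prod < 0)
    scale = 100.0 / n_words
    return WordFamilyRates(
        p0v=n0v * scale, p1v=n1v * scale, p2lv=n2lv * scale, p2uv=n2uv * scale,
        n_words=n_words,
    )
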
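"""Poincare-plot heart-rate asymmetry (HRA) analysis.

The Poincare plot is the scatter of consecutive-interval pairs
(RR_i, RR_{i+1}); a series of N beats yields N-1 pairs.  A pair above the
identity line (RR_{i+1} > RR_i) is a *deceleration* of the heart, below
it an *acceleration*, on it *neutral*.

Variance partition
------------------
With m the series mean and, for each pair,

    d_i = (RR_{i+1} - RR_i) / sqrt(2)        (distance across identity)
    e_i = (RR_i + RR_{i+1} - 2 m) / sqrt(2)  (distance along identity)

second moments over the n pairs give the short- and long-term dispersions
SD1^2 = sum d_i^2 / n and SD2^2 = sum e_i^2 / n, split by pair kind:
decelerations and accelerations partition SD1^2 exactly (neutral pairs
have d_i = 0); for SD2^2 the neutral pairs' e_i^2 is shared half/half so
that SD2d^2 + SD2a^2 = SD2^2 holds exactly.  Contribution indices are the
normalized partitions (C1d = SD1d^2/SD1^2 etc.); Guzik's index GI is C1d.
Porta's index PI is the percentage of below-identity (acceleration)
points among the points off the identity line.

Because the partitions are plain second moments (not ellipse fits), the
additivity identities hold to machine precision; SD1/SD2 may differ
marginally from ellipse-fitting HRV software.

Run analysis
------------
Maximal blocks of consecutive pairs of the same kind are *runs*:
deceleration runs (DR), acceleration runs (AR) and neutral runs (NR),
counted by length.  Every successive difference belongs to exactly one
run, so the length-weighted counts sum to N-1.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .core_io import RRISeries
from .errors import InsufficientDataError, UndefinedIndexError

DECELERATION = "deceleration"
ACCELERATION = "acceleration"
NEUTRAL = "neutral"


@dataclass(frozen=True)
class PoincarePair:
    """One Poincare-plot point with its asymmetry classification."""

    x: float  # RR_i, ms
    y: float  # RR_{i+1}, ms
    kind: str


@dataclass(frozen=True)
class PoincareAsymmetry:
    """Variance partitions, contribution indices and Guzik/Porta indices.

    All dispersion fields are in ms; contribution indices are fractions in
    [0, 1] (NaN where the corresponding variance is zero); ``pi`` is a
    percentage.
    """

    sd1: float
    sd2: float
    sd1_d: float
    sd1_a: float
    sd2_d: float
    sd2_a: float
    sdnn_d: float
    sdnn_a: float
    c1_d: float
    c1_a: float
    c2_d: float
    c2_a: float
    c_d: float
    c_a: float
    gi: float  # Guzik's index = c1_d, fraction
    pi: float  # Porta's index, %
    n_pairs: int
    n_decel: int
    n_accel: int
    n_neutral: int

    def as_dict(self) -> dict[str, float]:
        return {
            "sd1": self.sd1, "sd2": self.sd2,
            "sd1_d": self.sd1_d, "sd1_a": self.sd1_a,
            "sd2_d": self.sd2_d, "sd2_a": self.sd2_a,
            "sdnn_d": self.sdnn_d, "sdnn_a": self.sdnn_a,
            "c1_d": self.c1_d, "c1_a": self.c1_a,
            "c2_d": self.c2_d, "c2_a": self.c2_a,
            "c_d": self.c_d, "c_a": self.c_a,
            "gi": self.gi, "pi": self.pi,
        }


@dataclass(frozen=True)
class RunsDistribution:
    """Counts of maximal monotonic runs by kind and length."""

    dr: Mapping[int, int]  # deceleration runs: length -> count
    ar: Mapping[int, int]  # acceleration runs
    nr: Mapping[int, int]  # neutral runs

    def counts(self, kind: str, max_length: int = 5) -> list[int]:
        """Counts for run lengths 1..max_length of one kind.

        Runs longer than ``max_length`` are *not* folded into the last
        bucket; they are simply not part of the truncated report.
        """
        table = {"dr": self.dr, "ar": self.ar, "nr": self.nr}[kind]
        return [table.get(k, 0) for k in range(1, max_length + 1)]

    @property
    def total_differences(self) -> int:
        """Length-weighted total over all runs; equals N-1."""
        return sum(k * c for m in (self.dr, self.ar, self.nr) for k, c in m.items())


def _pair_signs(values: np.ndarray) -> np.ndarray:
    """Sign of each successive difference: +1 decel, -1 accel, 0 neutral."""
    return np.sign(np.diff(values)).astype(int)


def poincare_pairs(series: RRISeries) -> list[PoincarePair]:
    """All (RR_i, RR_{i+1}) pairs, classified by kind, in beat order."""
    values = series.values
    if values.size < 2:
        raise InsufficientDataError("need at least 2 beats for Poincare pairs")
    kinds = {1: DECELERATION, -1: ACCELERATION, 0: NEUTRAL}
    signs = _pair_signs(values)
    return [
        PoincarePair(float(x), float(y), kinds[int(s)])
        for x, y, s in zip(values[:-1], values[1:], signs)
    ]


def asymmetry_descriptors(series: RRISeries) -> PoincareAsymmetry:
    """Compute the full Poincare asymmetry description of a series.

    Raises
    ------
    UndefinedIndexError
        If every pair is neutral (constant series): C1 indices, GI and PI
        are all undefined.
    """
    values = series.values
    if values.size < 3:
        raise InsufficientDataError("need at least 3 beats for asymmetry analysis")
    x, y = values[:-1], values[1:]
    n = x.size
    signs = _pair_signs(values)
    decel, accel, neutral = signs > 0, signs < 0, signs == 0
    n_decel = int(np.count_nonzero(decel))
    n_accel = int(np.count_nonzero(accel))
    n_neutral = int(np.count_nonzero(neutral))
    if n_decel + n_accel == 0:
        raise UndefinedIndexError("all pairs neutral: asymmetry indices undefined")

    m = values.mean()
    d2 = (y - x) ** 2 / 2.0
    e2 = (x + y - 2.0 * m) ** 2 / 2.0

    sd1_sq = d2.sum() / n
    sd1d_sq = d2[decel].sum() / n
    sd1a_sq = d2[accel].sum() / n
    sd2_sq = e2.sum() / n
    neutral_half = e2[neutral].sum() / 2.0
    sd2d_sq = (e2[decel].sum() + neutral_half) / n
    sd2a_sq = (e2[accel].sum() + neutral_half) / n
    sdnnd_sq = (sd1d_sq + sd2d_sq) / 2.0
    sdnna_sq = (sd1a_sq + sd2a_sq) / 2.0
    total_sq = (sd1_sq + sd2_sq) / 2.0

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else float("nan")

    c1_d = ratio(sd1d_sq, sd1_sq)
    c2_d = ratio(sd2d_sq, sd2_sq)
    c_d = ratio(sdnnd_sq, total_sq)
    return PoincareAsymmetry(
        sd1=float(np.sqrt(sd1_sq)),
        sd2=float(np.sqrt(sd2_sq)),
        sd1_d=float(np.sqrt(sd1d_sq)),
        sd1_a=float(np.sqrt(sd1a_sq)),
        sd2_d=float(np.sqrt(sd2d_sq)),
        sd2_a=float(np.sqrt(sd2a_sq)),
        sdnn_d=float(np.sqrt(sdnnd_sq)),
        sdnn_a=float(np.sqrt(sdnna_sq)),
        c1_d=c1_d,
        c1_a=ratio(sd1a_sq, sd1_sq),
        c2_d=c2_d,
        c2_a=ratio(sd2a_sq, sd2_sq),
        c_d=c_d,
        c_a=ratio(sdnna_sq, total_sq),
        gi=c1_d,
        pi=100.0 * n_accel / (n_decel + n_accel),
        n_pairs=n,
        n_decel=n_decel,
        n_accel=n_accel,
        n_neutral=n_neutral,
    )


def hra_present(asym: PoincareAsymmetry) -> bool:
    """Whether heart-rate asymmetry is present: C1d > C1a and C2a > C2d."""
    return bool(asym.c1_d > asym.c1_a and asym.c2_a > asym.c2_d)


def run_distribution(series: RRISeries) -> RunsDistribution:
    """Count maximal runs of consecutive same-kind pairs by kind and length.

    All lengths are retained; truncation to the reported 1..5 range happens
    only in :meth:`RunsDistribution.counts`.
    """
    values = series.values
    if values.size < 2:
        raise InsufficientDataError("need at least 2 beats for run analysis")
    signs = _pair_signs(values)
    tables: dict[int, dict[int, int]] = {1: {}, -1: {}, 0: {}}
    start = 0
    for i in range(1, signs.size + 1):
        if i == signs.size or signs[i] != signs[start]:
            length = i - start
            table = tables[int(signs[start])]
            table[length] = table.get(length, 0) + 1
            start = i
    return RunsDistribution(dr=tables[1], ar=tables[-1], nr=tables[0])


def export_pairs(series: RRISeries, destination) -> None:
    """Write the classified Poincare points as CSV (x, y, kind)."""
    pairs = poincare_pairs(series)
    own = not hasattr(destination, "write")
    stream = open(destination, "w", encoding="utf-8", newline="") if own else destination
    try:
        writer = csv.writer(stream, lineterminator="\n")
        writer.writerow(["x_ms", "y_ms", "kind"])
        for p in pairs:
            writer.writerow([repr(p.x), repr(p.y), p.kind])
    finally:
        if own:
            stream.close()
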
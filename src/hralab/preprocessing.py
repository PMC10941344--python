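"""Artifact screening, interpolation-based correction and stationarity.

Detection uses two conservative, configurable rules rather than a full
artifact taxonomy (thresholds for which vary across devices): a
physiological range gate and a deviation gate against a centred running
median.  Detected beats are labelled ``technical_artifact``; correction
replaces labelled beats by interpolation over neighbouring normal beats
on the beat-index axis and relabels them ``interpolated``.

Stationarity of a full recording is screened with the Augmented
Dickey-Fuller unit-root test (constant-only regression, since series are
short and deliberately not detrended); it is reported, never used to gate
an analysis.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import median_filter
from statsmodels.tsa.stattools import adfuller

from .core_io import (
    ECTOPIC,
    INTERPOLATED,
    NORMAL,
    RRISeries,
    TECHNICAL_ARTIFACT,
)
from .errors import DegenerateInputError, InsufficientDataError, QualityError


@dataclass(frozen=True)
class ArtifactRule:
    """Two-rule artifact detector configuration.

    A beat is flagged when it falls outside ``[min_rr, max_rr]`` ms or
    deviates from the centred running median (window ``local_window``
    beats) by more than ``max_rel_change`` of that median.
    """

    min_rr: float = 300.0
    max_rr: float = 2000.0
    max_rel_change: float = 0.30
    local_window: int = 11

    def __post_init__(self) -> None:
        if not (0 < self.min_rr < self.max_rr):
            raise ValueError("need 0 < min_rr < max_rr")
        if not (0 < self.max_rel_change < 1):
            raise ValueError("max_rel_change must lie in (0, 1)")
        if self.local_window < 3 or self.local_window % 2 == 0:
            raise ValueError("local_window must be odd and >= 3")


@dataclass(frozen=True)
class StationarityResult:
    """Augmented Dickey-Fuller screening outcome for one recording."""

    statistic: float
    p_value: float
    n_lags: int
    stationary: bool  # p_value < alpha


def detect_artifacts(series: RRISeries, rule: ArtifactRule | None = None) -> RRISeries:
    """Label suspect beats ``technical_artifact``; other labels unchanged.

    Only beats currently labelled ``normal`` can be flagged, which makes
    detection idempotent and preserves upstream ``ectopic`` or
    ``interpolated`` annotations.
    """
    rule = rule or ArtifactRule()
    values = series.values
    if values.size < rule.local_window:
        raise InsufficientDataError(
            f"need at least {rule.local_window} beats, got {values.size}"
        )
    local_med = median_filter(values, size=rule.local_window, mode="nearest")
    suspect = (
        (values < rule.min_rr)
        | (values > rule.max_rr)
        | (np.abs(values - local_med) / local_med > rule.max_rel_change)
    )
    labels = series.labels.copy()
    labels[suspect & (labels == NORMAL)] = TECHNICAL_ARTIFACT
    return series.with_values(values.copy(), labels)


def correct_artifacts(
    series: RRISeries,
    max_fraction: float = 0.05,
    cubic_min_side: int = 4,
) -> RRISeries:
    """Replace labelled beats by interpolation over normal neighbours.

    Interpolation is on the beat-index axis.  A cubic spline through the
    normal beats is used for a gap flanked by at least ``cubic_min_side``
    normal beats on each side; otherwise the replacement is linear between
    the nearest normal neighbours (edge gaps clamp to the nearest normal
    value).  Normal beats are returned bit-identical; replaced beats are
    relabelled ``interpolated``.

    Raises
    ------
    QualityError
        If more than ``max_fraction`` of beats are labelled: such a
        recording is rejected rather than repaired.
    """
    labels = series.labels
    bad = (labels == TECHNICAL_ARTIFACT) | (labels == ECTOPIC)
    n_bad = int(np.count_nonzero(bad))
    if n_bad == 0:
        return series
    n = len(series)
    if n_bad / n > max_fraction:
        raise QualityError(
            f"{n_bad}/{n} beats labelled ({100 * n_bad / n:.1f}% > "
            f"{100 * max_fraction:.1f}%): recording rejected"
        )
    good_idx = np.flatnonzero(~bad)
    if good_idx.size < 2:
        raise InsufficientDataError("need at least 2 normal beats to interpolate")
    good_vals = series.values[good_idx]
    bad_idx = np.flatnonzero(bad)

    new_values = series.values.copy()
    linear = np.interp(bad_idx, good_idx, good_vals)
    spline = CubicSpline(good_idx, good_vals) if good_idx.size >= 4 else None
    left_counts = np.searchsorted(good_idx, bad_idx)
    for j, i in enumerate(bad_idx):
        n_left = left_counts[j]
        n_right = good_idx.size - n_left
        if spline is not None and n_left >= cubic_min_side and n_right >= cubic_min_side:
            new_values[i] = float(spline(i))
        else:
            new_values[i] = linear[j]
    new_labels = labels.copy()
    new_labels[bad] = INTERPOLATED
    return series.with_values(new_values, new_labels)


def assess_stationarity(series: RRISeries, alpha: float = 0.05) -> StationarityResult:
    """Screen a full RR series with the Augmented Dickey-Fuller test.

    Constant-only regression; lag order chosen by AIC up to the Schwert
    bound ``floor(12 * (N/100) ** 0.25)``.  ``stationary`` is the unit-root
    rejection at ``alpha``.
    """
    values = series.values
    if values.size < 30:
        raise InsufficientDataError(f"need at least 30 beats for ADF, got {values.size}")
    if np.ptp(values) == 0:
        raise DegenerateInputError("ADF test undefined on a constant series")
    maxlag = int(np.floor(12.0 * (values.size / 100.0) ** 0.25))
    stat, p_value, n_lags, *_ = adfuller(
        values, maxlag=maxlag, regression="c", autolag="AIC"
    )
    return StationarityResult(
        statistic=float(stat),
        p_value=float(p_value),
        n_lags=int(n_lags),
        stationary=bool(p_value < alpha),
    )
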
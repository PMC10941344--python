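"""Heart rate and linear time-domain HRV metrics.

Conventions (stated because HRV software packages differ):

* SDNN uses the sample standard deviation (denominator N-1).
* RMSSD averages the squared successive differences over their count
  (N-1 differences for N beats).
* pNN50 counts differences strictly greater than 50 ms.
* HRmin/HRmax default to instantaneous per-beat heart rate (a moving
  average over ``hr_window`` beats is available but off by default).
* No detrending is applied anywhere: trends carry physiological
  information under non-stationary conditions and are analysed as-is.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import RRISeries
from .errors import InsufficientDataError


@dataclass(frozen=True)
class TimeDomainSummary:
    """Time-domain summary of one RR series window."""

    n_beats: int
    hr_mean: float  # bpm, 60000 / mean RR
    hr_min: float  # bpm
    hr_max: float  # bpm
    mrr: float  # ms
    sdnn: float  # ms
    rmssd: float  # ms
    ln_rmssd: float  # dimensionless; NaN when rmssd == 0
    pnn50: float  # %

    def as_dict(self) -> dict[str, float]:
        return {
            "n_beats": self.n_beats,
            "hr_mean": self.hr_mean,
            "hr_min": self.hr_min,
            "hr_max": self.hr_max,
            "mrr": self.mrr,
            "sdnn": self.sdnn,
            "rmssd": self.rmssd,
            "ln_rmssd": self.ln_rmssd,
            "pnn50": self.pnn50,
        }


def time_domain_summary(series: RRISeries, hr_window: int = 1) -> TimeDomainSummary:
    """Compute the time-domain summary of a (windowed) RR series.

    Parameters
    ----------
    series
        RR intervals in ms; at least 3 beats.
    hr_window
        Width in beats of the moving average applied to instantaneous
        heart rate before taking HRmin/HRmax.  1 (default) means raw
        per-beat heart rate.
    """
    values = series.values
    n = values.size
    if n < 3:
        raise InsufficientDataError(f"need at least 3 beats, got {n}")
    if hr_window < 1 or hr_window > n:
        raise ValueError("hr_window must lie in [1, n_beats]")

    mrr = float(values.mean())
    hr_mean = 60000.0 / mrr
    hr_inst = 60000.0 / values
    if hr_window > 1:
        kernel = np.full(hr_window, 1.0 / hr_window)
        hr_smooth = np.convolve(hr_inst, kernel, mode="valid")
    else:
        hr_smooth = hr_inst
    diffs = np.diff(values)
    rmssd = float(np.sqrt(np.mean(diffs**2)))
    return TimeDomainSummary(
        n_beats=int(n),
        hr_mean=hr_mean,
        hr_min=float(hr_smooth.min()),
        hr_max=float(hr_smooth.max()),
        mrr=mrr,
        sdnn=float(values.std(ddof=1)),
        rmssd=rmssd,
        ln_rmssd=float(np.log(rmssd)) if rmssd > 0 else float("nan"),
        pnn50=float(100.0 * np.count_nonzero(np.abs(diffs) > 50.0) / diffs.size),
    )
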
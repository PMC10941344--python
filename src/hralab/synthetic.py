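"""Synthetic RR-interval series and cohorts.

The generator is a beat-domain additive model, not a physiological
cardiac model: each beat's RR interval is a baseline plus a linear trend,
a respiratory sinus arrhythmia (RSA) oscillation, a slower low-frequency
(LF, ~0.1 Hz) oscillation and white Gaussian noise, evaluated at the
beat's onset time.  This is sufficient to exercise every estimator in the
package (means, dispersions, symbolic patterns, asymmetry and run
statistics, stationarity screening) with known ground truth, while making
no claim of baroreflex realism.

Asymmetry is injected by skewing the RSA waveform: the skewed wave

    s_kappa(theta) = sin(theta + kappa * sin(theta))

rises steeply and falls slowly for kappa > 0 (and conversely for
kappa < 0), so positive kappa produces fewer, larger beat-to-beat RR
prolongations — shifting Guzik's index above 0.5 — while kappa = 0
recovers a plain sine and a symmetric series.

Condition presets take their scales (baseline RR, respiratory rate,
oscillation amplitudes, trend sign) from resting supine physiology,
isometric-handgrip sympathetic stimulation and early recovery in adult
endurance athletes: mean RR near 936/801/935 ms and respiratory rates
near 11/13/12 breaths/min for rest/stimulation/recovery respectively.

All randomness flows from an explicit integer seed per call; there is no
global random state.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core_io import (
    CONDITIONS,
    NORMAL,
    RECOVERY,
    REST,
    SNSA_STIM,
    ConditionRecording,
    RRISeries,
    SubjectRecord,
)
from .errors import GenerationError


@dataclass(frozen=True)
class TachogramModel:
    """Parameters of one synthetic RR series.

    Units: ``m``, ``a_resp``, ``a_lf``, ``sigma_n`` in ms; ``f_resp`` and
    ``f_lf`` in Hz; ``trend`` in ms/s; ``kappa`` dimensionless in (-1, 1);
    ``duration_s`` in seconds.
    """

    m: float = 900.0
    a_resp: float = 40.0
    f_resp: float = 11.0 / 60.0
    a_lf: float = 20.0
    f_lf: float = 0.1
    sigma_n: float = 8.0
    trend: float = 0.0
    kappa: float = 0.0
    duration_s: float = 360.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ValueError("baseline m must be positive")
        if min(self.a_resp, self.a_lf, self.sigma_n) < 0:
            raise ValueError("amplitudes and noise SD must be non-negative")
        if not (0 < self.f_resp < 0.6):
            raise ValueError("f_resp must lie in (0, 0.6) Hz")
        if not (-1 < self.kappa < 1):
            raise ValueError("kappa must lie in (-1, 1)")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


@dataclass(frozen=True)
class CohortModel:
    """Parameters of a synthetic cohort with planted covariate couplings.

    ``m_sd``/``a_resp_sd``/``resp_rate_sd`` are between-subject jitter
    SDs applied to the per-condition preset templates.  ``career_mean``/
    ``career_sd`` parameterize career duration in years.  ``coupling``
    scales how strongly a subject's (standardized) career duration drives
    the magnitude of that subject's stimulation response: negative values
    plant a negative career-versus-stimulation-delta association (shorter
    careers -> larger responses), zero plants none.
    """

    n_subjects: int = 9
    m_sd: float = 40.0
    a_resp_sd: float = 8.0
    resp_rate_sd: float = 1.5  # breaths/min
    career_mean: float = 6.4
    career_sd: float = 4.2
    coupling: float = 0.0
    duration_s: float = 360.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        if min(self.m_sd, self.a_resp_sd, self.resp_rate_sd, self.career_sd) < 0:
            raise ValueError("variation SDs must be non-negative")


def skewed_wave(theta: np.ndarray | float, kappa: float) -> np.ndarray | float:
    """Phase-warped sine with asymmetric rise/fall; kappa = 0 is sin."""
    return np.sin(theta + kappa * np.sin(theta))


def dominant_frequency(series: RRISeries, fs: float = 4.0, f_min: float = 0.05) -> float:
    """Frequency (Hz) of the tachogram's dominant oscillation above ``f_min``.

    The irregularly sampled RR series is linearly interpolated onto a
    uniform ``fs``-Hz grid, mean-removed, and the periodogram peak above
    ``f_min`` is returned.  Used to verify that the generator's planted
    respiratory frequency is recoverable.
    """
    from scipy.signal import periodogram

    t = series.onset_times
    grid = np.arange(0.0, t[-1], 1.0 / fs)
    resampled = np.interp(grid, t, series.values)
    freqs, power = periodogram(resampled - resampled.mean(), fs=fs)
    keep = freqs >= f_min
    return float(freqs[keep][np.argmax(power[keep])])


def generate_rr(model: TachogramModel) -> RRISeries:
    """Generate one RR series beat by beat from the additive model.

    Beat i at onset t_i (t_1 = 0) has

        RR_i = m + trend * t_i + a_resp * s_kappa(2 pi f_resp t_i)
             + a_lf * sin(2 pi f_lf t_i + phi) + eps_i

    with eps_i ~ N(0, sigma_n^2) and phi a seeded uniform phase; the next
    onset is t_i + RR_i / 1000, and generation stops when a beat would end
    beyond ``duration_s``.  A parameter set that yields RR <= 0 raises
    :class:`GenerationError` naming the offending beat.
    """
    rng = np.random.default_rng(model.seed)
    phi = rng.uniform(0, 2 * math.pi) if model.a_lf > 0 else 0.0
    values: list[float] = []
    t = 0.0
    while True:
        rr = (
            model.m
            + model.trend * t
            + model.a_resp * float(skewed_wave(2 * math.pi * model.f_resp * t, model.kappa))
            + model.a_lf * math.sin(2 * math.pi * model.f_lf * t + phi)
        )
        if model.sigma_n > 0:
            rr += rng.normal(0.0, model.sigma_n)
        if rr < 1.0:
            # at RR <= 0 the model is invalid outright; just above 0 the
            # beat clock advances by RR/1000 so RR decays geometrically
            # without ever crossing zero — treat sub-ms intervals as the
            # same degenerate regime instead of looping forever
            raise GenerationError(
                f"beat {len(values) + 1} at t={t:.3f}s has RR={rr:.3f} ms < 1 ms"
            )
        if t + rr / 1000.0 > model.duration_s:
            break
        values.append(rr)
        t += rr / 1000.0
    return RRISeries(values=np.asarray(values))


_PRESETS: Mapping[str, TachogramModel] = {
    # Rest: long RR, slow breathing, ample RSA, stationary, mild
    # deceleration dominance as seen in healthy supine subjects.
    REST: TachogramModel(
        m=936.0, a_resp=42.0, f_resp=11.0 / 60.0, a_lf=25.0,
        sigma_n=9.0, trend=0.0, kappa=0.08, duration_s=360.0,
    ),
    # Sympathetic stimulation: shorter RR, faster breathing, damped RSA,
    # progressive RR shortening (non-stationary), acceleration dominance.
    SNSA_STIM: TachogramModel(
        m=833.0, a_resp=20.0, f_resp=13.0 / 60.0, a_lf=18.0,
        sigma_n=7.0, trend=-0.15, kappa=-0.08, duration_s=360.0,
    ),
    # Recovery: RR climbing back toward rest (positive trend), RSA
    # rebounding beyond rest, renewed deceleration dominance.
    RECOVERY: TachogramModel(
        m=903.0, a_resp=48.0, f_resp=12.0 / 60.0, a_lf=25.0,
        sigma_n=9.0, trend=0.15, kappa=0.12, duration_s=360.0,
    ),
}


def condition_preset(name: str) -> TachogramModel:
    """Template model for one study condition (rest/snsa_stim/recovery)."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown condition {name!r}; expected one of {CONDITIONS}") from None


def inject_artifacts(
    series: RRISeries,
    rate: float,
    kinds: Sequence[str] = ("spike", "ectopic"),
    seed: int = 0,
) -> tuple[RRISeries, np.ndarray]:
    """Perturb a seeded subset of beats with technical/ectopic artifacts.

    ``round(rate * N)`` interior beats (never the first or last, never
    adjacent) are perturbed: a ``spike`` replaces the RR value with one
    outside the physiological range; an ``ectopic`` halves the RR and
    scales the following beat by 1.5 (a premature beat with a compensatory
    pause).  Labels are left ``normal`` — detection is the job of the
    preprocessing stage.  Returns the perturbed series and the sorted
    ground-truth indices of directly perturbed beats.
    """
    if not (0 <= rate <= 0.05):
        raise ValueError("artifact rate must lie in [0, 0.05]")
    if not kinds:
        raise ValueError("kinds must be non-empty")
    n = len(series)
    k = int(round(rate * n))
    if k == 0:
        return series, np.empty(0, dtype=int)
    rng = np.random.default_rng(seed)
    candidates = np.arange(1, n - 1)
    while True:  # resample until no two targets are adjacent (seeded, terminates fast)
        chosen = np.sort(rng.choice(candidates, size=k, replace=False))
        if k == 1 or np.min(np.diff(chosen)) >= 2:
            break
    values = series.values.copy()
    for i in chosen:
        kind = kinds[int(rng.integers(len(kinds)))]
        if kind == "spike":
            values[i] = 250.0 if rng.random() < 0.5 else 2200.0
        elif kind == "ectopic":
            values[i] *= 0.5
            values[i + 1] *= 1.5
        else:
            raise ValueError(f"unknown artifact kind {kind!r}")
    return series.with_values(values), chosen


def generate_cohort(model: CohortModel) -> list[SubjectRecord]:
    """Generate a complete synthetic cohort of three-condition subjects.

    Each subject's recordings are drawn from the condition presets with
    between-subject jitter on baseline RR, RSA amplitude and respiratory
    rate.  With nonzero ``coupling`` the subject's standardized career
    duration multiplies the stimulation response (extra beat-to-beat noise
    and RSA damping during ``snsa_stim``): ``coupling < 0`` makes
    shorter-career subjects respond more strongly, planting a negative
    Spearman correlation between career duration and stimulation-induced
    deltas of alternation-driven metrics (e.g. the count of length-1
    acceleration runs).
    """
    rng = np.random.default_rng(model.seed)
    careers = np.maximum(
        rng.normal(model.career_mean, model.career_sd, size=model.n_subjects), 0.5
    )
    z = (careers - careers.mean()) / careers.std() if careers.std() > 0 else np.zeros_like(careers)
    subjects: list[SubjectRecord] = []
    for j in range(model.n_subjects):
        subject_id = f"subj{j + 1:02d}"
        # Stimulation response magnitude: 1 + coupling * z is clipped away
        # from zero so responses stay physiological and rank order follows z.
        response = float(np.clip(1.0 + model.coupling * z[j], 0.15, 2.5))
        recordings: dict[str, ConditionRecording] = {}
        for condition in CONDITIONS:
            preset = condition_preset(condition)
            m = preset.m + rng.normal(0.0, model.m_sd)
            a_resp = max(preset.a_resp + rng.normal(0.0, model.a_resp_sd), 2.0)
            sigma_n = preset.sigma_n
            kappa = preset.kappa
            if condition == SNSA_STIM:
                # The stimulation response scales beat-to-beat noise up and
                # damps RSA: strong responders alternate more (more AR1).
                sigma_n = preset.sigma_n * (0.4 + 1.6 * response)
                a_resp = max(a_resp / (0.5 + response), 2.0)
            tach = TachogramModel(
                m=m, a_resp=a_resp, f_resp=preset.f_resp, a_lf=preset.a_lf,
                f_lf=preset.f_lf, sigma_n=sigma_n, trend=preset.trend,
                kappa=kappa, duration_s=model.duration_s,
                seed=int(rng.integers(2**31 - 1)),
            )
            series = generate_rr(tach)
            series = RRISeries(
                values=series.values, labels=series.labels,
                subject_id=subject_id, condition=condition,
            )
            resp_rate = float(
                np.clip(preset.f_resp * 60.0 + rng.normal(0.0, model.resp_rate_sd), 4.0, 40.0)
            )
            recordings[condition] = ConditionRecording(
                series=series, resp_rate=resp_rate, duration_s=model.duration_s
            )
        subjects.append(
            SubjectRecord(
                subject_id=subject_id,
                rest=recordings[REST],
                snsa_stim=recordings[SNSA_STIM],
                recovery=recordings[RECOVERY],
                career_duration=float(careers[j]),
            )
        )
    return subjects
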
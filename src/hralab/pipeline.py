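"""Windowing, per-recording analysis and cohort orchestration.

Short-term analysis uses a 5-min window from each 6-min recording
(default: the final five minutes, discarding the first settling minute;
configurable).  Ultra-short-term analysis uses named 1-min windows: the
fifth minute of rest and of sympathetic stimulation, and the first,
second and third minutes of recovery.  Window membership is by beat onset
time, half-open ``[start, start + length)``, so consecutive windows
partition a recording's beats without duplication or loss.

Stationarity of the full recording is attached to every row as metadata
and never gates any computation: non-stationary series are analysed
deliberately, with the flag available for interpretation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import group_stats, hra, symbolic, time_domain
from .core_io import (
    CONDITIONS,
    RECOVERY,
    REST,
    SNSA_STIM,
    ConditionRecording,
    RRISeries,
    SubjectRecord,
    read_tachogram,
    write_metrics_table,
)
from .errors import (
    CohortSizeError,
    DegenerateInputError,
    HRALabError,
    InsufficientDataError,
    UndefinedIndexError,
    WindowBoundsError,
)
from .preprocessing import (
    ArtifactRule,
    assess_stationarity,
    correct_artifacts,
    detect_artifacts,
)

logger = logging.getLogger(__name__)

SHORT_TERM = "short_term"
ULTRA_SHORT = "ultra_short"

#: Named 1-min windows per condition: minute numbers are 1-based.
ULTRA_MINUTES: Mapping[str, tuple[int, ...]] = {
    REST: (5,),
    SNSA_STIM: (5,),
    RECOVERY: (1, 2, 3),
}

#: File-name stems used in cohort input/output directories.
CONDITION_FILES = {REST: "rest.txt", SNSA_STIM: "stim.txt", RECOVERY: "recovery.txt"}


@dataclass(frozen=True)
class WindowSpec:
    """One analysis window within a recording."""

    mode: str  # short_term | ultra_short
    start_s: float
    length_s: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.start_s < 0 or self.length_s <= 0:
            raise ValueError("start_s must be >= 0 and length_s > 0")


@dataclass(frozen=True)
class AnalysisConfig:
    """Flat, file-loadable configuration for the whole pipeline."""

    artifact_min_rr: float = 300.0
    artifact_max_rr: float = 2000.0
    artifact_max_rel_change: float = 0.30
    artifact_local_window: int = 11
    artifact_max_fraction: float = 0.05
    stationarity_alpha: float = 0.05
    sigma_a: float = 0.05
    maxmin_levels: int = 6
    eqprob_levels: tuple[int, ...] = (4, 6)
    hr_window: int = 1
    short_window_length_s: float = 300.0
    short_window_start_s: float | None = None  # None: final 5 min of recording
    ultra_window_length_s: float = 60.0

    _KEYMAP = {
        "artifact.min_rr": "artifact_min_rr",
        "artifact.max_rr": "artifact_max_rr",
        "artifact.max_rel_change": "artifact_max_rel_change",
        "artifact.local_window": "artifact_local_window",
        "artifact.max_fraction": "artifact_max_fraction",
        "stationarity.alpha": "stationarity_alpha",
        "symbolic.sigma_a": "sigma_a",
        "symbolic.maxmin_levels": "maxmin_levels",
        "symbolic.eqprob_levels": "eqprob_levels",
        "time_domain.hr_window": "hr_window",
        "window.short_length_s": "short_window_length_s",
        "window.short_start_s": "short_window_start_s",
        "window.ultra_length_s": "ultra_window_length_s",
    }

    @property
    def artifact_rule(self) -> ArtifactRule:
        return ArtifactRule(
            min_rr=self.artifact_min_rr,
            max_rr=self.artifact_max_rr,
            max_rel_change=self.artifact_max_rel_change,
            local_window=self.artifact_local_window,
        )

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        """Load a flat key-value YAML file (dotted keys per module)."""
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key, value in raw.items():
            if key not in cls._KEYMAP:
                raise KeyError(f"unknown config key {key!r}")
            name = cls._KEYMAP[key]
            if name == "eqprob_levels":
                value = tuple(int(v) for v in value)
            kwargs[name] = value
        return cls(**kwargs)


def short_term_window(recording: ConditionRecording, config: AnalysisConfig) -> WindowSpec:
    """The 5-min short-term window (default: final 5 min of the recording)."""
    length = config.short_window_length_s
    if config.short_window_start_s is not None:
        start = config.short_window_start_s
    else:
        start = max(recording.duration_s - length, 0.0)
    return WindowSpec(mode=SHORT_TERM, start_s=start, length_s=length, label="5min")


def ultra_short_windows(condition: str, config: AnalysisConfig) -> list[WindowSpec]:
    """The named 1-min windows for a condition (minute numbers 1-based)."""
    length = config.ultra_window_length_s
    return [
        WindowSpec(
            mode=ULTRA_SHORT, start_s=(minute - 1) * length, length_s=length,
            label=f"min{minute}",
        )
        for minute in ULTRA_MINUTES[condition]
    ]


def extract_window(recording: ConditionRecording, spec: WindowSpec) -> RRISeries:
    """Beats whose onset time lies in ``[start_s, start_s + length_s)``."""
    if spec.start_s + spec.length_s > recording.duration_s + 1e-9:
        raise WindowBoundsError(
            f"window [{spec.start_s}, {spec.start_s + spec.length_s}) s exceeds "
            f"recording of {recording.duration_s} s"
        )
    series = recording.series
    onsets = series.onset_times
    mask = (onsets >= spec.start_s) & (onsets < spec.start_s + spec.length_s)
    return RRISeries(
        values=series.values[mask],
        labels=series.labels[mask],
        subject_id=series.subject_id,
        condition=series.condition,
    )


_HRA_NAN = {k: float("nan") for k in (
    "sd1", "sd2", "sd1_d", "sd1_a", "sd2_d", "sd2_a", "sdnn_d", "sdnn_a",
    "c1_d", "c1_a", "c2_d", "c2_a", "c_d", "c_a", "gi", "pi",
)}


def analyze_recording(
    recording: ConditionRecording,
    window: WindowSpec,
    config: AnalysisConfig | None = None,
    subject_id: str | None = None,
) -> dict[str, object]:
    """Compute every per-window metric as one flat row.

    The row holds the time-domain summary, the word-family rates of all
    three symbolization methods, the Poincare asymmetry descriptors, the
    run counts (lengths 1-5 plus NR1), the respiratory rate and the
    full-recording stationarity screen.  When every Poincare pair is
    neutral the asymmetry fields are NaN and ``hra_defined`` is False.
    Errors from individual stages propagate annotated with the stage name.
    """
    config = config or AnalysisConfig()
    series = recording.series
    row: dict[str, object] = {
        "subject_id": subject_id if subject_id is not None else series.subject_id,
        "condition": series.condition,
        "window": window.label or window.mode,
    }

    def stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except HRALabError as exc:
            raise type(exc)(f"[{name}] {exc}") from exc

    windowed = stage("window", extract_window, recording, window)
    flagged = stage("detect", detect_artifacts, windowed, config.artifact_rule)
    clean = stage("correct", correct_artifacts, flagged, config.artifact_max_fraction)

    td = stage("time_domain", time_domain.time_domain_summary, clean, config.hr_window)
    row.update(td.as_dict())

    sym_sets = [("sigma", symbolic.symbolize_sigma(clean, config.sigma_a)),
                ("maxmin", symbolic.symbolize_maxmin(clean, config.maxmin_levels))]
    for q in config.eqprob_levels:
        sym_sets.append((f"eqprob{q}", symbolic.symbolize_equal_probability(clean, q)))
    for prefix, sym in sym_sets:
        rates = stage("symbolic", symbolic.word_family_rates, sym)
        for fam, value in rates.as_dict().items():
            row[f"{prefix}_{fam.lower()}"] = value

    try:
        asym = hra.asymmetry_descriptors(clean)
        row.update(asym.as_dict())
        row["hra_defined"] = True
        row["hra_present"] = hra.hra_present(asym)
    except UndefinedIndexError:
        row.update(_HRA_NAN)
        row["hra_defined"] = False
        row["hra_present"] = False

    runs = stage("runs", hra.run_distribution, clean)
    for k, c in zip(range(1, 6), runs.counts("dr")):
        row[f"dr{k}"] = c
    for k, c in zip(range(1, 6), runs.counts("ar")):
        row[f"ar{k}"] = c
    row["nr1"] = runs.counts("nr", 1)[0]

    row["resp_rate"] = recording.resp_rate if recording.resp_rate is not None else float("nan")
    try:
        st = assess_stationarity(series, config.stationarity_alpha)
        row["adf_p"] = st.p_value
        row["stationary"] = st.stationary
    except (InsufficientDataError, DegenerateInputError):
        row["adf_p"] = float("nan")
        row["stationary"] = False
    row["n_interpolated"] = int(np.count_nonzero(clean.labels == "interpolated"))
    return row


def metric_table(
    cohort: Sequence[SubjectRecord],
    config: AnalysisConfig | None = None,
    mode: str = SHORT_TERM,
) -> pd.DataFrame:
    """Tidy per-(subject, condition, window) metric table for a cohort."""
    config = config or AnalysisConfig()
    rows = []
    for subject in cohort:
        for condition in CONDITIONS:
            recording = subject.recording(condition)
            if mode == SHORT_TERM:
                windows = [short_term_window(recording, config)]
            elif mode == ULTRA_SHORT:
                windows = ultra_short_windows(condition, config)
            else:
                raise ValueError(f"unknown mode {mode!r}")
            for spec in windows:
                rows.append(
                    analyze_recording(recording, spec, config, subject_id=subject.subject_id)
                )
    return pd.DataFrame(rows)


# Metrics summarized in the Table-1-style cohort report, in display order.
TABLE1_METRICS = [
    "resp_rate", "hr_mean", "hr_min", "hr_max", "n_beats", "mrr", "sdnn",
    "rmssd", "ln_rmssd", "pnn50",
    "sigma_0v", "sigma_2uv", "maxmin_0v", "maxmin_2uv",
    "eqprob4_0v", "eqprob4_2uv", "eqprob6_0v", "eqprob6_2uv",
    "sd1", "sd2", "sd1_d", "sd1_a", "sd2_d", "sd2_a",
    "c1_d", "c1_a", "c2_d", "c2_a", "sdnn_d", "sdnn_a", "c_d", "c_a", "pi",
    "dr1", "dr2", "dr3", "dr4", "dr5", "ar1", "ar2", "ar3", "ar4", "ar5", "nr1",
]

# Metric deltas correlated against covariates in the Table-2-style report.
TABLE2_METRICS = [
    "rmssd", "ln_rmssd",
    "sigma_0v", "sigma_2uv", "maxmin_0v", "maxmin_2uv",
    "eqprob4_0v", "eqprob4_2uv", "eqprob6_0v", "eqprob6_2uv",
    "sd1_d", "sd1_a", "sd2_d", "sd2_a", "c1_d", "c2_d", "c_a", "dr1", "ar1",
]


def summarize_conditions(table: pd.DataFrame, metrics: Sequence[str] | None = None) -> pd.DataFrame:
    """Table-1-style cohort summary: median (min-max) per condition,
    Friedman p and Dunn-Bonferroni pairwise p-values per metric."""
    metrics = list(metrics or TABLE1_METRICS)
    out_rows = []
    for metric in metrics:
        wide = table.pivot_table(
            index="subject_id", columns="condition", values=metric, sort=False
        ).reindex(columns=list(CONDITIONS)).dropna()
        row: dict[str, object] = {"metric": metric, "n": int(wide.shape[0])}
        for condition in CONDITIONS:
            col = wide[condition]
            row[f"{condition}_median"] = float(col.median())
            row[f"{condition}_min"] = float(col.min())
            row[f"{condition}_max"] = float(col.max())
        block = group_stats.RepeatedMeasuresBlock(
            wide.to_numpy(), metric=metric, conditions=tuple(CONDITIONS)
        )
        result = group_stats.dunn_bonferroni(block)
        row["friedman_q"] = result.statistic
        row["friedman_p"] = result.p_value
        assert result.pairwise is not None
        for (a, b), (_z, p_adj) in result.pairwise.items():
            row[f"p_{a}_vs_{b}"] = p_adj
        out_rows.append(row)
    return pd.DataFrame(out_rows)


def delta_correlations(
    table: pd.DataFrame,
    cohort: Sequence[SubjectRecord],
    metrics: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Table-2-style report: Spearman rho and p of per-subject metric
    deltas against the matching respiratory-rate delta, heart-rate delta
    and career duration, for both condition pairs."""
    metrics = list(metrics or TABLE2_METRICS)
    meta = {s.subject_id: s for s in cohort}
    out_rows = []
    for pair in ("stim-rest", "recovery-stim"):
        hi, lo = group_stats.DELTA_PAIRS[pair]
        hr_delta = group_stats.condition_deltas(table, "hr_mean", pair)
        subjects = list(hr_delta.index)
        resp_delta = pd.Series(
            {
                sid: (meta[sid].recording(hi).resp_rate or np.nan)
                - (meta[sid].recording(lo).resp_rate or np.nan)
                for sid in subjects
            }
        )
        career = pd.Series({sid: meta[sid].career_duration for sid in subjects}, dtype=float)
        for metric in metrics:
            deltas = group_stats.condition_deltas(table, metric, pair).reindex(subjects)
            row: dict[str, object] = {"pair": pair, "metric": metric, "n": int(deltas.notna().sum())}
            for name, covariate in (
                ("resp_rate_delta", resp_delta),
                ("hr_delta", hr_delta),
                ("career_duration", career),
            ):
                aligned = pd.concat([deltas, covariate.reindex(subjects)], axis=1).dropna()
                if len(aligned) >= 4 and aligned.iloc[:, 0].nunique() > 1 and aligned.iloc[:, 1].nunique() > 1:
                    res = group_stats.spearman_correlation(
                        aligned.iloc[:, 0].to_numpy(), aligned.iloc[:, 1].to_numpy()
                    )
                    row[f"rho_{name}"], row[f"p_{name}"] = res.statistic, res.p_value
                else:
                    row[f"rho_{name}"], row[f"p_{name}"] = float("nan"), float("nan")
            out_rows.append(row)
    return pd.DataFrame(out_rows)


def load_cohort(input_dir) -> list[SubjectRecord]:
    """Read a cohort directory: ``subjects.csv`` plus one folder per
    subject holding ``rest.txt``, ``stim.txt`` and ``recovery.txt``."""
    input_dir = Path(input_dir)
    meta_path = input_dir / "subjects.csv"
    if not meta_path.exists():
        raise CohortSizeError(f"no subjects.csv in {input_dir}")
    meta = pd.read_csv(meta_path)
    subjects: list[SubjectRecord] = []
    for rec in meta.to_dict("records"):
        sid = str(rec["subject_id"])
        subject_dir = input_dir / sid
        recordings = {}
        complete = True
        for condition, fname in CONDITION_FILES.items():
            path = subject_dir / fname
            if not path.exists():
                logger.warning("subject %s missing %s; skipped", sid, fname)
                complete = False
                break
            series = read_tachogram(path, subject_id=sid, condition=condition)
            resp_key = f"resp_rate_{'stim' if condition == SNSA_STIM else condition}"
            resp = rec.get(resp_key)
            recordings[condition] = ConditionRecording(
                series=series,
                resp_rate=float(resp) if resp is not None and not pd.isna(resp) else None,
            )
        if not complete:
            continue
        career = rec.get("career_duration")
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                rest=recordings[REST],
                snsa_stim=recordings[SNSA_STIM],
                recovery=recordings[RECOVERY],
                career_duration=float(career) if career is not None and not pd.isna(career) else None,
            )
        )
    return subjects


def run_cohort(
    input_dir,
    output_dir,
    config: AnalysisConfig | None = None,
    mode: str = SHORT_TERM,
) -> dict[str, Path]:
    """Full cohort analysis: per-row metrics, Table-1-style condition
    summary and Table-2-style delta correlations, written as CSV.

    Requires at least 3 subjects with all three conditions.  Output is a
    deterministic function of the input files and configuration.
    """
    config = config or AnalysisConfig()
    cohort = load_cohort(input_dir)
    if len(cohort) < 3:
        raise CohortSizeError(
            f"cohort analysis needs >= 3 complete subjects, found {len(cohort)}"
        )
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)

    table = metric_table(cohort, config, mode=mode)
    rows_path = output_dir / "rows.csv"
    write_metrics_table(table.to_dict("records"), rows_path)

    paths = {"rows": rows_path}
    if mode == SHORT_TERM:
        table1 = summarize_conditions(table)
        table2 = delta_correlations(table, cohort)
        paths["table1"] = output_dir / "table1.csv"
        paths["table2"] = output_dir / "table2.csv"
        write_metrics_table(table1.to_dict("records"), paths["table1"])
        write_metrics_table(table2.to_dict("records"), paths["table2"])
    logger.info("cohort analysis complete: %d subjects, outputs in %s", len(cohort), output_dir)
    return paths
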
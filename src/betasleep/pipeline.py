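"""End-to-end orchestration: session analysis and cohort statistics.

``run_session`` turns one recording into scored states, per-state
normalized spectra (frontal and hippocampal), band powers and a β-peak
detection per state.  ``run_cohort`` maps that over a session manifest and
derives the longitudinal results: the genotype × β-presence contingency
table with its χ² test, per-mouse β-onset ages, the β-vs-clasping
precedence summary, and genotype × state / genotype × age ANOVAs on β band
power.

Session-level β presence is taken from the REM spectrum when REM was
scored (the state where the rhythm is strongest), falling back to SWS,
quiet wake, then active wake.  Every output file carries the config hash
and seed in a ``#`` header comment.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import spectral
from .errors import EmptyStateError
from .io import (
    REM,
    STATES,
    SWS,
    QUIET_WAKE,
    ACTIVE_WAKE,
    Hypnogram,
    SessionRecording,
    read_manifest,
    read_session,
    write_hypnogram,
)
from .comodulogram import band_extrema, compute_comodulogram
from .scoring import ScoringThresholds, score_states, scoring_accuracy, session_epoch_features
from .spectral import (
    BETA_DISPLAY_BAND,
    BETA_SUM_BAND,
    DELTA_COMOD_BAND,
    NORMALIZATION_BAND,
    THETA_SUM_BAND,
    BetaPeak,
    Spectrum,
    band_power,
    compute_spectrogram,
    detect_beta_peak,
    peak_in_band,
    state_spectrum,
)
from .stats import (
    PrecedenceSummary,
    beta_onset_age,
    chi_square_2x2,
    precedence_summary,
    presence_contingency,
    two_way_anova,
    COHORT_COLUMNS,
)

log = logging.getLogger("betasleep")

_PRESENCE_PRIORITY = (REM, SWS, QUIET_WAKE, ACTIVE_WAKE)


@dataclass
class PipelineConfig:
    """Bands, thresholds and seed for a pipeline run."""

    thresholds: ScoringThresholds = field(default_factory=ScoringThresholds)
    beta_sum_band: tuple = BETA_SUM_BAND
    beta_display_band: tuple = BETA_DISPLAY_BAND
    theta_sum_band: tuple = THETA_SUM_BAND
    delta_comod_band: tuple = DELTA_COMOD_BAND
    normalization_range: tuple = NORMALIZATION_BAND
    prominence_threshold: float = 2.0
    presence_min_windows: int = 30  # windows a state needs before it decides session-level presence
    seed: int = 0

    def config_hash(self) -> str:
        blob = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    def header_meta(self) -> dict:
        return {"seed": self.seed, "config": self.config_hash()}


@dataclass
class SessionResult:
    """Everything derived from one session."""

    mouse_id: str
    genotype: str
    age_weeks: float
    hypnogram: Hypnogram
    spectra: dict  # {channel: {state: Spectrum}}
    beta_by_state: dict  # {state: BetaPeak} on the frontal channel
    beta: BetaPeak  # session-level detection (REM-priority)
    beta_state: str  # state the session-level detection came from
    state_rows: pd.DataFrame  # one row per state (cohort-table fragment)
    n_windows_by_state: dict = field(default_factory=dict)


def run_session(rec: SessionRecording, config: PipelineConfig | None = None) -> SessionResult:
    """Score states, compute state spectra and detect the β peak."""
    config = config or PipelineConfig()
    spg_f = compute_spectrogram(rec.channels["frontal_eeg"], rec.fs_signal)
    spg_h = compute_spectrogram(rec.channels["hippocampus_lfp"], rec.fs_signal)
    emg_rms, speed = session_epoch_features(rec, spg_h)
    hyp = score_states(spg_h, emg_rms, speed, config.thresholds)

    spectra: dict = {"frontal_eeg": {}, "hippocampus_lfp": {}}
    beta_by_state: dict = {}
    n_windows_by_state: dict = {}
    rows = []
    for state in STATES:
        try:
            spec_f = state_spectrum(spg_f, hyp, state, config.normalization_range)
            spec_h = state_spectrum(spg_h, hyp, state, config.normalization_range)
        except EmptyStateError:
            continue
        n_windows_by_state[state] = int(spectral.windows_in_state(spg_f, hyp, state).sum())
        spectra["frontal_eeg"][state] = spec_f
        spectra["hippocampus_lfp"][state] = spec_h
        peak = detect_beta_peak(
            spec_f,
            band=config.beta_sum_band,
            prominence_threshold=config.prominence_threshold,
        )
        beta_by_state[state] = peak
        rows.append(
            {
                "mouse_id": rec.mouse_id,
                "genotype": rec.genotype,
                "age_weeks": rec.age_weeks,
                "state": state,
                "band_power_beta": band_power(spec_f, *config.beta_sum_band),
                "band_power_theta": band_power(spec_h, *config.theta_sum_band),
                "beta_present": peak.present,
                "beta_peak_freq": peak.peak_freq,
                "beta_peak_power": peak.peak_power,
            }
        )
    if not beta_by_state:
        raise EmptyStateError("no state had any spectrogram window")
    # Session-level presence comes from the first state in the priority
    # order that is sampled well enough for a stable spectrum; with too few
    # windows everywhere, fall back to the best-sampled state.
    beta_state = next(
        (
            s
            for s in _PRESENCE_PRIORITY
            if n_windows_by_state.get(s, 0) >= config.presence_min_windows
        ),
        max(n_windows_by_state, key=n_windows_by_state.get),
    )
    return SessionResult(
        mouse_id=rec.mouse_id,
        genotype=rec.genotype,
        age_weeks=rec.age_weeks,
        hypnogram=hyp,
        spectra=spectra,
        beta_by_state=beta_by_state,
        beta=beta_by_state[beta_state],
        beta_state=beta_state,
        state_rows=pd.DataFrame(rows, columns=COHORT_COLUMNS),
        n_windows_by_state=n_windows_by_state,
    )


def session_comodulogram(rec: SessionRecording, result: SessionResult, config=None):
    """Waking-state hippocampus × frontal comodulogram for one session."""
    config = config or PipelineConfig()
    spg_h = compute_spectrogram(rec.channels["hippocampus_lfp"], rec.fs_signal)
    spg_f = compute_spectrogram(rec.channels["frontal_eeg"], rec.fs_signal)
    return compute_comodulogram(spg_h, spg_f, result.hypnogram)


@dataclass
class CohortResult:
    cohort_table: pd.DataFrame  # per (mouse, session, state)
    session_table: pd.DataFrame  # per (mouse, session)
    contingency: np.ndarray
    chi2: tuple[float, int, float]
    onsets: dict
    precedence: PrecedenceSummary
    anova_state: pd.DataFrame | None
    anova_age: pd.DataFrame | None


def run_cohort(
    manifest,
    clasping,
    config: PipelineConfig | None = None,
    out_dir=None,
) -> CohortResult:
    """Analyse every session in a manifest and compute cohort statistics.

    `manifest` is a DataFrame or a CSV path with columns
    mouse_id, genotype, age_weeks, path; `clasping` a list of
    :class:`ClaspingRecord`.  Failures in individual sessions are logged
    and skipped; the run continues.
    """
    config = config or PipelineConfig()
    if not isinstance(manifest, pd.DataFrame):
        manifest = read_manifest(manifest)
    state_frames, session_rows = [], []
    for _, row in manifest.iterrows():
        try:
            rec = read_session(row["path"], row)
            res = run_session(rec, config)
        except Exception as exc:  # per-mouse failures must not kill the cohort
            log.warning("session %s (%s) failed: %s", row["path"], row["mouse_id"], exc)
            continue
        state_frames.append(res.state_rows)
        session_rows.append(
            {
                "mouse_id": res.mouse_id,
                "genotype": res.genotype,
                "age_weeks": res.age_weeks,
                "beta_present": res.beta.present,
                "beta_peak_freq": res.beta.peak_freq,
                "beta_peak_power": res.beta.peak_power,
                "beta_state": res.beta_state,
            }
        )
        if out_dir is not None:
            out_dir = Path(out_dir)
            hyp_path = out_dir / "hypnograms" / f"{res.mouse_id}_{res.age_weeks:g}w.csv"
            hyp_path.parent.mkdir(parents=True, exist_ok=True)
            write_hypnogram(res.hypnogram, hyp_path, config.header_meta())

    cohort_table = (
        pd.concat(state_frames, ignore_index=True)
        if state_frames
        else pd.DataFrame(columns=COHORT_COLUMNS)
    )
    session_table = pd.DataFrame(
        session_rows,
        columns=[
            "mouse_id",
            "genotype",
            "age_weeks",
            "beta_present",
            "beta_peak_freq",
            "beta_peak_power",
            "beta_state",
        ],
    )

    contingency = presence_contingency(session_table)
    try:
        chi2 = chi_square_2x2(contingency)
    except Exception:
        chi2 = (np.nan, 1, np.nan)

    onsets = {}
    for mouse_id, grp in session_table.sort_values("age_weeks").groupby("mouse_id"):
        onsets[mouse_id] = beta_onset_age(zip(grp["age_weeks"], grp["beta_present"]))
    prec = precedence_summary(onsets, clasping)

    anova_state = anova_age = None
    if not cohort_table.empty:
        oldest = cohort_table["age_weeks"].max()
        at_oldest = cohort_table[cohort_table["age_weeks"] == oldest]
        try:
            anova_state = two_way_anova(
                at_oldest["band_power_beta"],
                at_oldest["genotype"],
                at_oldest["state"],
                names=("genotype", "state"),
            )
        except Exception as exc:
            log.warning("genotype x state ANOVA not estimable: %s", exc)
        rem = cohort_table[cohort_table["state"] == REM]
        try:
            anova_age = two_way_anova(
                rem["band_power_beta"],
                rem["genotype"],
                rem["age_weeks"],
                names=("genotype", "age"),
            )
        except Exception as exc:
            log.warning("genotype x age ANOVA not estimable: %s", exc)

    result = CohortResult(
        cohort_table,
        session_table,
        contingency,
        chi2,
        onsets,
        prec,
        anova_state,
        anova_age,
    )
    if out_dir is not None:
        _write_cohort_outputs(result, Path(out_dir), config)
    return result


def _write_cohort_outputs(result: CohortResult, out_dir: Path, config: PipelineConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = " ".join(f"{k}={v}" for k, v in config.header_meta().items())

    def dump(df: pd.DataFrame, name: str, index=False) -> None:
        with open(out_dir / name, "w") as fh:
            fh.write(f"# betasleep {meta}\n")
            df.to_csv(fh, index=index)

    dump(result.cohort_table, "cohort_table.csv")
    dump(result.session_table, "session_table.csv")
    dump(result.precedence.per_mouse, "precedence.csv")
    if result.anova_state is not None:
        dump(result.anova_state, "anova_genotype_state.csv", index=True)
    if result.anova_age is not None:
        dump(result.anova_age, "anova_genotype_age.csv", index=True)
    with open(out_dir / "summary.txt", "w") as fh:
        fh.write(f"# betasleep {meta}\n")
        fh.write(summary_text(result))


def summary_text(result: CohortResult) -> str:
    """Plain-text cohort report mirroring the study's result structure."""
    (a, b), (c, d) = result.contingency
    stat, df, p = result.chi2
    lines = [
        "Cohort summary",
        "==============",
        f"beta presence: R6/1 {a}/{a + b} positive, WT {c}/{c + d} positive",
        f"chi-square({df}) = {stat:.4g}, p = {p:.3g}",
        "",
    ]
    prec = result.precedence
    n_with = int(prec.per_mouse["precedence_weeks"].notna().sum())
    if n_with:
        lines += [
            f"beta onset precedes clasping in {prec.n_beta_first} of {n_with} mice "
            f"(clasp first in {prec.n_clasp_first}, tied in {prec.n_tied})",
            f"mean precedence {prec.mean_weeks:.2f} weeks (SEM {prec.sem_weeks:.2f})",
        ]
        det = prec.per_mouse["beta_onset_weeks"].dropna()
        if len(det):
            lines.append(
                f"beta onset ages: {det.min():.0f}-{det.max():.0f} weeks "
                f"(mean {det.mean():.1f}, SEM {det.std(ddof=1) / np.sqrt(len(det)):.2f})"
            )
    else:
        lines.append("no mouse had both beta and clasping onsets (precedence section empty)")
    for name, tbl in (("genotype x state", result.anova_state), ("genotype x age", result.anova_age)):
        if tbl is not None:
            lines += ["", f"two-way ANOVA ({name}) on beta band power:"]
            for eff, row in tbl.iterrows():
                lines.append(
                    f"  {eff}: F({row['df1']:.0f},{row['df2']:.0f}) = {row['F']:.3f}, p = {row['p']:.4g}"
                )
    return "\n".join(lines) + "\n"
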
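"""Cohort-level statistics: onset detection, precedence, χ² and ANOVA.

The longitudinal question is whether the β oscillation is an early disease
marker: at what age it first appears in each transgenic mouse, how that age
relates to the onset of hindlimb clasping, and whether β presence separates
the genotypes.  Group comparisons of band power use a fixed-effects two-way
ANOVA with interaction (Type II sums of squares on possibly unbalanced
data); the repeated-measures structure of within-mouse factors is
deliberately approximated as fixed — a documented simplification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import DegenerateTableError, DesignError, InputSizeError, JoinError
from .io import ClaspingRecord

COHORT_COLUMNS = [
    "mouse_id",
    "genotype",
    "age_weeks",
    "state",
    "band_power_beta",
    "band_power_theta",
    "beta_present",
    "beta_peak_freq",
    "beta_peak_power",
]


@dataclass
class PrecedenceSummary:
    """Per-mouse β-onset vs clasping-onset ages and their difference."""

    per_mouse: pd.DataFrame  # mouse_id, beta_onset_weeks, clasp_onset_weeks, precedence_weeks
    mean_weeks: float
    sem_weeks: float
    n_beta_first: int
    n_clasp_first: int
    n_tied: int


def beta_onset_age(sessions) -> float | None:
    """Age of the first session with a detected β peak; None if never.

    `sessions` is an ordered iterable of (age_weeks, beta_present) with
    strictly increasing ages.  First detection counts — no persistence
    requirement across later sessions.
    """
    sessions = list(sessions)
    if not sessions:
        raise InputSizeError("no sessions")
    ages = [a for a, _ in sessions]
    if any(b <= a for a, b in zip(ages, ages[1:])):
        raise InputSizeError("session ages must be strictly increasing")
    for age, present in sessions:
        if present:
            return float(age)
    return None


def precedence_summary(
    onsets: dict[str, float | None], clasping: list[ClaspingRecord]
) -> PrecedenceSummary:
    """Summarize clasping-onset minus β-onset (weeks) across mice.

    Positive precedence means β appeared first.  Mice lacking either onset
    are listed but excluded from the mean/SEM; equal onsets count as tied.
    """
    clasp_by_mouse = {r.mouse_id: r for r in clasping}
    rows = []
    for mouse_id, beta_onset in onsets.items():
        if beta_onset is not None and mouse_id not in clasp_by_mouse:
            raise JoinError(f"mouse {mouse_id} missing from the clasping table")
        rec = clasp_by_mouse.get(mouse_id)
        clasp_onset = rec.clasp_onset() if rec is not None else None
        prec = (
            clasp_onset - beta_onset
            if beta_onset is not None and clasp_onset is not None
            else np.nan
        )
        rows.append(
            {
                "mouse_id": mouse_id,
                "beta_onset_weeks": np.nan if beta_onset is None else beta_onset,
                "clasp_onset_weeks": np.nan if clasp_onset is None else clasp_onset,
                "precedence_weeks": prec,
            }
        )
    per_mouse = pd.DataFrame(
        rows, columns=["mouse_id", "beta_onset_weeks", "clasp_onset_weeks", "precedence_weeks"]
    )
    prec = per_mouse["precedence_weeks"].dropna().to_numpy()
    mean = float(prec.mean()) if prec.size else np.nan
    sem = float(prec.std(ddof=1) / np.sqrt(prec.size)) if prec.size > 1 else np.nan
    return PrecedenceSummary(
        per_mouse=per_mouse,
        mean_weeks=mean,
        sem_weeks=sem,
        n_beta_first=int((prec > 0).sum()),
        n_clasp_first=int((prec < 0).sum()),
        n_tied=int((prec == 0).sum()),
    )


def chi_square_2x2(table) -> tuple[float, int, float]:
    """Pearson chi-square on a 2×2 table, no continuity correction.

    statistic = N (ad − bc)² / (r1 r2 c1 c2), df = 1, p from the χ²₁ tail.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise DegenerateTableError("need a 2x2 table of non-negative counts")
    a, b, c, d = t.ravel()
    n = t.sum()
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise DegenerateTableError("zero margin in contingency table")
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(stat), 1, float(sstats.chi2.sf(stat, 1))


def two_way_anova(values, factor_a, factor_b, names=("genotype", "state")) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA with interaction, Type II sums of squares.

    Works on unbalanced data; every cell of the a×b design must be
    occupied.  Returns a table indexed by effect with columns
    ``F, df1, df2, p, sum_sq``.  A zero-variance response yields F = 0.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {"y": np.asarray(values, dtype=float), "a": list(factor_a), "b": list(factor_b)}
    )
    if df["a"].nunique() < 2 or df["b"].nunique() < 2:
        raise DesignError("each factor needs at least 2 levels")
    cells = df.groupby(["a", "b"]).size()
    if len(cells) < df["a"].nunique() * df["b"].nunique():
        raise DesignError("empty cell in the two-way design with interaction")

    if np.allclose(df["y"].var(ddof=0), 0.0):
        idx = [names[0], names[1], f"{names[0]}:{names[1]}"]
        return pd.DataFrame(
            {"F": 0.0, "df1": np.nan, "df2": np.nan, "p": 1.0, "sum_sq": 0.0}, index=idx
        )

    model = smf.ols("y ~ C(a) * C(b)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    resid_df = float(table.loc["Residual", "df"])
    rename = {"C(a)": names[0], "C(b)": names[1], "C(a):C(b)": f"{names[0]}:{names[1]}"}
    out = []
    for key, label in rename.items():
        row = table.loc[key]
        out.append(
            {
                "effect": label,
                "F": float(row["F"]),
                "df1": float(row["df"]),
                "df2": resid_df,
                "p": float(row["PR(>F)"]),
                "sum_sq": float(row["sum_sq"]),
            }
        )
    return pd.DataFrame(out).set_index("effect")


def presence_contingency(session_table: pd.DataFrame) -> np.ndarray:
    """2×2 genotype × β-presence counts from per-session detection results.

    A mouse counts as β-positive when any of its sessions has
    ``beta_present`` true.  Rows: R6/1, WT; columns: positive, negative.
    """
    per_mouse = session_table.groupby("mouse_id").agg(
        genotype=("genotype", "first"), positive=("beta_present", "any")
    )
    table = np.zeros((2, 2), dtype=int)
    for i, geno in enumerate(("R6/1", "WT")):
        sub = per_mouse[per_mouse["genotype"] == geno]
        table[i, 0] = int(sub["positive"].sum())
        table[i, 1] = int((~sub["positive"]).sum())
    return table
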
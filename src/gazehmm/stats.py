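"""Group comparisons: Welch's t-test, the split-plot ANOVA on precision
percentages, product-moment correlation, and behavioral summary tables.

The ANOVA is the univariate split-plot (mixed) decomposition for a balanced
design with one between-subjects factor (expertise group) and two
within-subject factors (AOI position 1-3 and image). Each within effect and
its group interaction are tested against the matching subject-interaction
error stratum; the between effect is tested against subjects-within-groups.
No sphericity correction is applied and only complete balanced tables are
accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DesignError, UsageError


@dataclass(frozen=True)
class GroupSummary:
    """Mean, sample SD (n-1 denominator) and size of one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0 or self.n < 2:
            raise UsageError("GroupSummary needs sd >= 0 and n >= 2")

    @classmethod
    def from_values(cls, values) -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        return cls(mean=float(v.mean()), sd=float(v.std(ddof=1)), n=len(v))


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def welch_t_test(g1: GroupSummary, g2: GroupSummary) -> WelchResult:
    """Two-sided Welch t-test from group summaries.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2) with Welch-Satterthwaite degrees
    of freedom; with equal variances and equal n the df reduce exactly to
    n1 + n2 - 2.
    """
    v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
    if v1 + v2 == 0:
        raise UsageError("Welch t undefined: both group variances are zero")
    t = (g1.mean - g2.mean) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p=float(p))


def pearson_r(x, y) -> float:
    """Product-moment correlation of paired observations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise UsageError("pearson_r needs paired samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise UsageError("pearson_r undefined for a zero-variance sample")
    return float(sps.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# split-plot ANOVA
# ---------------------------------------------------------------------------

ANOVA_COLUMNS = ["effect", "SS", "df", "MS", "F", "p"]


def _split_plot_from_array(Y: np.ndarray, n_per_group: int) -> pd.DataFrame:
    """Univariate split-plot decomposition.

    Y has shape (a*s, b, c): subjects ordered by group, then the two within
    factors; ``n_per_group`` = s subjects per group, equal across the a groups.
    """
    total_subj, b, c = Y.shape
    s = n_per_group
    a = total_subj // s
    m = Y.mean()
    Yg = Y.reshape(a, s, b, c)
    m_g = Yg.mean(axis=(1, 2, 3))              # (a,)
    m_subj = Yg.mean(axis=(2, 3))              # (a, s)
    m_b = Y.mean(axis=(0, 2))                  # (b,)
    m_c = Y.mean(axis=(0, 1))                  # (c,)
    m_gb = Yg.mean(axis=(1, 3))                # (a, b)
    m_gc = Yg.mean(axis=(1, 2))                # (a, c)
    m_bc = Y.mean(axis=0)                      # (b, c)
    m_gbc = Yg.mean(axis=1)                    # (a, b, c)
    m_sb = Yg.mean(axis=3)                     # (a, s, b)
    m_sc = Yg.mean(axis=2)                     # (a, s, c)

    ss = {}
    ss["group"] = s * b * c * ((m_g - m) ** 2).sum()
    ss["subject(group)"] = b * c * ((m_subj - m_g[:, None]) ** 2).sum()
    ss["image"] = a * s * c * ((m_b - m) ** 2).sum()
    ss["group:image"] = s * c * (
        (m_gb - m_g[:, None] - m_b[None, :] + m) ** 2
    ).sum()
    ss["image:subject(group)"] = c * (
        (m_sb - m_subj[:, :, None] - m_gb[:, None, :] + m_g[:, None, None]) ** 2
    ).sum()
    ss["position"] = a * s * b * ((m_c - m) ** 2).sum()
    ss["group:position"] = s * b * (
        (m_gc - m_g[:, None] - m_c[None, :] + m) ** 2
    ).sum()
    ss["position:subject(group)"] = b * (
        (m_sc - m_subj[:, :, None] - m_gc[:, None, :] + m_g[:, None, None]) ** 2
    ).sum()
    ss["image:position"] = a * s * (
        (m_bc - m_b[:, None] - m_c[None, :] + m) ** 2
    ).sum()
    ss["group:image:position"] = s * (
        (
            m_gbc
            - m_gb[:, :, None]
            - m_gc[:, None, :]
            - m_bc[None, :, :]
            + m_g[:, None, None]
            + m_b[None, :, None]
            + m_c[None, None, :]
            - m
        )
        ** 2
    ).sum()
    ss_total = ((Y - m) ** 2).sum()
    ss["image:position:subject(group)"] = ss_total - sum(ss.values())

    df = {
        "group": a - 1,
        "subject(group)": a * (s - 1),
        "image": b - 1,
        "group:image": (a - 1) * (b - 1),
        "image:subject(group)": a * (s - 1) * (b - 1),
        "position": c - 1,
        "group:position": (a - 1) * (c - 1),
        "position:subject(group)": a * (s - 1) * (c - 1),
        "image:position": (b - 1) * (c - 1),
        "group:image:position": (a - 1) * (b - 1) * (c - 1),
        "image:position:subject(group)": a * (s - 1) * (b - 1) * (c - 1),
    }
    error_of = {
        "group": "subject(group)",
        "image": "image:subject(group)",
        "group:image": "image:subject(group)",
        "position": "position:subject(group)",
        "group:position": "position:subject(group)",
        "image:position": "image:position:subject(group)",
        "group:image:position": "image:position:subject(group)",
    }
    rows = []
    for effect in df:
        ms = ss[effect] / df[effect] if df[effect] > 0 else np.nan
        F = p = np.nan
        err = error_of.get(effect)
        if err is not None and df[err] > 0:
            ms_err = ss[err] / df[err]
            if ms_err > 0:
                F = ms / ms_err
                p = float(sps.f.sf(F, df[effect], df[err]))
        rows.append(
            {"effect": effect, "SS": ss[effect], "df": df[effect], "MS": ms, "F": F, "p": p}
        )
    return pd.DataFrame(rows, columns=ANOVA_COLUMNS)


def mixed_anova(table: pd.DataFrame, value: str = "precision_percent") -> pd.DataFrame:
    """Split-plot ANOVA on a long-form per-subject precision table.

    Required columns: ``subject_id``, ``group``, ``image_id``, ``position``
    (AOI position coded 1-3) and the dependent variable. The design must be
    complete and balanced: every subject contributes every image x position
    cell exactly once, and groups have equal size.
    """
    needed = {"subject_id", "group", "image_id", "position", value}
    missing = needed - set(table.columns)
    if missing:
        raise DesignError(f"ANOVA table is missing columns: {sorted(missing)}")
    images = sorted(table["image_id"].unique())
    positions = sorted(table["position"].unique())
    groups = sorted(table["group"].unique())
    subj_group = table.groupby("subject_id")["group"].agg(set)
    if (subj_group.map(len) != 1).any():
        raise DesignError("a subject appears in more than one group")
    counts = table.groupby(["subject_id", "image_id", "position"]).size()
    full = len(images) * len(positions)
    bad = []
    for subj in subj_group.index:
        have = counts.loc[subj] if subj in counts.index.get_level_values(0) else None
        n_cells = int(have.size) if have is not None else 0
        if n_cells != full or (have > 1).any():
            bad.append(str(subj))
    if bad:
        raise DesignError(f"incomplete or duplicated cells for subject(s): {bad}")
    sizes = {g: (subj_group.map(lambda x: next(iter(x))) == g).sum() for g in groups}
    if len(set(sizes.values())) != 1:
        raise DesignError(f"unequal group sizes {sizes}: balanced design required")
    s = next(iter(sizes.values()))
    pivot = table.pivot_table(
        index=["group", "subject_id"], columns=["image_id", "position"], values=value
    )
    pivot = pivot.sort_index()
    Y = pivot.to_numpy().reshape(len(groups) * s, len(images), len(positions))
    return _split_plot_from_array(Y, n_per_group=s)


# ---------------------------------------------------------------------------
# behavioral summaries
# ---------------------------------------------------------------------------

def behavioral_summary(
    scores: pd.DataFrame, task_times: pd.DataFrame, groups: pd.Series | dict
) -> pd.DataFrame:
    """Per group x image: per-target error rate and completion-time mean/SD.

    ``scores`` is the output of :func:`gazehmm.precision.score_touches`
    (columns ``hit_T1..hit_T3``); ``task_times`` has columns subject_id,
    image_id, time_ms; ``groups`` maps subject_id -> group label.
    """
    groups = pd.Series(groups)
    scores = scores.assign(group=scores["subject_id"].map(groups))
    task_times = task_times.assign(group=task_times["subject_id"].map(groups))
    hit_cols = [c for c in scores.columns if c.startswith("hit_")]
    rows = []
    for (g, img), block in scores.groupby(["group", "image_id"]):
        times = task_times.query("group == @g and image_id == @img")["time_ms"]
        row = {"group": g, "image_id": img}
        for c in hit_cols:
            row[f"error_rate_{c[4:]}"] = float(1.0 - block[c].mean())
        row["mean_time_ms"] = float(times.mean()) if len(times) else np.nan
        row["sd_time_ms"] = float(times.std(ddof=1)) if len(times) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def write_stats_report(results: dict, path) -> None:
    """One row per test: name, statistic, df, p (CSV)."""
    rows = []
    for name, res in results.items():
        if isinstance(res, WelchResult):
            rows.append({"test": name, "statistic": res.t, "df": res.df, "p": res.p})
        elif isinstance(res, float):
            rows.append({"test": name, "statistic": res, "df": np.nan, "p": np.nan})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.4f")
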
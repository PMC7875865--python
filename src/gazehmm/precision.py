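"""Linking hidden states to predefined AOIs and the fixation-overlap precision
statistic; also behavioral touch scoring.

Every fixation is classified exhaustively and disjunctively to exactly one
hidden state (smoothed-posterior argmax by default, Viterbi optional). States
are cross-tabulated against AOI labels; each prime/target AOI is linked to the
state holding most of its fixations (many-to-one is allowed — several AOIs may
share a state). Precision of an AOI is the percentage of its linked state's
fixations that actually fall inside the AOI: a "tight" state sitting on its
AOI scores near 100, a diffuse state spilling into white space scores low.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import BoundsError, UsageError
from .hmm import FitResult, posterior_state_probs, viterbi_path
from .io import AOI_LABELS, TARGET_LABELS, WHITE_SPACE, AOISet, FixationSequence, TouchEvent

log = logging.getLogger(__name__)

TOUCH_RADIUS_PX = 50.0


# ---------------------------------------------------------------------------
# fixation -> state
# ---------------------------------------------------------------------------

def classify_fixations(
    fit: FitResult, sequences: list[FixationSequence], mode: str = "posterior_argmax"
) -> pd.DataFrame:
    """Assign every fixation to its best-suited hidden state.

    Returns a DataFrame with columns subject_id, image_id, fixation_index,
    x, y, state. ``posterior_argmax`` takes the smoothed-posterior maximum
    (ties to the lower state index); ``viterbi`` uses max-product decoding.
    """
    if mode not in ("posterior_argmax", "viterbi"):
        raise UsageError(f"unknown decoding mode {mode!r}")
    model = fit.model
    rows = []
    for seq in sequences:
        if mode == "posterior_argmax":
            states = np.argmax(posterior_state_probs(model, seq), axis=1)
        else:
            states = viterbi_path(model, seq)
        for r, s in zip(seq.records, states):
            rows.append(
                {
                    "subject_id": seq.subject_id,
                    "image_id": seq.image_id,
                    "fixation_index": r.fixation_index,
                    "x": r.x,
                    "y": r.y,
                    "state": int(s),
                }
            )
    out = pd.DataFrame(rows)
    if (out["state"] >= model.n_states).any() or (out["state"] < 0).any():
        raise UsageError("decoded state outside [0, n_states)")
    return out


# ---------------------------------------------------------------------------
# point -> AOI label
# ---------------------------------------------------------------------------

def aoi_label_of(point, aoiset: AOISet) -> str:
    """Label of the region containing the point, else WS; boundaries count as inside."""
    x, y = float(point[0]), float(point[1])
    if not (0 <= x <= aoiset.canvas_width and 0 <= y <= aoiset.canvas_height):
        raise BoundsError(f"point ({x}, {y}) outside canvas of {aoiset.image_id!r}")
    for region in aoiset.regions:
        if region.contains(x, y):
            return region.label
    return WHITE_SPACE


def aoi_labels_of(x: np.ndarray, y: np.ndarray, aoiset: AOISet) -> np.ndarray:
    """Vectorised :func:`aoi_label_of`; earlier regions win where unscored
    regions happen to overlap."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out_of_canvas = (
        (x < 0) | (x > aoiset.canvas_width) | (y < 0) | (y > aoiset.canvas_height)
    )
    if out_of_canvas.any():
        i = int(np.flatnonzero(out_of_canvas)[0])
        raise BoundsError(
            f"point ({x[i]}, {y[i]}) outside canvas of {aoiset.image_id!r}"
        )
    labels = np.full(len(x), WHITE_SPACE, dtype=object)
    unassigned = np.ones(len(x), dtype=bool)
    for region in aoiset.regions:
        hit = unassigned & region.contains(x, y)
        labels[hit] = region.label
        unassigned &= ~hit
    return labels


# ---------------------------------------------------------------------------
# state x AOI cross-tabulation
# ---------------------------------------------------------------------------

@dataclass
class OverlapMatrix:
    """Fixation counts per hidden state x AOI label (incl. WS)."""

    counts: pd.DataFrame  # index: state, columns: labels

    @property
    def state_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())


def overlap_matrix(
    assignment: pd.DataFrame, aoiset: AOISet, n_states: int | None = None
) -> OverlapMatrix:
    """Cross-tabulate decoded states against AOI labels.

    The grand total always equals the number of classified fixations
    (exhaustive and disjunctive classification).
    """
    labels = aoi_labels_of(
        assignment["x"].to_numpy(), assignment["y"].to_numpy(), aoiset
    )
    n = int(n_states if n_states is not None else assignment["state"].max() + 1)
    columns = [lab for lab in aoiset.labels if lab in AOI_LABELS]
    columns += [lab for lab in aoiset.labels if lab not in AOI_LABELS]
    columns += [WHITE_SPACE]
    counts = pd.DataFrame(0, index=range(n), columns=columns, dtype=int)
    tab = pd.crosstab(assignment["state"].to_numpy(), labels)
    for col in tab.columns:
        counts.loc[tab.index, col] = tab[col].to_numpy()
    return OverlapMatrix(counts=counts)


def link_states_to_aois(matrix: OverlapMatrix) -> dict[str, int | None]:
    """Link each prime/target AOI to the hidden state with most of its fixations.

    Many-to-one is allowed: one state may absorb several AOIs (frequent
    transitioning between nearby regions merges them into a single state).
    Ties go to the lower state index; an AOI with no fixations anywhere maps
    to None and is flagged downstream. WS is never linked.
    """
    linkage: dict[str, int | None] = {}
    for label in AOI_LABELS:
        if label not in matrix.counts.columns:
            linkage[label] = None
            continue
        col = matrix.counts[label]
        if col.sum() == 0:
            linkage[label] = None
            log.warning("AOI %s has zero fixations in every state; linkage undefined", label)
        else:
            linkage[label] = int(col.idxmax())  # idxmax: first (lowest) index on ties
    return linkage


def distractor_states(matrix: OverlapMatrix, linkage: dict[str, int | None]) -> list[int]:
    """States linked to no prime/target AOI: distractor / orientation regions in WS."""
    linked = {s for s in linkage.values() if s is not None}
    return [int(s) for s in matrix.counts.index if s not in linked]


# ---------------------------------------------------------------------------
# precision
# ---------------------------------------------------------------------------

def precision_scores(
    matrix: OverlapMatrix,
    linkage: dict[str, int | None],
    group: str = "",
    image_id: str = "",
    per_subject: bool = False,
    assignment: pd.DataFrame | None = None,
    aoiset: AOISet | None = None,
) -> pd.DataFrame:
    """Fixation-overlap precision per AOI.

    precision(a) = 100 x (# fixations of linked state s_a inside a)
                       / (# fixations assigned to s_a).

    In per-subject mode both counts are restricted to one subject's fixations
    while the linkage stays group-level (the group model defines the states).
    A subject with no fixations in the linked state scores 0 and is flagged.
    AOIs with undefined linkage are omitted and flagged in the log.
    """
    rows = []
    if per_subject:
        if assignment is None or aoiset is None:
            raise UsageError("per-subject precision needs the assignment and the AOI set")
        labels = aoi_labels_of(
            assignment["x"].to_numpy(), assignment["y"].to_numpy(), aoiset
        )
        for subject in sorted(assignment["subject_id"].unique()):
            mask = (assignment["subject_id"] == subject).to_numpy()
            for aoi, state in linkage.items():
                if state is None:
                    log.warning("AOI %s: linkage undefined, row omitted", aoi)
                    continue
                in_state = mask & (assignment["state"] == state).to_numpy()
                n_state = int(in_state.sum())
                n_in = int((in_state & (labels == aoi)).sum())
                rows.append(
                    {
                        "group": group,
                        "image_id": image_id,
                        "subject_id": subject,
                        "aoi_label": aoi,
                        "linked_state": state,
                        "n_state_fixations": n_state,
                        "n_in_aoi": n_in,
                        "precision_percent": 100.0 * n_in / n_state if n_state else 0.0,
                        "flagged": int(n_state == 0),
                    }
                )
    else:
        totals = matrix.state_totals
        for aoi, state in linkage.items():
            if state is None:
                log.warning("AOI %s: linkage undefined, row omitted", aoi)
                continue
            n_state = int(totals.loc[state])
            n_in = int(matrix.counts.loc[state, aoi]) if aoi in matrix.counts else 0
            rows.append(
                {
                    "group": group,
                    "image_id": image_id,
                    "aoi_label": aoi,
                    "linked_state": state,
                    "n_state_fixations": n_state,
                    "n_in_aoi": n_in,
                    "precision_percent": 100.0 * n_in / n_state if n_state else 0.0,
                    "flagged": int(n_state == 0),
                }
            )
    return pd.DataFrame(rows)


def write_precision_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# behavioral touch scoring
# ---------------------------------------------------------------------------

def score_touches(
    touches: list[TouchEvent], aoiset: AOISet, radius: float = TOUCH_RADIUS_PX
) -> pd.DataFrame:
    """Count identified targets per subject x image.

    A target counts as identified when any touch lies within the (inclusive)
    Euclidean radius of its center; each target at most once. Subjects with no
    touches on an image simply do not appear — callers supply the roster.
    """
    targets = [r for r in aoiset.regions if r.label in TARGET_LABELS]
    if not targets:
        raise UsageError(f"AOI set {aoiset.image_id!r} defines no target regions")
    per_subject: dict[str, dict[str, bool]] = {}
    for t in touches:
        if t.image_id != aoiset.image_id:
            continue
        hits = per_subject.setdefault(t.subject_id, {r.label: False for r in targets})
        for region in targets:
            dx, dy = t.x - region.center[0], t.y - region.center[1]
            if (dx * dx + dy * dy) ** 0.5 <= radius:
                hits[region.label] = True
    rows = [
        {
            "subject_id": subj,
            "image_id": aoiset.image_id,
            **{f"hit_{lab}": int(v) for lab, v in hits.items()},
            "n_identified": int(sum(hits.values())),
        }
        for subj, hits in sorted(per_subject.items())
    ]
    return pd.DataFrame(rows)
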
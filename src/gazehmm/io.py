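"""Fixation tables, AOI definitions and touch events: data model plus readers/writers.

Conventions
-----------
Coordinates are pixels with the origin at the top-left corner, x rightward and
y downward (screen convention of the tablet task). Coordinates are stored as
decimals — fixations mapped onto a reference image need not land on integer
pixels. CSV files are comma-separated UTF-8 with a mandatory header and "."
decimal mark. Polygon membership uses the even-odd rule with boundary points
counting as inside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .errors import BoundsError, FormatError, IntegrityError

FIXATION_COLUMNS = [
    "subject_id",
    "group",
    "image_id",
    "fixation_index",
    "onset_ms",
    "duration_ms",
    "x_px",
    "y_px",
]

TOUCH_COLUMNS = ["subject_id", "image_id", "x_px", "y_px", "time_ms"]

#: AOI labels that take part in precision scoring; everything else is a
#: distractor region or white space.
PRIME_LABELS = ("P1", "P2", "P3")
TARGET_LABELS = ("T1", "T2", "T3")
AOI_LABELS = PRIME_LABELS + TARGET_LABELS
WHITE_SPACE = "WS"


@dataclass(frozen=True)
class FixationRecord:
    """One fixation: where gaze rested, when, and for how long."""

    subject_id: str
    group: str
    image_id: str
    fixation_index: int
    onset_ms: float
    duration_ms: float
    x: float
    y: float

    def __post_init__(self):
        if not self.duration_ms > 0:
            raise IntegrityError(
                f"fixation duration must be positive, got {self.duration_ms}"
            )
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise IntegrityError("fixation coordinates must be finite")


@dataclass
class FixationSequence:
    """The ordered scanpath of one subject on one image.

    This is the observation sequence the HMM is estimated from.
    """

    subject_id: str
    group: str
    image_id: str
    records: list[FixationRecord]

    def __post_init__(self):
        if not self.records:
            raise IntegrityError("a fixation sequence cannot be empty")
        for r in self.records:
            if (r.subject_id, r.group, r.image_id) != (
                self.subject_id,
                self.group,
                self.image_id,
            ):
                raise IntegrityError(
                    "all records of a sequence must share subject, group and image"
                )
        idx = [r.fixation_index for r in self.records]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise IntegrityError(
                "fixation_index must be strictly increasing within a sequence"
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def xy(self) -> np.ndarray:
        """(T, 2) array of fixation coordinates in pixels."""
        return np.array([[r.x, r.y] for r in self.records], dtype=float)

    @property
    def durations(self) -> np.ndarray:
        return np.array([r.duration_ms for r in self.records], dtype=float)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([r.onset_ms for r in self.records], dtype=float)


@dataclass
class AOIRegion:
    """A labelled polygon on the stimulus, e.g. a prime (P1–P3) or target (T1–T3).

    ``center`` is the touch-scoring center (for targets, the point around which
    the 50-px identification radius is drawn).
    """

    label: str
    polygon: np.ndarray  # (k, 2) vertices, pixels
    center: np.ndarray | None = None
    _shape: shapely.Polygon = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        self.polygon = np.asarray(self.polygon, dtype=float)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2 or len(self.polygon) < 3:
            raise IntegrityError(
                f"region {self.label!r}: polygon needs >= 3 (x, y) vertices"
            )
        self._shape = shapely.Polygon(self.polygon)
        if self._shape.area <= 0:
            raise IntegrityError(f"region {self.label!r}: polygon has no area")
        if self.center is None:
            c = self._shape.centroid
            self.center = np.array([c.x, c.y])
        else:
            self.center = np.asarray(self.center, dtype=float)

    @property
    def shape(self) -> shapely.Polygon:
        return self._shape

    def contains(self, x, y) -> np.ndarray:
        """Vectorised membership test; boundary points count as inside."""
        return shapely.intersects_xy(self._shape, x, y)


@dataclass
class AOISet:
    """All labelled regions of one image plus its canvas; the complement is WS."""

    image_id: str
    canvas_width: float
    canvas_height: float
    regions: list[AOIRegion]

    def __post_init__(self):
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise IntegrityError(f"duplicate AOI labels in image {self.image_id!r}")
        for r in self.regions:
            v = r.polygon
            if (
                (v[:, 0] < 0).any()
                or (v[:, 1] < 0).any()
                or (v[:, 0] > self.canvas_width).any()
                or (v[:, 1] > self.canvas_height).any()
            ):
                raise BoundsError(
                    f"region {r.label!r} has vertices outside the "
                    f"{self.canvas_width}x{self.canvas_height} canvas"
                )
        scored = [r for r in self.regions if r.label in AOI_LABELS]
        for i, a in enumerate(scored):
            for b in scored[i + 1 :]:
                if a.shape.intersection(b.shape).area > 1e-9:
                    raise IntegrityError(
                        f"prime/target regions {a.label!r} and {b.label!r} overlap"
                    )

    def __getitem__(self, label: str) -> AOIRegion:
        for r in self.regions:
            if r.label == label:
                return r
        raise KeyError(label)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.regions]


@dataclass(frozen=True)
class TouchEvent:
    """One screen touch made to mark a found target."""

    subject_id: str
    image_id: str
    x: float
    y: float
    time_ms: float


# ---------------------------------------------------------------------------
# fixation tables
# ---------------------------------------------------------------------------

def read_fixation_table(path) -> list[FixationSequence]:
    """Read a fixation CSV into one :class:`FixationSequence` per subject x image.

    The file must carry the header columns ``subject_id, group, image_id,
    fixation_index, onset_ms, duration_ms, x_px, y_px``. Rows may appear in any
    order; sequences are sorted by ``fixation_index``.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "group": str, "image_id": str})
    missing = [c for c in FIXATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"fixation table is missing column(s): {', '.join(missing)}")
    for col in ("fixation_index", "onset_ms", "duration_ms", "x_px", "y_px"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise FormatError(f"non-numeric value in column {col!r} at line {line}")
        df[col] = coerced
    dup = df.duplicated(subset=["subject_id", "image_id", "fixation_index"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise IntegrityError(
            "duplicate fixation_index "
            f"{int(row.fixation_index)} for subject {row.subject_id!r} "
            f"on image {row.image_id!r}"
        )
    sequences = []
    for (subj, img), block in df.groupby(["subject_id", "image_id"], sort=True):
        block = block.sort_values("fixation_index")
        groups = block["group"].unique()
        if len(groups) != 1:
            raise IntegrityError(
                f"subject {subj!r} carries multiple group labels: {list(groups)}"
            )
        records = [
            FixationRecord(
                subject_id=subj,
                group=groups[0],
                image_id=img,
                fixation_index=int(r.fixation_index),
                onset_ms=float(r.onset_ms),
                duration_ms=float(r.duration_ms),
                x=float(r.x_px),
                y=float(r.y_px),
            )
            for r in block.itertuples()
        ]
        sequences.append(
            FixationSequence(subject_id=subj, group=groups[0], image_id=img, records=records)
        )
    return sequences


def write_fixation_table(sequences: list[FixationSequence], path) -> None:
    rows = [
        {
            "subject_id": s.subject_id,
            "group": s.group,
            "image_id": s.image_id,
            "fixation_index": r.fixation_index,
            "onset_ms": r.onset_ms,
            "duration_ms": r.duration_ms,
            "x_px": r.x,
            "y_px": r.y,
        }
        for s in sequences
        for r in s.records
    ]
    pd.DataFrame(rows, columns=FIXATION_COLUMNS).to_csv(
        path, index=False, float_format="%.6f"
    )


# ---------------------------------------------------------------------------
# AOI files
# ---------------------------------------------------------------------------

def read_aoi_file(path) -> dict[str, AOISet]:
    """Read AOI definitions (one JSON object per image, or a list of them).

    Schema per image: ``{"image_id": ..., "canvas": [w, h],
    "regions": [{"label": ..., "polygon": [[x, y], ...], "center": [x, y]}, ...]}``.
    """
    try:
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"AOI file is not valid JSON: {exc}") from exc
    docs = doc if isinstance(doc, list) else [doc]
    out = {}
    for d in docs:
        try:
            image_id = d["image_id"]
            w, h = d["canvas"]
            regions = [
                AOIRegion(
                    label=r["label"],
                    polygon=np.asarray(r["polygon"], dtype=float),
                    center=np.asarray(r["center"], dtype=float) if "center" in r else None,
                )
                for r in d["regions"]
            ]
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"malformed AOI document: {exc}") from exc
        aoiset = AOISet(
            image_id=image_id, canvas_width=float(w), canvas_height=float(h), regions=regions
        )
        if image_id in out:
            raise IntegrityError(f"image {image_id!r} defined twice in AOI file")
        out[image_id] = aoiset
    return out


def write_aoi_file(aoisets: dict[str, AOISet] | AOISet, path) -> None:
    """Write AOI definitions; coordinates serialised via repr for a bit-exact round trip."""
    if isinstance(aoisets, AOISet):
        aoisets = {aoisets.image_id: aoisets}
    docs = [
        {
            "image_id": a.image_id,
            "canvas": [a.canvas_width, a.canvas_height],
            "regions": [
                {
                    "label": r.label,
                    "polygon": [[float(x), float(y)] for x, y in r.polygon],
                    "center": [float(r.center[0]), float(r.center[1])],
                }
                for r in a.regions
            ],
        }
        for a in aoisets.values()
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(docs if len(docs) > 1 else docs[0], fh, indent=1)


# ---------------------------------------------------------------------------
# touch events
# ---------------------------------------------------------------------------

def read_touch_table(path) -> list[TouchEvent]:
    df = pd.read_csv(path, dtype={"subject_id": str, "image_id": str})
    missing = [c for c in TOUCH_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"touch table is missing column(s): {', '.join(missing)}")
    return [
        TouchEvent(
            subject_id=r.subject_id,
            image_id=r.image_id,
            x=float(r.x_px),
            y=float(r.y_px),
            time_ms=float(r.time_ms),
        )
        for r in df.itertuples()
    ]


def write_touch_table(touches: list[TouchEvent], path) -> None:
    rows = [
        {
            "subject_id": t.subject_id,
            "image_id": t.image_id,
            "x_px": t.x,
            "y_px": t.y,
            "time_ms": t.time_ms,
        }
        for t in touches
    ]
    pd.DataFrame(rows, columns=TOUCH_COLUMNS).to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    issues: list[str]
    group_counts: dict[str, int]

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_dataset(
    sequences: list[FixationSequence], aoisets: dict[str, AOISet]
) -> ValidationReport:
    """Report-only consistency check of fixations against AOI canvases.

    Lists fixations outside their image's canvas, images without AOI
    definitions, and per-group sequence counts. Never mutates its inputs.
    """
    issues = []
    for seq in sequences:
        aoi = aoisets.get(seq.image_id)
        if aoi is None:
            issues.append(f"image {seq.image_id!r} has no AOI definition")
            continue
        xy = seq.xy
        out = (
            (xy[:, 0] < 0)
            | (xy[:, 0] > aoi.canvas_width)
            | (xy[:, 1] < 0)
            | (xy[:, 1] > aoi.canvas_height)
        )
        for t in np.flatnonzero(out):
            r = seq.records[t]
            issues.append(
                f"subject {seq.subject_id!r} image {seq.image_id!r} fixation "
                f"{r.fixation_index}: ({r.x:.1f}, {r.y:.1f}) outside canvas"
            )
    # deduplicate the missing-AOI messages but keep order
    seen, uniq = set(), []
    for msg in issues:
        if msg not in seen:
            seen.add(msg)
            uniq.append(msg)
    counts: dict[str, int] = {}
    for seq in sequences:
        counts[seq.group] = counts.get(seq.group, 0) + 1
    return ValidationReport(issues=uniq, group_counts=counts)
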
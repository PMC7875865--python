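"""Synthetic visual-search data with known ground truth.

Generates search scenes (three primes stacked in a right-hand band, three
targets embedded in the image field), a ground-truth Gaussian HMM whose states
are attraction regions centered on the AOIs plus distractor and orientation
states, group presets that mimic the expert/novice contrast (experts: tighter
emissions, extra fine-grained states, more persistent dwelling; novices:
broader emissions and more mass on a canvas-wide orientation state), and fully
seeded cohorts of scanpaths, touch events and task times.

Default magnitudes are scale-realistic for a tablet search task: a 1920x1200
canvas, fixation durations lognormal with median ~280 ms, and sequence lengths
lognormal with median ~120 fixations clipped to [40, 350]. With no distractor
states the ground truth has 7 states (6 AOI states + 1 orientation state).
Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import GazeHMMError
from .hmm import VARIANCE_FLOOR, GaussianHMM
from .io import (
    AOIRegion,
    AOISet,
    FixationRecord,
    FixationSequence,
    TouchEvent,
)

DEFAULT_CANVAS = (1920.0, 1200.0)

#: states after the 6 AOI states: distractors (if any), then one orientation state
ORIENTATION_SD_FRACTION = 0.22  # of canvas extent per axis


@dataclass
class SceneConfig:
    canvas: tuple[float, float] = DEFAULT_CANVAS
    aoi_size: float = 140.0           # square AOI edge length, px
    prime_column_x: float | None = None  # left edge of the right-hand prime band
    target_positions: list[tuple[float, float]] | None = None  # centers, px
    n_distractor_states: int = 0
    self_transition: float = 0.80
    prime_target_boost: float = 0.08  # extra P_k -> T_k transition mass
    emission_sd: float = 45.0         # SD of AOI-centered states, px


@dataclass
class CohortConfig:
    n_per_group: int = 25
    seq_len_median: float = 120.0     # lognormal median, clipped to [40, 350]
    seq_len_sigma: float = 0.45
    seq_len_range: tuple[int, int] = (40, 350)
    duration_median_ms: float = 280.0
    duration_sigma: float = 0.40
    hit_prob_expert: float = 0.95
    hit_prob_novice: float = 0.90
    touch_scatter_px: float = 15.0
    motor_overhead_ms: float = 1200.0  # per touch attempt
    seed: int = 0


def _square(cx: float, cy: float, half: float) -> np.ndarray:
    return np.array(
        [[cx - half, cy - half], [cx + half, cy - half], [cx + half, cy + half], [cx - half, cy + half]]
    )


def make_search_scene(config: SceneConfig, seed: int = 0) -> tuple[AOISet, GaussianHMM]:
    """Build a search scene and its ground-truth HMM.

    AOI states sit on the prime/target centers with SD ``emission_sd``;
    distractor states get random centers in the image field; the final state
    is a broad orientation state spanning the canvas. The transition matrix
    has dominant self-transitions plus elevated prime->target mass for the
    matched pairs (the arrangement of a hypothetical 7-state search model).
    """
    rng = np.random.default_rng(seed)
    w, h = config.canvas
    half = config.aoi_size / 2.0
    band_x = config.prime_column_x if config.prime_column_x is not None else w - 1.5 * config.aoi_size
    prime_cx = band_x + half
    prime_cys = np.linspace(h * 0.2, h * 0.8, 3)
    centers = {f"P{i+1}": (prime_cx, cy) for i, cy in enumerate(prime_cys)}
    if config.target_positions is not None:
        if len(config.target_positions) != 3:
            raise GazeHMMError("exactly three target positions required")
        t_centers = [tuple(map(float, p)) for p in config.target_positions]
    else:
        # seeded placement in the image field left of the prime band, kept disjoint
        t_centers = []
        for _ in range(200):
            cand = (
                float(rng.uniform(2 * half, band_x - 2 * half)),
                float(rng.uniform(2 * half, h - 2 * half)),
            )
            if all(
                max(abs(cand[0] - c[0]), abs(cand[1] - c[1])) > 2.4 * half
                for c in t_centers
            ):
                t_centers.append(cand)
            if len(t_centers) == 3:
                break
        else:
            raise GazeHMMError("could not place three disjoint targets at requested size")
    for i, c in enumerate(t_centers):
        centers[f"T{i+1}"] = c
    regions = [
        AOIRegion(label=lab, polygon=_square(cx, cy, half), center=np.array([cx, cy]))
        for lab, (cx, cy) in centers.items()
    ]
    aoiset = AOISet(image_id="synthetic", canvas_width=w, canvas_height=h, regions=regions)

    labels = ["P1", "P2", "P3", "T1", "T2", "T3"]
    means = [centers[lab] for lab in labels]
    sds = [config.emission_sd] * 6
    for _ in range(config.n_distractor_states):
        means.append(
            (float(rng.uniform(2 * half, band_x - half)), float(rng.uniform(half, h - half)))
        )
        sds.append(config.emission_sd * 1.3)
    means.append((w / 2.0, h / 2.0))  # orientation state
    sds_xy = [(sd, sd) for sd in sds] + [
        (ORIENTATION_SD_FRACTION * w, ORIENTATION_SD_FRACTION * h)
    ]
    n = len(means)
    A = np.full((n, n), (1.0 - config.self_transition) / (n - 1))
    np.fill_diagonal(A, config.self_transition)
    for k in range(3):  # elevated prime_k -> target_k transitions
        A[k, 3 + k] += config.prime_target_boost
        A[k] /= A[k].sum()
    pi = np.full(n, 0.5 / (n - 1))
    pi[-1] = 0.5  # searches tend to start with broad orientation
    model = GaussianHMM(
        pi=pi,
        A=A,
        means=np.array(means),
        covars=np.maximum(np.array(sds_xy, dtype=float) ** 2, VARIANCE_FLOOR),
    )
    return aoiset, model


# ---------------------------------------------------------------------------
# group presets
# ---------------------------------------------------------------------------

def expert_preset(
    truth: GaussianHMM,
    sd_scale: float = 0.6,
    n_extra_states: int = 2,
    self_boost: float = 0.06,
    canvas: tuple[float, float] = DEFAULT_CANVAS,
    seed: int = 0,
) -> GaussianHMM:
    """Expert variant: tighter emissions on AOI states, extra fine-grained
    distractor states, higher AOI self-transitions."""
    rng = np.random.default_rng(seed)
    n0 = truth.n_states
    n = n0 + n_extra_states
    means = np.vstack(
        [truth.means, rng.uniform([0.1, 0.1], [0.75, 0.9], size=(n_extra_states, 2)) * canvas]
    )
    covars = np.vstack(
        [truth.covars * sd_scale**2, np.full((n_extra_states, 2), (45.0 * sd_scale) ** 2)]
    )
    covars = np.maximum(covars, VARIANCE_FLOOR)
    A = np.full((n, n), 1.0 / n)
    A[:n0, :n0] = truth.A * (n0 / (n0 + 1.0))  # leak some mass to new states
    A[:n0, n0:] = (1.0 - A[:n0, :n0].sum(axis=1))[:, None] / max(n_extra_states, 1)
    for k in range(min(6, n0)):
        A[k, k] += self_boost
    A /= A.sum(axis=1, keepdims=True)
    pi = np.concatenate([truth.pi, np.full(n_extra_states, truth.pi.min() * 0.5)])
    pi /= pi.sum()
    return GaussianHMM(pi=pi, A=A, means=means, covars=covars)


def novice_preset(
    truth: GaussianHMM, sd_scale: float = 1.5, orientation_extra: float = 0.10
) -> GaussianHMM:
    """Novice variant: broader emissions, extra transition mass onto the broad
    orientation state (assumed to be the last state of the truth)."""
    covars = np.maximum(truth.covars * sd_scale**2, VARIANCE_FLOOR)
    A = truth.A.copy()
    A[:, -1] += orientation_extra
    A /= A.sum(axis=1, keepdims=True)
    return GaussianHMM(pi=truth.pi.copy(), A=A, means=truth.means.copy(), covars=covars)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_subject(
    model: GaussianHMM,
    length: int,
    canvas: tuple[float, float] = DEFAULT_CANVAS,
    seed: int = 0,
    subject_id: str = "s0",
    group: str = "expert",
    image_id: str = "synthetic",
    duration_median_ms: float = 280.0,
    duration_sigma: float = 0.40,
    return_states: bool = False,
):
    """Sample one scanpath: states from (pi, A), coordinates from the state
    Gaussians clipped to the canvas, durations lognormal."""
    if length < 1:
        raise GazeHMMError("sequence length must be >= 1")
    rng = np.random.default_rng(seed)
    n = model.n_states
    states = np.empty(length, dtype=int)
    states[0] = rng.choice(n, p=model.pi)
    for t in range(1, length):
        states[t] = rng.choice(n, p=model.A[states[t - 1]])
    if model.covariance_kind == "diag":
        sd = np.sqrt(model.covars[states])
        xy = model.means[states] + rng.standard_normal((length, 2)) * sd
    else:
        xy = np.array(
            [rng.multivariate_normal(model.means[s], model.covars[s]) for s in states]
        )
    xy[:, 0] = np.clip(xy[:, 0], 0.0, canvas[0])
    xy[:, 1] = np.clip(xy[:, 1], 0.0, canvas[1])
    durations = rng.lognormal(np.log(duration_median_ms), duration_sigma, size=length)
    onsets = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    records = [
        FixationRecord(
            subject_id=subject_id,
            group=group,
            image_id=image_id,
            fixation_index=t,
            onset_ms=float(onsets[t]),
            duration_ms=float(durations[t]),
            x=float(xy[t, 0]),
            y=float(xy[t, 1]),
        )
        for t in range(length)
    ]
    seq = FixationSequence(subject_id=subject_id, group=group, image_id=image_id, records=records)
    return (seq, states) if return_states else seq


def simulate_touch_scores(
    n_per_group: int,
    n_images: int,
    hit_prob_expert: float,
    hit_prob_novice: float,
    rng: np.random.Generator,
    n_targets_per_image: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Total targets found per subject (experts, novices); binomial per target."""
    m = n_images * n_targets_per_image
    experts = rng.binomial(m, hit_prob_expert, size=n_per_group).astype(float)
    novices = rng.binomial(m, hit_prob_novice, size=n_per_group).astype(float)
    return experts, novices


@dataclass
class Cohort:
    """A simulated study: scanpaths, touches, task times and truth bookkeeping."""

    sequences: list[FixationSequence]
    touches: list[TouchEvent]
    task_times: pd.DataFrame  # subject_id, image_id, time_ms
    groups: dict[str, str]    # subject_id -> group
    aoisets: dict[str, AOISet]
    true_models: dict[tuple[str, str], GaussianHMM]  # (group, image_id) -> model
    manifest: dict = field(default_factory=dict)


def simulate_cohort(
    scenes: dict[str, tuple[AOISet, GaussianHMM, GaussianHMM]],
    config: CohortConfig,
) -> Cohort:
    """Simulate a two-group cohort over one or more images.

    ``scenes`` maps image_id -> (AOI set, expert model, novice model). Each
    subject contributes one scanpath per image; touch events land near target
    centers with the group's hit probability and Gaussian scatter; completion
    time is the summed fixation durations plus motor overhead per touch.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.seq_len_range
    sequences: list[FixationSequence] = []
    touches: list[TouchEvent] = []
    time_rows = []
    groups: dict[str, str] = {}
    true_models: dict[tuple[str, str], GaussianHMM] = {}
    for image_id, (aoiset, expert_model, novice_model) in scenes.items():
        true_models[("expert", image_id)] = expert_model
        true_models[("novice", image_id)] = novice_model
    for g_idx, (group, hit_prob) in enumerate(
        [("expert", config.hit_prob_expert), ("novice", config.hit_prob_novice)]
    ):
        for k in range(config.n_per_group):
            subject_id = f"{group[0]}{k:03d}"
            groups[subject_id] = group
            for image_id, (aoiset, expert_model, novice_model) in scenes.items():
                model = expert_model if group == "expert" else novice_model
                length = int(
                    np.clip(
                        rng.lognormal(np.log(config.seq_len_median), config.seq_len_sigma),
                        lo,
                        hi,
                    )
                )
                seq = simulate_subject(
                    model,
                    length,
                    canvas=(aoiset.canvas_width, aoiset.canvas_height),
                    seed=int(rng.integers(2**31 - 1)),
                    subject_id=subject_id,
                    group=group,
                    image_id=image_id,
                    duration_median_ms=config.duration_median_ms,
                    duration_sigma=config.duration_sigma,
                )
                sequences.append(seq)
                t_end = float(seq.onsets[-1] + seq.durations[-1])
                n_touches = 0
                for region in aoiset.regions:
                    if not region.label.startswith("T"):
                        continue
                    if rng.random() < hit_prob:
                        n_touches += 1
                        tx = region.center[0] + rng.normal(0, config.touch_scatter_px)
                        ty = region.center[1] + rng.normal(0, config.touch_scatter_px)
                        touches.append(
                            TouchEvent(
                                subject_id=subject_id,
                                image_id=image_id,
                                x=float(np.clip(tx, 0, aoiset.canvas_width)),
                                y=float(np.clip(ty, 0, aoiset.canvas_height)),
                                time_ms=t_end + n_touches * config.motor_overhead_ms,
                            )
                        )
                time_rows.append(
                    {
                        "subject_id": subject_id,
                        "image_id": image_id,
                        "time_ms": t_end + n_touches * config.motor_overhead_ms,
                    }
                )
    manifest = {"cohort_config": asdict(config), "images": sorted(scenes)}
    return Cohort(
        sequences=sequences,
        touches=touches,
        task_times=pd.DataFrame(time_rows),
        groups=groups,
        aoisets={img: sc[0] for img, sc in scenes.items()},
        true_models=true_models,
        manifest=manifest,
    )


def make_study(
    n_images: int = 1,
    scene_config: SceneConfig | None = None,
    cohort_config: CohortConfig | None = None,
    seed: int = 0,
) -> Cohort:
    """Convenience wrapper: build scenes with group presets and simulate a cohort."""
    scene_config = scene_config or SceneConfig()
    cohort_config = cohort_config or CohortConfig(seed=seed)
    rng = np.random.default_rng(seed)
    scenes = {}
    for i in range(n_images):
        s_seed = int(rng.integers(2**31 - 1))
        aoiset, truth = make_search_scene(scene_config, seed=s_seed)
        aoiset.image_id = f"img{i+1}"
        expert = expert_preset(truth, canvas=scene_config.canvas, seed=s_seed + 1)
        novice = novice_preset(truth)
        scenes[aoiset.image_id] = (aoiset, expert, novice)
    return simulate_cohort(scenes, cohort_config)
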
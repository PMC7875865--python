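"""End-to-end orchestration: configuration, logging, and the staged run.

A run consumes a fixation CSV, an AOI JSON and (optionally) a touch CSV,
fits one HMM scan per group x image, repairs discontinuities, selects models
by BIC, classifies fixations, computes precision tables, runs the group
statistics, renders figures, and writes a manifest so the run is
self-describing and reproducible bit-for-bit from config + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import GazeHMMError, StageError
from .io import (
    AOI_LABELS,
    PRIME_LABELS,
    TARGET_LABELS,
    read_aoi_file,
    read_fixation_table,
    read_touch_table,
    validate_dataset,
    write_aoi_file,
    write_fixation_table,
    write_touch_table,
)
from .precision import (
    classify_fixations,
    link_states_to_aois,
    overlap_matrix,
    precision_scores,
    score_touches,
    write_precision_table,
)
from .selection import repair_discontinuities, scan_state_range, select_model, write_scan_report
from .simulate import CohortConfig, SceneConfig, make_study
from .stats import GroupSummary, behavioral_summary, mixed_anova, welch_t_test
from .viz import render_overlays, state_density_map

log = logging.getLogger("gazehmm")


def configure_logging(level: int = logging.INFO, logfile=None) -> None:
    handlers = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


@dataclass
class PipelineConfig:
    fixations: str | None = None
    aois: str | None = None
    touches: str | None = None
    output_dir: str = "gazehmm_run"
    n_min: int = 2
    n_max: int = 14
    restarts: int = 3
    extra_restarts: int = 5
    seed: int = 0
    covariance_kind: str = "diag"
    decode_mode: str = "posterior_argmax"
    per_subject: bool = True
    run_anova: bool = True
    render_figures: bool = True
    simulate: dict | None = None  # scene/cohort blocks for synthetic input

    def validate(self) -> None:
        if not (1 <= self.n_min <= self.n_max):
            raise GazeHMMError(f"invalid state range [{self.n_min}, {self.n_max}]")
        if self.covariance_kind not in ("diag", "full"):
            raise GazeHMMError(f"unknown covariance_kind {self.covariance_kind!r}")
        if self.decode_mode not in ("posterior_argmax", "viterbi"):
            raise GazeHMMError(f"unknown decode_mode {self.decode_mode!r}")
        if self.seed is None:
            raise GazeHMMError("a seed is required: no silent nondeterminism")
        if self.simulate is None and (self.fixations is None or self.aois is None):
            raise GazeHMMError("either input paths or a simulate block must be given")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise GazeHMMError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _config_hash(config: PipelineConfig) -> str:
    text = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def simulate_inputs(config: PipelineConfig, outdir: Path) -> tuple[str, str, str]:
    """Materialise synthetic fixation/AOI/touch files from the simulate block."""
    block = config.simulate or {}
    scene = SceneConfig(**{k: v for k, v in block.get("scene", {}).items()})
    cohort_kwargs = dict(block.get("cohort", {}))
    cohort_kwargs.setdefault("seed", config.seed)
    cohort = make_study(
        n_images=int(block.get("n_images", 1)),
        scene_config=scene,
        cohort_config=CohortConfig(**cohort_kwargs),
        seed=config.seed,
    )
    fix_path = outdir / "fixations.csv"
    aoi_path = outdir / "aois.json"
    touch_path = outdir / "touches.csv"
    write_fixation_table(cohort.sequences, fix_path)
    write_aoi_file(cohort.aoisets, aoi_path)
    write_touch_table(cohort.touches, touch_path)
    cohort.task_times.to_csv(outdir / "task_times.csv", index=False)
    with open(outdir / "simulation_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(cohort.manifest, fh, indent=1, default=str)
    return str(fix_path), str(aoi_path), str(touch_path)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the run directory."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    configure_logging(logfile=outdir / "run.log")
    log.info("gazehmm %s starting; config hash %s", __version__, _config_hash(config))

    if config.simulate is not None:
        try:
            fix_path, aoi_path, touch_path = simulate_inputs(config, outdir)
        except GazeHMMError as exc:
            raise StageError("simulate", str(exc)) from exc
        config.fixations, config.aois = fix_path, aoi_path
        config.touches = config.touches or touch_path

    try:
        sequences = read_fixation_table(config.fixations)
        aoisets = read_aoi_file(config.aois)
        touches = read_touch_table(config.touches) if config.touches else []
    except GazeHMMError as exc:
        raise StageError("gaze_io", str(exc)) from exc
    report = validate_dataset(sequences, aoisets)
    log.info("loaded %d sequences; group counts %s", len(sequences), report.group_counts)
    for issue in report.issues:
        log.warning("validation: %s", issue)

    groups = sorted({s.group for s in sequences})
    images = sorted({s.image_id for s in sequences})
    models_dir = outdir / "models"
    models_dir.mkdir(exist_ok=True)
    figures_dir = outdir / "figures"
    scans, precision_rows, subject_rows = [], [], []
    for image_id in images:
        aoiset = aoisets.get(image_id)
        if aoiset is None:
            raise StageError("gaze_io", f"no AOI definition for image {image_id!r}")
        for grp in groups:
            block = [s for s in sequences if s.group == grp and s.image_id == image_id]
            if not block:
                continue
            try:
                scan = scan_state_range(
                    block,
                    n_min=config.n_min,
                    n_max=config.n_max,
                    restarts=config.restarts,
                    base_seed=config.seed,
                    group=grp,
                    image_id=image_id,
                    covariance_kind=config.covariance_kind,
                )
                scan = repair_discontinuities(
                    scan, block, extra_restarts=config.extra_restarts, base_seed=config.seed
                )
            except GazeHMMError as exc:
                raise StageError("state_selection", str(exc)) from exc
            scans.append(scan)
            fit = select_model(scan)
            log.info("%s/%s: selected N=%d", grp, image_id, scan.selected_n)
            fit.model.to_json(models_dir / f"{grp}_{image_id}.json")
            try:
                assignment = classify_fixations(fit, block, mode=config.decode_mode)
                matrix = overlap_matrix(assignment, aoiset, n_states=fit.model.n_states)
                linkage = link_states_to_aois(matrix)
                precision_rows.append(
                    precision_scores(matrix, linkage, group=grp, image_id=image_id)
                )
                if config.per_subject:
                    subject_rows.append(
                        precision_scores(
                            matrix,
                            linkage,
                            group=grp,
                            image_id=image_id,
                            per_subject=True,
                            assignment=assignment,
                            aoiset=aoiset,
                        )
                    )
            except GazeHMMError as exc:
                raise StageError("aoi_precision", str(exc)) from exc
            if config.render_figures:
                figures_dir.mkdir(exist_ok=True)
                grids = state_density_map(
                    assignment,
                    canvas=(aoiset.canvas_width, aoiset.canvas_height),
                    n_states=fit.model.n_states,
                )
                render_overlays(grids, aoiset, figures_dir / f"states_{grp}_{image_id}.png")

    write_scan_report(scans, outdir / "scan_report.csv")
    precision = pd.concat(precision_rows, ignore_index=True)
    write_precision_table(precision, outdir / "precision.csv")
    if subject_rows:
        per_subject = pd.concat(subject_rows, ignore_index=True)
        write_precision_table(per_subject, outdir / "precision_per_subject.csv")

    # ---- group statistics -------------------------------------------------
    stats_out = {}
    try:
        if touches:
            score_frames = [
                score_touches(touches, aoisets[img]) for img in images if img in aoisets
            ]
            scores = pd.concat(score_frames, ignore_index=True)
            subj_groups = {s.subject_id: s.group for s in sequences}
            totals = scores.groupby("subject_id")["n_identified"].sum()
            by_group = {
                g: [totals[s] for s in totals.index if subj_groups.get(s) == g]
                for g in groups
            }
            if len(groups) == 2 and all(len(v) >= 2 for v in by_group.values()):
                w = welch_t_test(
                    GroupSummary.from_values(by_group[groups[0]]),
                    GroupSummary.from_values(by_group[groups[1]]),
                )
                stats_out["welch_targets_found"] = dataclasses.asdict(w)
        if config.run_anova and subject_rows and len(groups) == 2:
            for kind, labels in (("primes", PRIME_LABELS), ("targets", TARGET_LABELS)):
                tab = per_subject[per_subject["aoi_label"].isin(labels)].copy()
                tab["position"] = tab["aoi_label"].str[1].astype(int)
                if tab.empty:
                    continue
                try:
                    anova = mixed_anova(tab)
                    anova.to_csv(outdir / f"anova_{kind}.csv", index=False)
                    stats_out[f"anova_{kind}"] = "written"
                except GazeHMMError as exc:
                    log.warning("ANOVA (%s) skipped: %s", kind, exc)
        if touches:
            task_times_path = outdir / "task_times.csv"
            if task_times_path.exists():
                behavioral_summary(
                    scores, pd.read_csv(task_times_path, dtype={"subject_id": str, "image_id": str}),
                    {s.subject_id: s.group for s in sequences},
                ).to_csv(outdir / "behavioral_summary.csv", index=False)
    except GazeHMMError as exc:
        raise StageError("group_stats", str(exc)) from exc
    with open(outdir / "stats.json", "w", encoding="utf-8") as fh:
        json.dump(stats_out, fh, indent=1, default=str)

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "groups": groups,
        "images": images,
        "selected_states": {
            f"{s.group}/{s.image_id}": s.selected_n for s in scans
        },
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    log.info("run complete: %s", outdir)
    return outdir
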
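"""End-to-end experiment orchestration.

Two execution modes share one statistics path:

* **tabular** — simulate ground truth, read lineages directly from it, and
  compute turnover statistics and group inference (fast; how the cohort
  statistics are validated against the study's printed values);
* **imaging** — additionally render every segment on every imaging day,
  run bouton detection on the rendered stacks, and track the resulting
  calls across days before computing the same statistics (slow; validates
  the full measurement chain).

Every stage draws its seed deterministically from one master seed, every
stage's configuration is echoed into the output tree, and the manifest
records a configuration hash plus per-output row counts, so a rerun with
the same configuration is reproducible bit for bit (tabular) or voxel for
voxel (imaging).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import boutondetect, boutontrack, groupstats, imagesim, synthcohort, turnoverstats
from .schedule import TRAIN_REST, StudySchedule

__all__ = ["RunConfig", "RunResult", "run_experiment"]

log = logging.getLogger("boutonflux")

BUILTIN_PRESETS = {"wt": synthcohort.wt_preset, "mecp2dup": synthcohort.mecp2dup_preset}


@dataclass
class RunConfig:
    mode: str = "tabular"  # tabular | imaging
    presets: dict = field(default_factory=lambda: {"WT": "wt", "MECP2dup": "mecp2dup"})
    schedule: StudySchedule = TRAIN_REST
    imaging: imagesim.ImagingSpec = field(default_factory=imagesim.ImagingSpec)
    detection: boutondetect.DetectionConfig = field(default_factory=boutondetect.DetectionConfig)
    seed: int = 0
    max_render_segments: int = 100

    def resolve_presets(self, calibration_seed: int) -> dict[str, synthcohort.CohortPreset]:
        out = {}
        for genotype, preset in self.presets.items():
            if isinstance(preset, synthcohort.CohortPreset):
                out[genotype] = preset
            elif isinstance(preset, str):
                out[genotype] = BUILTIN_PRESETS[preset.lower()](seed=calibration_seed)
            elif isinstance(preset, dict):
                out[genotype] = synthcohort.CohortPreset.from_dict(preset)
            else:
                raise TypeError(f"cannot interpret preset for {genotype}: {preset!r}")
        return out

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "presets": {
                g: (p if isinstance(p, (str, dict)) else p.to_dict())
                for g, p in self.presets.items()
            },
            "schedule": self.schedule.to_dict(),
            "imaging": self.imaging.to_dict(),
            "detection": self.detection.to_dict(),
            "seed": self.seed,
            "max_render_segments": self.max_render_segments,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        if "schedule" in kwargs:
            kwargs["schedule"] = StudySchedule.from_dict(kwargs["schedule"])
        if "imaging" in kwargs:
            kwargs["imaging"] = imagesim.ImagingSpec.from_dict(kwargs["imaging"])
        if "detection" in kwargs:
            kwargs["detection"] = boutondetect.DetectionConfig.from_dict(kwargs["detection"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunResult:
    out_dir: Path
    per_segment: pd.DataFrame
    cohort_summary: pd.DataFrame
    contrasts: groupstats.ContrastReport | None
    manifest: dict


def _segment_lineages_imaging(
    segment: synthcohort.SegmentGroundTruth,
    config: RunConfig,
    seed_seq: np.random.SeedSequence,
    image_dir: Path | None,
    warnings: list[str],
) -> pd.DataFrame:
    days = config.schedule.imaging_days
    calls_by_day = {}
    day_seeds = seed_seq.generate_state(len(days)) >> 1
    trace = imagesim.make_trace(segment.length, imagesim.trace_seed(segment.segment_id))
    for day, dseed in zip(days, day_seeds):
        stack = imagesim.render_segment(segment, day, config.imaging, int(dseed), trace=trace)
        calls = boutondetect.detect_stack(stack, config=config.detection)
        if image_dir is not None:
            imagesim.write_stack(stack, image_dir / f"{segment.segment_id}_d{day}.tif")
            if day == days[0]:
                imagesim.write_swc(trace, image_dir / f"{segment.segment_id}.swc")
            calls.to_csv(image_dir / f"{segment.segment_id}_d{day}_calls.csv", index=False)
        kept = calls[~calls["excluded_isolated"]].reset_index(drop=True)
        if len(kept) < len(calls):
            warnings.append(
                f"{segment.segment_id} day {day}: {len(calls) - len(kept)} isolated call(s) excluded"
            )
        calls_by_day[day] = kept
    series = boutontrack.track_segment(
        calls_by_day,
        segment_id=segment.segment_id,
        mouse_id=segment.mouse_id,
        genotype=segment.genotype,
        length_um=segment.length,
        schedule=config.schedule,
    )
    return series.lineage_frame()


def run_experiment(config: RunConfig, out_dir) -> RunResult:
    """Run simulate → (render → detect → track) → stats → report."""
    if config.mode not in ("tabular", "imaging"):
        raise ValueError(f"unknown mode {config.mode!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    counts: dict[str, int] = {}
    master = np.random.SeedSequence(config.seed)
    calib_seed, cohort_seed_root, imaging_seed_root = (
        int(s) for s in (master.generate_state(3) >> 1)
    )

    presets = config.resolve_presets(calib_seed)
    schedule = config.schedule
    schedule.to_yaml(out / "schedule.yaml")

    all_segments: list[pd.DataFrame] = []
    all_lineages: list[pd.DataFrame] = []
    for gi, (genotype, preset) in enumerate(sorted(presets.items())):
        stage = f"simulate[{genotype}]"
        log.info("stage %s: %d segments, %d mice", stage, preset.n_segments, preset.n_mice)
        preset.to_yaml(out / f"preset_{genotype}.yaml")
        cohort = synthcohort.sample_cohort(preset, schedule, cohort_seed_root + gi)
        seg_frame = synthcohort.segments_frame(cohort)
        truth_long = synthcohort.ground_truth_long(cohort, schedule)
        seg_frame.to_csv(out / f"segments_{genotype}.csv", index=False)
        truth_long.to_csv(out / f"ground_truth_{genotype}.csv", index=False)
        counts[f"segments_{genotype}.csv"] = len(seg_frame)
        counts[f"ground_truth_{genotype}.csv"] = len(truth_long)
        all_segments.append(seg_frame)

        if config.mode == "tabular":
            all_lineages.append(synthcohort.lineage_table(cohort, schedule))
        else:
            if len(cohort) > config.max_render_segments:
                raise RuntimeError(
                    f"stage render[{genotype}]: {len(cohort)} segments exceed the "
                    f"imaging-mode cap of {config.max_render_segments}"
                )
            image_dir = out / f"images_{genotype}"
            image_dir.mkdir(exist_ok=True)
            seg_seeds = np.random.SeedSequence(imaging_seed_root + gi).spawn(len(cohort))
            for segment, sseed in zip(cohort, seg_seeds):
                all_lineages.append(
                    _segment_lineages_imaging(segment, config, sseed, image_dir, warnings)
                )

    segments = pd.concat(all_segments, ignore_index=True)
    nonempty = [f for f in all_lineages if len(f)]
    lineages = pd.concat(nonempty or all_lineages[:1], ignore_index=True)
    events = boutontrack.events_from_lineages(lineages, schedule)
    events.to_csv(out / "events.csv", index=False)
    counts["events.csv"] = len(events)

    per_segment = turnoverstats.segment_statistics(lineages, segments, schedule)
    per_segment.to_csv(out / "per_segment_stats.csv", index=False)
    counts["per_segment_stats.csv"] = len(per_segment)

    summary = turnoverstats.aggregate_cohort(per_segment)
    summary.to_csv(out / "cohort_summary.csv", index=False)
    with open(out / "cohort_summary.json", "w") as fh:
        json.dump(summary.to_dict(orient="records"), fh, indent=2)
    counts["cohort_summary.json"] = len(summary)

    contrasts = None
    if per_segment["genotype"].nunique() >= 1 and len(schedule.phase_labels) >= 1:
        contrasts = groupstats.report_contrasts(per_segment, schedule)
        (out / "report.md").write_text(contrasts.to_markdown())
        with open(out / "report.json", "w") as fh:
            json.dump(contrasts.to_dict(), fh, indent=2)
        warnings.extend(contrasts.notices)

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "mode": config.mode,
        "row_counts": counts,
        "warnings": warnings,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return RunResult(out, per_segment, summary, contrasts, manifest)
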
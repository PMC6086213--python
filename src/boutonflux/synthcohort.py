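"""Ground-truth generator for longitudinal axonal-bouton cohorts.

Simulates en passant bouton populations on axon segments of wild-type and
MECP2-duplication cohorts over a train-then-rest imaging schedule, without
rendering images. Each segment carries two bouton size classes:

* **alpha** (> 2 µm diameter): dense (~2.7/100 µm in wild type) and nearly
  immortal — they survive each 4 d interval with probability
  ``alpha_p_survive_4d`` and are replenished by a matching tiny formation
  term so their density is stationary.
* **beta** (1–2 µm): the plastic class. Baseline boutons survive the
  training interval with ``p_survive_training`` and, if still present, the
  rest interval with ``p_survive_rest_pre``. New boutons appear per phase as
  Poisson counts proportional to the baseline count (``formation_intensity_*``)
  and, once formed, persist through the following interval with
  ``p_stabilize_new`` — newly formed boutons are far less stable than
  pre-existing ones.

``calibrate_preset`` inverts this model: given target cohort statistics
(formation/elimination fractions, survival, stabilization) it returns latent
parameters whose emergent per-segment statistics match the targets. Survival
and stabilization probabilities map onto targets in closed form; formation
intensities are found by simulation-based fixed-point iteration. The model
has five free beta-dynamics parameters against seven targets, so the two
elimination fractions are implied rather than independently tunable; the
calibration report carries their residuals.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import special, stats

from .schedule import TRAIN_REST, StudySchedule

__all__ = [
    "CohortPreset",
    "BoutonGroundTruth",
    "SegmentGroundTruth",
    "CalibrationTargets",
    "CalibrationReport",
    "sample_segment",
    "sample_cohort",
    "calibrate_preset",
    "lineage_table",
    "segments_frame",
    "ground_truth_long",
    "wt_targets",
    "mecp2dup_targets",
    "wt_preset",
    "mecp2dup_preset",
    "REFERENCE_STATS",
]

ALPHA = "alpha"
BETA = "beta"

#: Reported cohort statistics (value, SEM; percent unless noted) that the
#: genotype presets are calibrated to / validated against.
REFERENCE_STATS = {
    "WT": {
        "elimination_training": (17.0, 3.0),
        "elimination_rest": (6.0, 2.0),
        "formation_training": (10.0, 2.0),
        "formation_rest": (9.0, 2.0),
        "survival_d4": (77.0, 4.0),
        "survival_d8": (69.0, 4.0),
        "maintenance_rest_preexisting": (85.0, 4.0),
        "stabilization": (32.0, 9.0),
        "tor_beta_4d": (23.0, 4.0),
        "tor_alpha_4d": (0.5, 0.25),
        "density_alpha": (2.7, 0.3),  # boutons / 100 um
        "density_beta": (4.0, 0.4),
        "n_segments": 58,
        "n_mice": 6,
    },
    "MECP2dup": {
        "elimination_training": (5.0, 1.0),
        "elimination_rest": (4.0, 1.0),
        "formation_training": (10.0, 2.0),
        "formation_rest": (6.0, 1.0),
        "survival_d4": (95.0, 1.0),
        "survival_d8": (89.0, 2.0),
        "stabilization": (40.0, 8.0),
        "density_alpha": (2.4, 0.3),
        "density_beta": (5.8, 0.7),
        "n_segments": 54,
        "n_mice": 7,
    },
}


def _truncnorm(mean: float, sd: float, lo: float, hi: float):
    if sd <= 0:
        raise ValueError("sd must be positive")
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm(a, b, loc=mean, scale=sd)


def _truncnorm_rvs(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size=None
):
    """Truncated-normal draws by inverse CDF (equivalent to scipy's
    truncnorm.rvs but without per-call distribution construction)."""
    a = special.ndtr((lo - mean) / sd)
    b = special.ndtr((hi - mean) / sd)
    u = rng.uniform(a, b, size=size)
    return mean + sd * special.ndtri(u)


@dataclass
class CohortPreset:
    """Latent generative parameters for one genotype's cohort."""

    genotype: str = "WT"
    n_mice: int = 6
    n_segments: int = 58
    # segment geometry (um)
    segment_length_mean: float = 138.0
    segment_length_sd: float = 73.0
    segment_length_bounds: tuple[float, float] = (30.0, 360.0)
    # densities, boutons / 100 um
    alpha_density: float = 2.7
    beta_density: float = 4.0
    # diameter distributions (um): truncated normal, bimodal across 2 um
    alpha_diameter: tuple[float, float, float, float] = (2.6, 0.35, 2.05, 3.5)
    beta_diameter: tuple[float, float, float, float] = (1.4, 0.25, 1.0, 1.95)
    # beta dynamics
    p_survive_training: float = 0.77
    p_survive_rest_pre: float = 0.896
    p_stabilize_new: float = 0.32
    formation_intensity_training: float = 0.15
    formation_intensity_rest: float = 0.12
    # alpha dynamics: nearly immortal, density-stationary
    alpha_p_survive_4d: float = 0.995
    alpha_formation_intensity: float = 0.005
    # cohort structure
    mouse_effect_sd: float = 0.0  # logit-normal shift on beta survival probs
    min_spacing_um: float = 0.5

    def validate(self) -> None:
        for name in (
            "p_survive_training",
            "p_survive_rest_pre",
            "p_stabilize_new",
            "alpha_p_survive_4d",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.alpha_density <= 0 or self.beta_density <= 0:
            raise ValueError("densities must be > 0")
        if self.formation_intensity_training < 0 or self.formation_intensity_rest < 0:
            raise ValueError("formation intensities must be >= 0")
        if self.segment_length_bounds[0] <= 0:
            raise ValueError("segment lengths must be positive")
        if self.beta_diameter[3] > 2.0 or self.alpha_diameter[2] < 2.0:
            raise ValueError("diameter distributions must not cross the 2 um class boundary")

    def length_dist(self):
        lo, hi = self.segment_length_bounds
        return _truncnorm(self.segment_length_mean, self.segment_length_sd, lo, hi)

    def diameter_dist(self, size_class: str):
        m, s, lo, hi = self.alpha_diameter if size_class == ALPHA else self.beta_diameter
        return _truncnorm(m, s, lo, hi)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["segment_length_bounds"] = list(self.segment_length_bounds)
        d["alpha_diameter"] = list(self.alpha_diameter)
        d["beta_diameter"] = list(self.beta_diameter)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortPreset":
        d = dict(d)
        for key in ("segment_length_bounds", "alpha_diameter", "beta_diameter"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "CohortPreset":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class BoutonGroundTruth:
    bouton_id: str
    segment_id: str
    arc_position: float  # um from segment origin
    diameter: float  # um
    size_class: str  # alpha / beta
    birth_day: int  # -1 for baseline, else first imaging day present
    death_day: int | None = None  # first imaging day absent, None if never

    def __post_init__(self) -> None:
        if self.size_class not in (ALPHA, BETA):
            raise ValueError(f"unknown size class {self.size_class!r}")
        expected = ALPHA if self.diameter > 2.0 else BETA
        if expected != self.size_class:
            raise ValueError(
                f"size_class {self.size_class} inconsistent with diameter {self.diameter}"
            )
        if self.death_day is not None and self.death_day <= max(self.birth_day, 0):
            raise ValueError("death_day must follow birth_day")

    @property
    def first_day(self) -> int:
        return max(self.birth_day, 0)

    def present_on(self, day: int) -> bool:
        if day < self.first_day:
            return False
        return self.death_day is None or day < self.death_day


@dataclass
class SegmentGroundTruth:
    segment_id: str
    mouse_id: str
    genotype: str
    length: float  # um
    boutons: list[BoutonGroundTruth] = field(default_factory=list)

    def present(self, day: int, size_class: str | None = None) -> list[BoutonGroundTruth]:
        return [
            b
            for b in self.boutons
            if b.present_on(day) and (size_class is None or b.size_class == size_class)
        ]


def _logit_shift(p: float, shift: float) -> float:
    if shift == 0.0 or p in (0.0, 1.0):
        return p
    z = math.log(p / (1.0 - p)) + shift
    return 1.0 / (1.0 + math.exp(-z))


def _draw_positions(
    rng: np.random.Generator,
    length: float,
    n: int,
    existing: list[float],
    min_spacing: float,
) -> list[float]:
    """Uniform positions on [0, length] with a minimum pairwise spacing."""
    out: list[float] = []
    occupied = list(existing)
    for _ in range(n):
        for _attempt in range(2000):
            x = float(rng.uniform(0.0, length))
            if all(abs(x - y) >= min_spacing for y in occupied):
                out.append(x)
                occupied.append(x)
                break
        else:
            raise RuntimeError(
                f"could not place {n} boutons with {min_spacing} um spacing on {length} um"
            )
    return out


def _beta_survival_prob(
    preset: CohortPreset, phase_name: str, is_new: bool, shift: float
) -> float:
    if is_new:
        p = preset.p_stabilize_new
    elif phase_name == "training":
        p = preset.p_survive_training
    else:
        p = preset.p_survive_rest_pre
    return _logit_shift(p, shift)


def sample_segment(
    preset: CohortPreset,
    schedule: StudySchedule = TRAIN_REST,
    seed: int | np.random.Generator = 0,
    *,
    segment_id: str = "s0",
    mouse_id: str = "m0",
    genotype: str | None = None,
    length: float | None = None,
    survival_logit_shift: float = 0.0,
) -> SegmentGroundTruth:
    """Simulate one axon segment's bouton population over the schedule.

    Baseline counts per class are Poisson(density x length / 100); positions
    are uniform with the preset's minimum spacing; dynamics follow the
    per-phase survival/formation laws described in the module docstring.
    """
    preset.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genotype = preset.genotype if genotype is None else genotype

    if length is None:
        lo, hi = preset.segment_length_bounds
        length = float(
            _truncnorm_rvs(rng, preset.segment_length_mean, preset.segment_length_sd, lo, hi)
        )
    if length <= 0:
        raise ValueError("segment length must be positive")

    seg = SegmentGroundTruth(segment_id, mouse_id, genotype, length)
    day0 = schedule.imaging_days[0]
    counter = 0

    def _new_boutons(size_class: str, n: int, birth_day: int) -> list[BoutonGroundTruth]:
        nonlocal counter
        if n == 0:
            return []
        positions = _draw_positions(
            rng, length, n, [b.arc_position for b in seg.boutons], preset.min_spacing_um
        )
        m, sdev, lo, hi = (
            preset.alpha_diameter if size_class == ALPHA else preset.beta_diameter
        )
        diams = np.atleast_1d(_truncnorm_rvs(rng, m, sdev, lo, hi, size=n))
        made = []
        for pos, d in zip(positions, diams):
            made.append(
                BoutonGroundTruth(
                    bouton_id=f"{segment_id}:b{counter}",
                    segment_id=segment_id,
                    arc_position=pos,
                    diameter=float(d),
                    size_class=size_class,
                    birth_day=birth_day,
                )
            )
            counter += 1
        seg.boutons.extend(made)
        return made

    n_alpha0 = int(rng.poisson(preset.alpha_density * length / 100.0))
    n_beta0 = int(rng.poisson(preset.beta_density * length / 100.0))
    _new_boutons(ALPHA, n_alpha0, -1)
    _new_boutons(BETA, n_beta0, -1)
    baseline_beta = n_beta0
    baseline_alpha = n_alpha0

    for start, end, phase_name in schedule.phases():
        # survival of boutons alive at the start of the phase
        for b in seg.boutons:
            if not b.present_on(start):
                continue
            if b.size_class == ALPHA:
                p = preset.alpha_p_survive_4d
            else:
                is_new = b.birth_day >= 0 and b.birth_day == start
                p = _beta_survival_prob(preset, phase_name, is_new, survival_logit_shift)
            if rng.random() >= p:
                b.death_day = end
        # formation, proportional to the baseline count of the class
        lam_beta = (
            preset.formation_intensity_training
            if phase_name == "training"
            else preset.formation_intensity_rest
        )
        _new_boutons(BETA, int(rng.poisson(lam_beta * baseline_beta)), end)
        _new_boutons(ALPHA, int(rng.poisson(preset.alpha_formation_intensity * baseline_alpha)), end)

    # keep a stable ordering along the arc
    seg.boutons.sort(key=lambda b: b.arc_position)
    assert all(b.present_on(day0) == (b.birth_day < 0) for b in seg.boutons)
    return seg


def sample_cohort(
    preset: CohortPreset,
    schedule: StudySchedule = TRAIN_REST,
    seed: int = 0,
    *,
    n_segments: int | None = None,
    n_mice: int | None = None,
) -> list[SegmentGroundTruth]:
    """Simulate a cohort, partitioning segments near-evenly across mice.

    With ``mouse_effect_sd > 0`` each mouse carries a logit-normal shift on
    the beta survival probabilities (used only for mixed-model operating-
    characteristic experiments; off by default).
    """
    preset.validate()
    n_segments = preset.n_segments if n_segments is None else int(n_segments)
    n_mice = preset.n_mice if n_mice is None else int(n_mice)
    if n_mice < 1:
        raise ValueError("need at least one mouse")
    ss = np.random.SeedSequence(seed)
    mouse_rng = np.random.default_rng(ss.spawn(1)[0])
    shifts = (
        mouse_rng.normal(0.0, preset.mouse_effect_sd, size=n_mice)
        if preset.mouse_effect_sd > 0
        else np.zeros(n_mice)
    )
    edges = np.linspace(0, n_segments, n_mice + 1).astype(int)
    mouse_of = np.repeat(np.arange(n_mice), np.diff(edges))

    segments = []
    children = ss.spawn(n_segments + 1)[1:]
    for i, child in enumerate(children):
        m = int(mouse_of[i])
        segments.append(
            sample_segment(
                preset,
                schedule,
                np.random.default_rng(child),
                segment_id=f"{preset.genotype}_seg{i:03d}",
                mouse_id=f"{preset.genotype}_m{m}",
                survival_logit_shift=float(shifts[m]),
            )
        )
    return segments


# ---------------------------------------------------------------------------
# tabular views


def segments_frame(segments: list[SegmentGroundTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "segment_id": [s.segment_id for s in segments],
            "mouse_id": [s.mouse_id for s in segments],
            "genotype": [s.genotype for s in segments],
            "length_um": [s.length for s in segments],
        }
    )


def lineage_table(
    segments: list[SegmentGroundTruth], schedule: StudySchedule = TRAIN_REST
) -> pd.DataFrame:
    """One row per bouton lineage with per-day presence flags."""
    rows = []
    for s in segments:
        for b in s.boutons:
            row = {
                "segment_id": s.segment_id,
                "mouse_id": s.mouse_id,
                "genotype": s.genotype,
                "lineage_id": b.bouton_id,
                "size_class": b.size_class,
                "arc_position_um": b.arc_position,
                "diameter_um": b.diameter,
                "reappeared": False,
                "class_changed": False,
            }
            for d in schedule.imaging_days:
                row[f"present_d{d}"] = b.present_on(d)
            rows.append(row)
    cols = [
        "segment_id",
        "mouse_id",
        "genotype",
        "lineage_id",
        "size_class",
        "arc_position_um",
        "diameter_um",
        "reappeared",
        "class_changed",
    ] + [f"present_d{d}" for d in schedule.imaging_days]
    return pd.DataFrame(rows, columns=cols)


def segments_from_long(
    ground_truth: pd.DataFrame,
    segments: pd.DataFrame,
    schedule: StudySchedule = TRAIN_REST,
) -> list[SegmentGroundTruth]:
    """Rebuild ground-truth objects from the long CSV representation."""
    days = list(schedule.imaging_days)
    out = []
    seg_meta = segments.set_index("segment_id")
    for sid, sub in ground_truth.groupby("segment_id", sort=False):
        meta = seg_meta.loc[sid]
        seg = SegmentGroundTruth(
            str(sid), str(meta["mouse_id"]), str(meta["genotype"]), float(meta["length_um"])
        )
        for bid, rows in sub.groupby("bouton_id", sort=False):
            pres = {int(r["day"]): bool(r["present"]) for _, r in rows.iterrows()}
            present_days = [d for d in days if pres.get(d, False)]
            if not present_days:
                continue
            birth = -1 if present_days[0] == days[0] else present_days[0]
            later = [d for d in days if d > present_days[-1]]
            death = later[0] if later else None
            r0 = rows.iloc[0]
            seg.boutons.append(
                BoutonGroundTruth(
                    bouton_id=str(bid),
                    segment_id=str(sid),
                    arc_position=float(r0["arc_position_um"]),
                    diameter=float(r0["diameter_um"]),
                    size_class=str(r0["size_class"]),
                    birth_day=birth,
                    death_day=death,
                )
            )
        seg.boutons.sort(key=lambda b: b.arc_position)
        out.append(seg)
    return out


def ground_truth_long(
    segments: list[SegmentGroundTruth], schedule: StudySchedule = TRAIN_REST
) -> pd.DataFrame:
    """Long-format ground truth: one row per bouton per imaging day."""
    rows = []
    for s in segments:
        for b in s.boutons:
            for d in schedule.imaging_days:
                rows.append(
                    {
                        "segment_id": s.segment_id,
                        "mouse_id": s.mouse_id,
                        "genotype": s.genotype,
                        "day": d,
                        "bouton_id": b.bouton_id,
                        "arc_position_um": b.arc_position,
                        "diameter_um": b.diameter,
                        "size_class": b.size_class,
                        "present": b.present_on(d),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# calibration


@dataclass
class CalibrationTargets:
    """Target cohort-mean per-segment fractions (all on [0, 1])."""

    elimination_training: float
    elimination_rest: float
    formation_training: float
    formation_rest: float
    survival_d4: float
    survival_d8: float
    stabilization: float

    def validate(self) -> None:
        for name, v in dataclasses.asdict(self).items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"target {name}={v} outside [0, 1]")
        if self.survival_d8 > self.survival_d4 + 1e-12:
            raise ValueError("survival_d8 cannot exceed survival_d4")
        if self.formation_training + self.formation_rest >= 1.0:
            raise ValueError("formation fractions must sum to < 1 of total observed")
        # elimination fractions use the total-observed denominator, so they
        # cannot exceed the corresponding baseline loss fraction
        if self.elimination_training > (1.0 - self.survival_d4) + 1e-9:
            raise ValueError(
                "infeasible targets: elimination_training > 1 - survival_d4 "
                "(binding constraint: baseline losses during training)"
            )
        if self.elimination_rest > (self.survival_d4 - self.survival_d8) + 1e-9:
            raise ValueError(
                "infeasible targets: elimination_rest > survival_d4 - survival_d8 "
                "(binding constraint: pre-existing losses during rest)"
            )


@dataclass
class CalibrationReport:
    achieved: dict[str, float]
    targets: dict[str, float]
    residuals: dict[str, float]
    implied_only: tuple[str, ...]
    n_segments: int
    iterations: int
    converged: bool
    seed: int
    notes: list[str] = field(default_factory=list)


def wt_targets() -> CalibrationTargets:
    r = REFERENCE_STATS["WT"]
    return CalibrationTargets(
        elimination_training=r["elimination_training"][0] / 100,
        elimination_rest=r["elimination_rest"][0] / 100,
        formation_training=r["formation_training"][0] / 100,
        formation_rest=r["formation_rest"][0] / 100,
        survival_d4=r["survival_d4"][0] / 100,
        survival_d8=r["survival_d8"][0] / 100,
        stabilization=r["stabilization"][0] / 100,
    )


def mecp2dup_targets() -> CalibrationTargets:
    r = REFERENCE_STATS["MECP2dup"]
    return CalibrationTargets(
        elimination_training=r["elimination_training"][0] / 100,
        elimination_rest=r["elimination_rest"][0] / 100,
        formation_training=r["formation_training"][0] / 100,
        formation_rest=r["formation_rest"][0] / 100,
        survival_d4=r["survival_d4"][0] / 100,
        survival_d8=r["survival_d8"][0] / 100,
        stabilization=r["stabilization"][0] / 100,
    )


def _cohort_means(preset: CohortPreset, schedule: StudySchedule, seed: int, n_segments: int):
    from . import turnoverstats

    segs = sample_cohort(preset, schedule, seed, n_segments=n_segments, n_mice=preset.n_mice)
    table = turnoverstats.segment_statistics(lineage_table(segs, schedule), segments_frame(segs), schedule)
    keys = {
        "formation_training": "formation_training",
        "formation_rest": "formation_rest",
        "elimination_training": "elimination_training",
        "elimination_rest": "elimination_rest",
        "survival_d4": "survival_d4",
        "survival_d8": "survival_d8",
        "stabilization": "stabilization_new",
    }
    return {k: float(table[col].mean()) for k, col in keys.items()}


def calibrate_preset(
    targets: CalibrationTargets,
    *,
    genotype: str = "WT",
    alpha_density: float = 2.7,
    beta_density: float = 4.0,
    n_mice: int = 6,
    n_segments_final: int = 58,
    schedule: StudySchedule = TRAIN_REST,
    seed: int = 0,
    n_segments: int = 600,
    tol: float = 0.005,
    max_iter: int = 40,
    **preset_overrides,
) -> tuple[CohortPreset, CalibrationReport]:
    """Tune latent preset parameters to the target cohort statistics.

    Survival probabilities and the stabilization probability follow from the
    targets in closed form (per-segment survival fractions are unbiased for
    the underlying Bernoulli probabilities). The two formation intensities
    are found by damped multiplicative fixed-point iteration on simulated
    cohorts of ``n_segments`` segments with common random numbers, to within
    ``tol`` of the target fractions. Elimination fractions are implied by the
    survival and formation parameters (the model is over-determined); their
    residuals are reported, not optimized.
    """
    targets.validate()
    notes: list[str] = []

    p_st = targets.survival_d4
    p_sr = targets.survival_d8 / targets.survival_d4 if targets.survival_d4 > 0 else 0.0
    baseline = 1.0 - targets.formation_training - targets.formation_rest
    lam_t = targets.formation_training / baseline
    lam_r = targets.formation_rest / baseline

    preset = CohortPreset(
        genotype=genotype,
        n_mice=n_mice,
        n_segments=n_segments_final,
        alpha_density=alpha_density,
        beta_density=beta_density,
        p_survive_training=p_st,
        p_survive_rest_pre=min(p_sr, 1.0),
        p_stabilize_new=targets.stabilization,
        formation_intensity_training=lam_t,
        formation_intensity_rest=lam_r,
        **preset_overrides,
    )

    want = {"formation_training": targets.formation_training, "formation_rest": targets.formation_rest}
    iterations = 0
    converged = all(v == 0.0 for v in want.values())
    if converged:
        preset.formation_intensity_training = 0.0
        preset.formation_intensity_rest = 0.0
    achieved = None
    while not converged and iterations < max_iter:
        iterations += 1
        achieved = _cohort_means(preset, schedule, seed, n_segments)
        converged = True
        for key, attr in (
            ("formation_training", "formation_intensity_training"),
            ("formation_rest", "formation_intensity_rest"),
        ):
            tgt, got = want[key], achieved[key]
            if tgt == 0.0:
                setattr(preset, attr, 0.0)
                continue
            if abs(got - tgt) > tol:
                converged = False
                lam = getattr(preset, attr)
                factor = np.clip(tgt / got, 0.25, 4.0) if got > 0 else 3.0
                setattr(preset, attr, float(lam * factor) if got > 0 else max(lam * 3, 1e-3))
    if achieved is None:
        achieved = _cohort_means(preset, schedule, seed, n_segments)

    tgt_dict = dataclasses.asdict(targets)
    residuals = {k: achieved[k] - tgt_dict[k] for k in achieved}
    implied = ("elimination_training", "elimination_rest")
    for k in implied:
        if abs(residuals[k]) > 0.01:
            notes.append(
                f"{k} implied by survival and formation parameters misses its target "
                f"by {residuals[k]:+.3f}; the seven targets are jointly over-determined."
            )
    report = CalibrationReport(
        achieved=achieved,
        targets=tgt_dict,
        residuals=residuals,
        implied_only=implied,
        n_segments=n_segments,
        iterations=iterations,
        converged=converged,
        seed=seed,
        notes=notes,
    )
    return preset, report


def wt_preset(seed: int = 0, **kwargs) -> CohortPreset:
    """Wild-type preset calibrated to the reference cohort statistics."""
    r = REFERENCE_STATS["WT"]
    preset, _ = calibrate_preset(
        wt_targets(),
        genotype="WT",
        alpha_density=r["density_alpha"][0],
        beta_density=r["density_beta"][0],
        n_mice=r["n_mice"],
        n_segments_final=r["n_segments"],
        seed=seed,
        **kwargs,
    )
    return preset


def mecp2dup_preset(seed: int = 0, **kwargs) -> CohortPreset:
    """MECP2-duplication preset calibrated to the reference cohort statistics."""
    r = REFERENCE_STATS["MECP2dup"]
    preset, _ = calibrate_preset(
        mecp2dup_targets(),
        genotype="MECP2dup",
        alpha_density=r["density_alpha"][0],
        beta_density=r["density_beta"][0],
        n_mice=r["n_mice"],
        n_segments_final=r["n_segments"],
        seed=seed,
        **kwargs,
    )
    return preset
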
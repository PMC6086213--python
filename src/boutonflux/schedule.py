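"""Imaging schedule for longitudinal bouton tracking.

The default experiment images each axonal segment three times: at baseline
(day 0), after four days of rotarod training (day 4), and after four further
days of home-cage rest (day 8). Each consecutive pair of imaging days defines
a named phase ("training" or "rest") over which formation/elimination events
are scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

__all__ = ["StudySchedule", "TRAIN_REST", "REST_ONLY"]


@dataclass(frozen=True)
class StudySchedule:
    """Ordered imaging days plus a phase label per consecutive interval."""

    imaging_days: tuple[int, ...] = (0, 4, 8)
    phase_labels: tuple[str, ...] = ("training", "rest")

    def __post_init__(self) -> None:
        days = tuple(int(d) for d in self.imaging_days)
        object.__setattr__(self, "imaging_days", days)
        object.__setattr__(self, "phase_labels", tuple(self.phase_labels))
        if len(days) < 2:
            raise ValueError("schedule needs at least two imaging days")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("imaging days must be strictly increasing")
        if len(self.phase_labels) != len(days) - 1:
            raise ValueError(
                "need exactly one phase label per consecutive day pair "
                f"({len(days) - 1}), got {len(self.phase_labels)}"
            )
        if len(set(self.phase_labels)) != len(self.phase_labels):
            raise ValueError("phase labels must be unique")

    @property
    def n_days(self) -> int:
        return len(self.imaging_days)

    def phases(self) -> list[tuple[int, int, str]]:
        """(start_day, end_day, phase_name) per interval."""
        return [
            (a, b, name)
            for (a, b), name in zip(
                zip(self.imaging_days, self.imaging_days[1:]), self.phase_labels
            )
        ]

    def phase_interval(self, name: str) -> tuple[int, int]:
        for a, b, label in self.phases():
            if label == name:
                return a, b
        raise KeyError(f"no phase named {name!r}")

    def to_dict(self) -> dict:
        return {
            "imaging_days": list(self.imaging_days),
            "phase_labels": list(self.phase_labels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudySchedule":
        return cls(tuple(d["imaging_days"]), tuple(d["phase_labels"]))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "StudySchedule":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


#: day 0 -> 4 training, day 4 -> 8 rest (the paradigm of the study design)
TRAIN_REST = StudySchedule((0, 4, 8), ("training", "rest"))

#: a single 4 d home-cage interval, used for spontaneous-turnover estimates
REST_ONLY = StudySchedule((0, 4), ("rest",))
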
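"""Longitudinal matching of bouton calls across imaging days.

Boutons are identified across sessions by arc position along the traced
axon: calls from consecutive days are linked by greedy nearest-neighbour
matching (closest pairs first, each call used once, pairs farther apart
than the tolerance left unmatched). Linked chains over the schedule form
*lineages*; unmatched calls open (formation) or close (elimination)
lineages. A bouton that disappears and later reappears at the same site is
treated as two lineages — an elimination followed by a formation — and the
later lineage is flagged ``reappeared`` so both accountings can be reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schedule import TRAIN_REST, StudySchedule

__all__ = ["Link", "SegmentTimeSeries", "match_days", "track_segment", "label_events"]

DEFAULT_TOLERANCE_UM = 2.0


@dataclass(frozen=True)
class Link:
    index_a: int
    index_b: int
    displacement_um: float


def _positions(calls) -> np.ndarray:
    if isinstance(calls, pd.DataFrame):
        return calls["arc_position_um"].to_numpy(float)
    return np.asarray(calls, dtype=float)


def match_days(calls_a, calls_b, tolerance: float = DEFAULT_TOLERANCE_UM) -> list[Link]:
    """Greedy nearest-neighbour matching of two days' calls by arc position.

    Closest pairs are linked first; each call is used at most once; pairs
    beyond ``tolerance`` stay unmatched. Distance ties break toward the pair
    with the smaller arc position, which makes the result symmetric in the
    argument order.
    """
    pa, pb = _positions(calls_a), _positions(calls_b)
    for name, p in (("first", pa), ("second", pb)):
        if len(p) > 1 and np.min(np.diff(np.sort(p))) < 0.01:
            raise ValueError(
                f"duplicate arc positions within 0.01 um in the {name} day's calls "
                "(upstream candidate-merge failure)"
            )
    if len(pa) == 0 or len(pb) == 0:
        return []
    d = np.abs(pa[:, None] - pb[None, :])
    ii, jj = np.nonzero(d <= tolerance)
    if len(ii) == 0:
        return []
    lo = np.minimum(pa[ii], pb[jj])
    hi = np.maximum(pa[ii], pb[jj])
    order = np.lexsort((hi, lo, np.round(d[ii, jj], 9)))
    used_a = np.zeros(len(pa), bool)
    used_b = np.zeros(len(pb), bool)
    links = []
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        if used_a[i] or used_b[j]:
            continue
        used_a[i] = used_b[j] = True
        links.append(Link(i, j, float(pb[j] - pa[i])))
    return links


@dataclass
class SegmentTimeSeries:
    """Matched longitudinal record of one segment's bouton calls."""

    segment_id: str
    mouse_id: str
    genotype: str
    length_um: float
    schedule: StudySchedule
    calls: dict[int, pd.DataFrame]
    links: dict[tuple[int, int], list[Link]] = field(default_factory=dict)
    lineages: pd.DataFrame | None = None

    def lineage_frame(self) -> pd.DataFrame:
        if self.lineages is None:
            raise RuntimeError("segment has not been tracked yet")
        df = self.lineages.copy()
        df.insert(0, "genotype", self.genotype)
        df.insert(0, "mouse_id", self.mouse_id)
        df.insert(0, "segment_id", self.segment_id)
        return df


def track_segment(
    calls: dict[int, pd.DataFrame],
    *,
    segment_id: str,
    mouse_id: str = "m0",
    genotype: str = "-",
    length_um: float,
    schedule: StudySchedule = TRAIN_REST,
    tolerance: float = DEFAULT_TOLERANCE_UM,
) -> SegmentTimeSeries:
    """Link calls across all consecutive imaging days and build lineages.

    ``calls`` maps imaging day to a call table with at least
    ``arc_position_um`` and ``size_class`` columns (``excluded_isolated``
    rows should be removed upstream).
    """
    days = schedule.imaging_days
    for d in days:
        if d not in calls:
            raise KeyError(f"segment {segment_id}: calls for day {d} missing")
    frames = {d: calls[d].reset_index(drop=True) for d in days}
    series = SegmentTimeSeries(
        segment_id, mouse_id, genotype, length_um, schedule, frames
    )

    # lineage bookkeeping: map (day, call index) -> lineage index
    records: list[dict] = []
    owner: dict[tuple[int, int], int] = {}

    def open_lineage(day_idx: int, call_idx: int) -> None:
        day = days[day_idx]
        row = frames[day].iloc[call_idx]
        rec = {
            "lineage_id": f"{segment_id}:L{len(records)}",
            "size_class": row["size_class"],
            "arc_position_um": float(row["arc_position_um"]),
            "diameter_um": float(row.get("diameter_um", np.nan)),
            "reappeared": False,
            "class_changed": False,
        }
        for d in days:
            rec[f"present_d{d}"] = False
        rec[f"present_d{day}"] = True
        owner[(day_idx, call_idx)] = len(records)
        records.append(rec)

    for idx in range(len(frames[days[0]])):
        open_lineage(0, idx)

    for k in range(len(days) - 1):
        da, db = days[k], days[k + 1]
        links = match_days(frames[da], frames[db], tolerance)
        series.links[(da, db)] = links
        matched_b = set()
        for link in links:
            lin = owner[(k, link.index_a)]
            owner[(k + 1, link.index_b)] = lin
            records[lin][f"present_d{db}"] = True
            if frames[db].iloc[link.index_b]["size_class"] != records[lin]["size_class"]:
                records[lin]["class_changed"] = True
            matched_b.add(link.index_b)
        for idx in range(len(frames[db])):
            if idx not in matched_b:
                open_lineage(k + 1, idx)

    lineages = pd.DataFrame(
        records,
        columns=[
            "lineage_id",
            "size_class",
            "arc_position_um",
            "diameter_um",
            "reappeared",
            "class_changed",
        ]
        + [f"present_d{d}" for d in days],
    )

    # flag reappearances: a lineage formed at day k whose site matches a
    # lineage eliminated at or before day k
    if len(lineages):
        P = lineages[[f"present_d{d}" for d in days]].to_numpy(bool)
        first = P.argmax(axis=1)
        last = len(days) - 1 - P[:, ::-1].argmax(axis=1)
        pos = lineages["arc_position_um"].to_numpy(float)
        for i in range(len(lineages)):
            if first[i] == 0:
                continue
            dead = (last < first[i]) & (np.abs(pos - pos[i]) <= tolerance)
            dead[i] = False
            if dead.any():
                lineages.loc[i, "reappeared"] = True

    series.lineages = lineages
    return series


def events_from_lineages(
    lineage_frame: pd.DataFrame, schedule: StudySchedule = TRAIN_REST
) -> pd.DataFrame:
    """Per-lineage per-phase event labels from a lineage presence table.

    Emits one row per lineage per phase with ``category`` in
    ``{maintained, formed, eliminated, absent}`` plus lineage-level context:
    ``origin`` (``baseline`` or ``formed_<phase>``), first/last day present,
    and a ``stabilized`` flag for lineages formed in the first phase
    (present through the final session).
    """
    days = schedule.imaging_days
    phases = schedule.phases()
    rows = []
    for _, lin in lineage_frame.iterrows():
        present = {d: bool(lin[f"present_d{d}"]) for d in days}
        if not any(present.values()):
            continue
        first = next(d for d in days if present[d])
        last = max(d for d in days if present[d])
        if first == days[0]:
            origin = "baseline"
        else:
            origin = "formed_" + next(name for a, b, name in phases if b == first)
        stabilized = np.nan
        if len(days) >= 3 and first == days[1]:
            stabilized = bool(present[days[2]])
        for a, b, name in phases:
            if present[a] and present[b]:
                event = "maintained"
            elif present[a] and not present[b]:
                event = "eliminated"
            elif not present[a] and present[b] and first == b:
                event = "formed"
            else:
                event = "absent"
            rows.append(
                {
                    "segment_id": lin["segment_id"],
                    "mouse_id": lin.get("mouse_id", "-"),
                    "genotype": lin.get("genotype", "-"),
                    "bouton_lineage_id": lin["lineage_id"],
                    "category": event,
                    "phase": name,
                    "origin": origin,
                    "day_first": first,
                    "day_last": last,
                    "arc_position_um": lin["arc_position_um"],
                    "size_class": lin["size_class"],
                    "stabilized": stabilized,
                    "reappeared": bool(lin.get("reappeared", False)),
                }
            )
    return pd.DataFrame(rows)


def label_events(series: SegmentTimeSeries) -> pd.DataFrame:
    """Event labels for one tracked segment (see :func:`events_from_lineages`)."""
    if series.lineages is None:
        raise RuntimeError("segment has not been tracked yet")
    return events_from_lineages(series.lineage_frame(), series.schedule)


def lineages_from_events(events: pd.DataFrame, schedule: StudySchedule = TRAIN_REST) -> pd.DataFrame:
    """Invert :func:`events_from_lineages`: rebuild the lineage presence table.

    Lineage presence is a contiguous run of imaging days (reappearances are
    separate lineages by construction), so ``day_first``/``day_last`` fully
    determine it.
    """
    days = schedule.imaging_days
    lin = events.drop_duplicates("bouton_lineage_id")[
        [
            "segment_id",
            "mouse_id",
            "genotype",
            "bouton_lineage_id",
            "size_class",
            "arc_position_um",
            "day_first",
            "day_last",
            "reappeared",
        ]
    ].rename(columns={"bouton_lineage_id": "lineage_id"})
    for d in days:
        lin[f"present_d{d}"] = (lin["day_first"] <= d) & (d <= lin["day_last"])
    lin["diameter_um"] = np.nan
    lin["class_changed"] = False
    return lin.drop(columns=["day_first", "day_last"]).reset_index(drop=True)
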
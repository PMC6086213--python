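"""Per-segment bouton turnover statistics and cohort aggregation.

All statistics are computed per axonal segment and then aggregated as
unweighted mean ± SEM across segments (segments are the statistical unit;
pooled counts are deliberately not used). Formation and elimination
fractions use the *total-observed* denominator: the number of distinct
bouton lineages of the class seen at any imaging session. Because of that
denominator, elimination fractions and survival fractions do not sum to
100% — survival uses the baseline (first-session) denominator instead.

Rest-phase elimination defaults to the pre-existing accounting (losses of
boutons that were already present at baseline); the alternate accounting
that also counts losses of boutons formed during training is always
computed alongside (``elimination_<phase>_all``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .schedule import TRAIN_REST, StudySchedule

__all__ = [
    "segment_statistics",
    "aggregate_cohort",
    "segment_density",
    "phase_fractions",
    "turnover_rate",
    "survival_curve",
    "stabilization_rate",
]

_ID_COLS = ("segment_id", "mouse_id", "genotype", "length_um")


def segment_density(n_boutons: int, length_um: float) -> float:
    """Boutons per 100 um of axon."""
    if length_um <= 0:
        raise ValueError("segment length must be positive")
    return 100.0 * n_boutons / length_um


def _indicator_counts(
    lineages: pd.DataFrame, schedule: StudySchedule, segment_ids: pd.Index
) -> pd.DataFrame:
    days = schedule.imaging_days
    pcols = [f"present_d{d}" for d in days]
    n = len(lineages)
    P = (
        lineages[pcols].to_numpy(dtype=bool)
        if n
        else np.zeros((0, len(days)), dtype=bool)
    )
    observed = P.any(axis=1)
    first = np.where(observed, P.argmax(axis=1), -1)
    beta = lineages["size_class"].to_numpy() == "beta" if n else np.zeros(0, bool)

    ind = {"segment_id": lineages["segment_id"].to_numpy() if n else np.array([], object)}
    for cls, cmask in (("beta", beta), ("alpha", ~beta)):
        m = cmask & observed
        ind[f"{cls}_n"] = m
        ind[f"{cls}_d0"] = m & P[:, 0] if n else m
        for k, (_a, _b, name) in enumerate(schedule.phases()):
            ind[f"{cls}_formed_{name}"] = m & (first == k + 1)
            ind[f"{cls}_elim_all_{name}"] = m & P[:, k] & ~P[:, k + 1]
            ind[f"{cls}_elim_pre_{name}"] = m & P[:, 0] & P[:, k] & ~P[:, k + 1]
        for k in range(1, len(days)):
            ind[f"{cls}_base_alive_d{days[k]}"] = m & P[:, 0] & P[:, k]
        if len(days) >= 3:
            ind[f"{cls}_new"] = m & (first == 1)
            ind[f"{cls}_new_stab"] = m & (first == 1) & P[:, 2]
    frame = pd.DataFrame(ind)
    counts = frame.groupby("segment_id").sum()
    return counts.reindex(segment_ids, fill_value=0).astype(float)


def segment_statistics(
    lineages: pd.DataFrame,
    segments: pd.DataFrame,
    schedule: StudySchedule = TRAIN_REST,
) -> pd.DataFrame:
    """Compute the full per-segment statistic table.

    Parameters
    ----------
    lineages
        One row per bouton lineage with ``present_d<day>`` flags,
        ``size_class`` and ``segment_id`` (from :func:`synthcohort.lineage_table`
        or :mod:`boutontrack`).
    segments
        One row per segment with ``segment_id``, ``mouse_id``, ``genotype``,
        ``length_um``. Segments with no boutons are retained (they contribute
        zero densities and NaN fractions).
    """
    days = schedule.imaging_days
    seg = segments.reset_index(drop=True)
    ids = pd.Index(seg["segment_id"])
    c = _indicator_counts(lineages, schedule, ids)
    L = seg["length_um"].to_numpy(float)
    if np.any(L <= 0):
        raise ValueError("segment lengths must be positive")

    out = seg[[col for col in _ID_COLS if col in seg.columns]].copy()

    def frac(num: np.ndarray, den: np.ndarray) -> np.ndarray:
        den = np.asarray(den, float)
        return np.where(den > 0, np.asarray(num, float) / np.where(den > 0, den, 1.0), np.nan)

    for cls in ("alpha", "beta"):
        out[f"density_{cls}"] = 100.0 * c[f"{cls}_d0"].to_numpy() / L
        out[f"n_observed_{cls}"] = c[f"{cls}_n"].to_numpy()
    out["n_baseline_beta"] = c["beta_d0"].to_numpy()

    n_beta = c["beta_n"].to_numpy()
    n_alpha = c["alpha_n"].to_numpy()
    for k, (_a, _b, name) in enumerate(schedule.phases()):
        formed = c[f"beta_formed_{name}"].to_numpy()
        elim_all = c[f"beta_elim_all_{name}"].to_numpy()
        elim_pre = c[f"beta_elim_pre_{name}"].to_numpy()
        out[f"formation_{name}"] = frac(formed, n_beta)
        out[f"elimination_{name}"] = frac(elim_pre, n_beta)
        out[f"elimination_{name}_all"] = frac(elim_all, n_beta)
        out[f"tor_fraction_beta_{name}"] = (
            out[f"formation_{name}"] + out[f"elimination_{name}"]
        ) / 2.0
        out[f"tor_per_length_beta_{name}"] = (formed + elim_all) * 100.0 / (2.0 * L)
        a_formed = c[f"alpha_formed_{name}"].to_numpy()
        a_elim = c[f"alpha_elim_all_{name}"].to_numpy()
        out[f"tor_fraction_alpha_{name}"] = (
            frac(a_formed, n_alpha) + frac(a_elim, n_alpha)
        ) / 2.0
        out[f"tor_per_length_alpha_{name}"] = (a_formed + a_elim) * 100.0 / (2.0 * L)

    base = c["beta_d0"].to_numpy()
    for k in range(1, len(days)):
        out[f"survival_d{days[k]}"] = frac(c[f"beta_base_alive_d{days[k]}"].to_numpy(), base)
    if len(days) >= 3:
        out["maintenance_rest_preexisting"] = frac(
            c[f"beta_base_alive_d{days[2]}"].to_numpy(),
            c[f"beta_base_alive_d{days[1]}"].to_numpy(),
        )
        out["stabilization_new"] = frac(c["beta_new_stab"].to_numpy(), c["beta_new"].to_numpy())
    return out


def aggregate_cohort(
    per_segment: pd.DataFrame, by: str = "genotype", stats: list[str] | None = None
) -> pd.DataFrame:
    """Unweighted mean ± SEM across segments, per genotype and statistic.

    SEM = sd / sqrt(n) over segments with a defined value for the statistic;
    segments where a statistic is undefined (NaN, e.g. zero denominator) are
    excluded from that statistic only. With fewer than two contributing
    segments the SEM is reported as NaN and flagged.
    """
    if len(per_segment) == 0:
        raise ValueError("no segments to aggregate")
    skip = set(_ID_COLS)
    if stats is None:
        stats = [
            col
            for col in per_segment.columns
            if col not in skip and pd.api.types.is_numeric_dtype(per_segment[col])
        ]
    long = per_segment.melt(
        id_vars=[by], value_vars=stats, var_name="statistic", value_name="value"
    ).dropna(subset=["value"])
    g = long.groupby([by, "statistic"])["value"]
    agg = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    agg["sem"] = agg["sd"] / np.sqrt(agg["n"])
    agg["sem_defined"] = agg["n"] >= 2
    agg.loc[~agg["sem_defined"], "sem"] = np.nan
    return agg[[by, "statistic", "mean", "sem", "n", "sem_defined"]]


# ---------------------------------------------------------------------------
# single-segment convenience wrappers (thin views over segment_statistics)


def _single(lineages: pd.DataFrame, length_um: float, schedule: StudySchedule) -> pd.Series:
    if lineages["segment_id"].nunique() > 1:
        raise ValueError("expected lineages from a single segment")
    sid = lineages["segment_id"].iloc[0] if len(lineages) else "segment"
    seg = pd.DataFrame(
        {"segment_id": [sid], "mouse_id": ["-"], "genotype": ["-"], "length_um": [length_um]}
    )
    return segment_statistics(lineages, seg, schedule).iloc[0]


def phase_fractions(
    lineages: pd.DataFrame, schedule: StudySchedule = TRAIN_REST, length_um: float = 100.0
) -> dict[str, float]:
    """Formation/elimination fractions per phase for one segment (beta boutons)."""
    row = _single(lineages, length_um, schedule)
    out = {}
    for _a, _b, name in schedule.phases():
        out[f"formation_{name}"] = row[f"formation_{name}"]
        out[f"elimination_{name}"] = row[f"elimination_{name}"]
        out[f"elimination_{name}_all"] = row[f"elimination_{name}_all"]
    return out


def turnover_rate(
    lineages: pd.DataFrame,
    length_um: float,
    phase: str,
    size_class: str = "beta",
    schedule: StudySchedule = TRAIN_REST,
) -> tuple[float, float]:
    """(gain + loss)/2 for one segment: as a fraction of observed boutons of
    the class, and as events per 100 um of axon."""
    schedule.phase_interval(phase)  # validates the phase name
    row = _single(lineages, length_um, schedule)
    return (
        float(row[f"tor_fraction_{size_class}_{phase}"]),
        float(row[f"tor_per_length_{size_class}_{phase}"]),
    )


def survival_curve(
    lineages: pd.DataFrame, schedule: StudySchedule = TRAIN_REST
) -> tuple[float, float, float]:
    """(survival to day 4, survival to day 8, rest maintenance of day-4
    survivors) for baseline beta boutons of one segment."""
    days = schedule.imaging_days
    if len(days) < 3:
        raise ValueError("survival curve needs a three-session schedule")
    row = _single(lineages, 100.0, schedule)
    return (
        float(row[f"survival_d{days[1]}"]),
        float(row[f"survival_d{days[2]}"]),
        float(row["maintenance_rest_preexisting"]),
    )


def stabilization_rate(lineages: pd.DataFrame, schedule: StudySchedule = TRAIN_REST) -> float:
    """Fraction of boutons first seen at the second session still present at
    the third, for one segment. NaN if no such bouton exists."""
    if len(schedule.imaging_days) < 3:
        raise ValueError("stabilization needs a three-session schedule")
    return float(_single(lineages, 100.0, schedule)["stabilization_new"])
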
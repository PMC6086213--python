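"""Turnover statistics: arithmetic oracles, recount equivalence, invariants."""

import numpy as np
import pandas as pd
import pytest

from boutonflux import synthcohort as sc
from boutonflux import turnoverstats as ts
from boutonflux.schedule import TRAIN_REST


def lineage_rows(segment_id, presences, size_class="beta", mouse="m0", genotype="WT"):
    """presences: list of (d0, d4, d8) booleans."""
    rows = []
    for i, (p0, p4, p8) in enumerate(presences):
        rows.append(
            {
                "segment_id": segment_id,
                "mouse_id": mouse,
                "genotype": genotype,
                "lineage_id": f"{segment_id}:b{i}",
                "size_class": size_class,
                "arc_position_um": 5.0 * i,
                "diameter_um": 1.5 if size_class == "beta" else 2.5,
                "reappeared": False,
                "class_changed": False,
                "present_d0": p0,
                "present_d4": p4,
                "present_d8": p8,
            }
        )
    return rows


def seg_frame(segment_id, length, mouse="m0", genotype="WT"):
    return pd.DataFrame(
        {
            "segment_id": [segment_id],
            "mouse_id": [mouse],
            "genotype": [genotype],
            "length_um": [length],
        }
    )


def test_density_arithmetic():
    assert ts.segment_density(8, 200.0) == 4.0
    assert ts.segment_density(0, 150.0) == 0.0
    with pytest.raises(ValueError):
        ts.segment_density(3, 0.0)


def test_phase_fraction_arithmetic():
    # 10 lineages observed, 2 eliminated during training
    pres = [(True, False, False)] * 2 + [(True, True, True)] * 8
    lin = pd.DataFrame(lineage_rows("s", pres))
    out = ts.phase_fractions(lin)
    assert out["elimination_training"] == pytest.approx(0.2)
    assert out["formation_training"] == 0.0
    assert out["formation_rest"] == 0.0


def test_no_events_means_all_zero_fractions():
    lin = pd.DataFrame(lineage_rows("s", [(True, True, True)] * 6))
    out = ts.phase_fractions(lin)
    assert all(v == 0.0 for v in out.values())


def test_pooled_count_arithmetic():
    """314 baseline, 40 training-formed, 42 rest-formed, 64 eliminated during
    training, 23 eliminated during rest: fractions of the 396 observed are
    40/396 ~ 0.101 formation and 64/396 ~ 0.162 elimination."""
    pres = []
    pres += [(True, False, False)] * 64  # eliminated in training
    pres += [(True, True, False)] * 23  # eliminated in rest
    pres += [(True, True, True)] * (314 - 64 - 23)
    pres += [(False, True, True)] * 40  # training-formed
    pres += [(False, False, True)] * 42  # rest-formed
    lin = pd.DataFrame(lineage_rows("pool", pres))
    out = ts.phase_fractions(lin)
    assert out["formation_training"] == pytest.approx(40 / 396)
    assert out["elimination_training"] == pytest.approx(64 / 396)
    assert out["formation_rest"] == pytest.approx(42 / 396)
    assert out["elimination_rest"] == pytest.approx(23 / 396)


def test_turnover_rate_arithmetic():
    # formed 2, eliminated 1, length 150 um -> 1 event per 100 um per side
    pres = [(True, False, False)] + [(False, True, True)] * 2 + [(True, True, True)] * 7
    lin = pd.DataFrame(lineage_rows("s", pres))
    frac, per_len = ts.turnover_rate(lin, length_um=150.0, phase="training")
    assert per_len == pytest.approx((2 + 1) * 100 / (2 * 150.0))
    assert frac == pytest.approx((2 / 10 + 1 / 10) / 2)
    frac_rest, per_len_rest = ts.turnover_rate(lin, length_um=150.0, phase="rest")
    assert frac_rest == 0.0 and per_len_rest == 0.0
    with pytest.raises(KeyError):
        ts.turnover_rate(lin, 150.0, phase="weekend")


def test_survival_curve_arithmetic():
    pres = [(True, True, True)] * 7 + [(True, True, False)] + [(True, False, False)] * 2
    lin = pd.DataFrame(lineage_rows("s", pres))
    s4, s8, maint = ts.survival_curve(lin)
    assert (s4, s8, maint) == (0.8, 0.7, pytest.approx(7 / 8))
    all_live = pd.DataFrame(lineage_rows("s", [(True, True, True)] * 5))
    assert ts.survival_curve(all_live) == (1.0, 1.0, 1.0)


def test_stabilization_arithmetic():
    pres = [(False, True, True)] * 2 + [(False, True, False)] * 3 + [(True, True, True)]
    lin = pd.DataFrame(lineage_rows("s", pres))
    assert ts.stabilization_rate(lin) == pytest.approx(0.4)
    none_formed = pd.DataFrame(lineage_rows("s", [(True, True, True)] * 3))
    assert np.isnan(ts.stabilization_rate(none_formed))


def test_aggregate_mean_and_sem():
    per_seg = pd.DataFrame(
        {
            "segment_id": ["a", "b", "c"],
            "mouse_id": ["m"] * 3,
            "genotype": ["WT"] * 3,
            "length_um": [100.0] * 3,
            "elimination_training": [0.1, 0.2, 0.3],
        }
    )
    agg = ts.aggregate_cohort(per_seg).set_index("statistic")
    row = agg.loc["elimination_training"]
    assert row["mean"] == pytest.approx(0.2)
    assert row["sem"] == pytest.approx(0.1 / np.sqrt(3), rel=1e-6)
    assert row["n"] == 3

    single = ts.aggregate_cohort(per_seg.iloc[:1]).set_index("statistic")
    assert np.isnan(single.loc["elimination_training", "sem"])
    assert not single.loc["elimination_training", "sem_defined"]


def test_zero_denominator_segments_excluded_not_dropped(wt_preset):
    lin = pd.DataFrame(lineage_rows("full", [(True, True, True)] * 3))
    segs = pd.concat(
        [seg_frame("full", 100.0), seg_frame("empty", 80.0)], ignore_index=True
    )
    table = ts.segment_statistics(lin, segs)
    assert len(table) == 2
    empty = table.set_index("segment_id").loc["empty"]
    assert empty["density_beta"] == 0.0
    assert np.isnan(empty["formation_training"])
    agg = ts.aggregate_cohort(table).set_index("statistic")
    assert agg.loc["formation_training", "n"] == 1


def brute_force_recount(lin: pd.DataFrame, length: float) -> dict:
    """Independent recount with plain Python set logic over lineage rows."""
    rows = lin.to_dict(orient="records")
    beta = [r for r in rows if r["size_class"] == "beta"]
    observed = [r for r in beta if r["present_d0"] or r["present_d4"] or r["present_d8"]]
    n = len(observed)
    base = [r for r in observed if r["present_d0"]]
    formed_t = [r for r in observed if not r["present_d0"] and r["present_d4"]]
    formed_r = [
        r for r in observed if not r["present_d0"] and not r["present_d4"] and r["present_d8"]
    ]
    elim_t = [r for r in base if not r["present_d4"]]
    elim_r_pre = [r for r in base if r["present_d4"] and not r["present_d8"]]
    elim_r_all = [r for r in observed if r["present_d4"] and not r["present_d8"]]
    out = {
        "n_observed_beta": n,
        "density_beta": 100.0 * len(base) / length,
        "formation_training": len(formed_t) / n if n else np.nan,
        "formation_rest": len(formed_r) / n if n else np.nan,
        "elimination_training": len(elim_t) / n if n else np.nan,
        "elimination_rest": len(elim_r_pre) / n if n else np.nan,
        "elimination_rest_all": len(elim_r_all) / n if n else np.nan,
        "survival_d4": (
            sum(r["present_d4"] for r in base) / len(base) if base else np.nan
        ),
        "survival_d8": (
            sum(r["present_d8"] for r in base) / len(base) if base else np.nan
        ),
        "stabilization_new": (
            sum(r["present_d8"] for r in formed_t) / len(formed_t) if formed_t else np.nan
        ),
    }
    alive4 = [r for r in base if r["present_d4"]]
    out["maintenance_rest_preexisting"] = (
        sum(r["present_d8"] for r in alive4) / len(alive4) if alive4 else np.nan
    )
    return out


def test_equivalence_with_brute_force_recount(wt_preset):
    """Vectorized statistics equal a direct set-operation recount on every
    simulated segment."""
    segs = sc.sample_cohort(wt_preset, TRAIN_REST, seed=13, n_segments=80, n_mice=6)
    lin = sc.lineage_table(segs)
    table = ts.segment_statistics(lin, sc.segments_frame(segs)).set_index("segment_id")
    for seg in segs:
        want = brute_force_recount(lin[lin.segment_id == seg.segment_id], seg.length)
        got = table.loc[seg.segment_id]
        for key, val in want.items():
            if isinstance(val, float) and np.isnan(val):
                assert np.isnan(got[key]), key
            else:
                assert got[key] == pytest.approx(val), key


def test_alternate_rest_accounting_never_below_preexisting(wt_preset):
    segs = sc.sample_cohort(wt_preset, TRAIN_REST, seed=31, n_segments=100, n_mice=6)
    table = ts.segment_statistics(sc.lineage_table(segs), sc.segments_frame(segs))
    ok = table.dropna(subset=["elimination_rest", "elimination_rest_all"])
    assert (ok["elimination_rest_all"] >= ok["elimination_rest"] - 1e-12).all()


def test_survival_plus_baseline_elimination_is_one(wt_preset):
    """survival_d4 + eliminated-in-training/baseline = 1 exactly per segment
    (baseline denominator, not the total-observed one)."""
    segs = sc.sample_cohort(wt_preset, TRAIN_REST, seed=8, n_segments=50, n_mice=5)
    lin = sc.lineage_table(segs)
    table = ts.segment_statistics(lin, sc.segments_frame(segs)).set_index("segment_id")
    for seg in segs:
        row = table.loc[seg.segment_id]
        base = [b for b in seg.boutons if b.size_class == "beta" and b.birth_day == -1]
        if not base:
            continue
        elim_frac_baseline = sum(b.death_day == 4 for b in base) / len(base)
        assert row["survival_d4"] + elim_frac_baseline == pytest.approx(1.0)


def test_invariance_under_row_and_segment_relabeling(wt_preset):
    segs = sc.sample_cohort(wt_preset, TRAIN_REST, seed=2, n_segments=12, n_mice=3)
    lin = sc.lineage_table(segs)
    seg_f = sc.segments_frame(segs)
    a = ts.segment_statistics(lin, seg_f)
    rng = np.random.default_rng(0)
    shuffled = lin.sample(frac=1.0, random_state=7).reset_index(drop=True)
    b = ts.segment_statistics(shuffled, seg_f)
    pd.testing.assert_frame_equal(a, b)
    # aggregation is invariant to segment order too
    agg_a = ts.aggregate_cohort(a)
    agg_b = ts.aggregate_cohort(a.sample(frac=1.0, random_state=3))
    pd.testing.assert_frame_equal(
        agg_a.sort_values(["genotype", "statistic"], ignore_index=True),
        agg_b.sort_values(["genotype", "statistic"], ignore_index=True),
    )
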
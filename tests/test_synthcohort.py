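"""Generator: dynamics laws, determinism, bookkeeping, calibration."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from boutonflux import synthcohort as sc
from boutonflux import turnoverstats as ts
from boutonflux.schedule import REST_ONLY, TRAIN_REST, StudySchedule


def test_schedule_validation():
    with pytest.raises(ValueError):
        StudySchedule((0, 4, 4), ("training", "rest"))
    with pytest.raises(ValueError):
        StudySchedule((0, 4, 8), ("training",))
    assert TRAIN_REST.phases() == [(0, 4, "training"), (4, 8, "rest")]
    assert TRAIN_REST.phase_interval("rest") == (4, 8)


def test_static_preset_keeps_every_bouton(static_preset):
    seg = sc.sample_segment(static_preset, TRAIN_REST, seed=5, length=150.0)
    assert len(seg.boutons) > 0
    for b in seg.boutons:
        assert b.birth_day == -1 and b.death_day is None
        assert all(b.present_on(d) for d in (0, 4, 8))


def test_full_annihilation_of_baseline_betas(static_preset):
    preset = dataclasses.replace(static_preset, p_survive_training=0.0)
    seg = sc.sample_segment(preset, TRAIN_REST, seed=5, length=200.0)
    betas = [b for b in seg.boutons if b.size_class == "beta" and b.birth_day == -1]
    assert len(betas) > 0
    assert all(b.death_day == 4 for b in betas)


def test_same_seed_gives_identical_cohort(wt_preset):
    a = sc.lineage_table(sc.sample_cohort(wt_preset, TRAIN_REST, seed=3, n_segments=10, n_mice=2))
    b = sc.lineage_table(sc.sample_cohort(wt_preset, TRAIN_REST, seed=3, n_segments=10, n_mice=2))
    pd.testing.assert_frame_equal(a, b)


def test_cohort_partitioned_across_mice(wt_preset):
    segs = sc.sample_cohort(wt_preset, TRAIN_REST, seed=1, n_segments=58, n_mice=6)
    assert len(segs) == 58
    mice = {s.mouse_id for s in segs}
    assert len(mice) == 6


def test_geometry_and_class_invariants(wt_preset):
    for seed in range(5):
        seg = sc.sample_segment(wt_preset, TRAIN_REST, seed=seed)
        pos = sorted(b.arc_position for b in seg.boutons)
        assert all(0 <= p <= seg.length for p in pos)
        assert np.min(np.diff(pos)) >= wt_preset.min_spacing_um - 1e-9
        assert 30 <= seg.length <= 360
        for b in seg.boutons:
            assert (b.size_class == "alpha") == (b.diameter > 2.0)
            if b.death_day is not None:
                assert b.death_day > max(b.birth_day, 0)


def test_survival_expectation_matches_parameters(wt_preset):
    """Day-4 survival of baseline betas is Bernoulli(p_survive_training);
    day-8 survival multiplies in the rest-phase law. Checked on ~10k boutons
    within 3 binomial SD."""
    segs = sc.sample_cohort(wt_preset, TRAIN_REST, seed=42, n_segments=2000, n_mice=6)
    lin = sc.lineage_table(segs)
    base = lin[(lin.size_class == "beta") & lin.present_d0]
    n = len(base)
    assert n > 10_000
    p4 = base.present_d4.mean()
    p8 = base.present_d8.mean()
    e4 = wt_preset.p_survive_training
    e8 = wt_preset.p_survive_training * wt_preset.p_survive_rest_pre
    assert abs(p4 - e4) < 3 * np.sqrt(e4 * (1 - e4) / n)
    assert abs(p8 - e8) < 3 * np.sqrt(e8 * (1 - e8) / n)


def test_elimination_bookkeeping_exact(wt_preset):
    """Per segment: baseline = eliminated-during-training + present-at-day-4."""
    for seed in range(10):
        seg = sc.sample_segment(wt_preset, TRAIN_REST, seed=seed)
        base = [b for b in seg.boutons if b.birth_day == -1]
        elim = [b for b in base if b.death_day == 4]
        alive = [b for b in base if b.present_on(4)]
        assert len(base) == len(elim) + len(alive)


def test_no_mouse_effect_means_binomial_mouse_spread(wt_preset):
    """With mouse_effect_sd = 0 the per-mouse baseline survival counts behave
    as one shared binomial: every count falls in a Bonferroni-adjusted exact
    binomial interval, and the standardized counts show no overdispersion
    (chi-square band over mice x seeds)."""
    p = wt_preset.p_survive_training
    zs = []
    n_mice_total = 6 * 6
    alpha_each = 0.001 / n_mice_total
    for seed in range(6):
        segs = sc.sample_cohort(wt_preset, TRAIN_REST, seed=seed, n_segments=60, n_mice=6)
        lin = sc.lineage_table(segs)
        base = lin[(lin.size_class == "beta") & lin.present_d0]
        for _, grp in base.groupby("mouse_id"):
            n = len(grp)
            k = int(grp.present_d4.sum())
            lo, hi = sps.binom.ppf([alpha_each / 2, 1 - alpha_each / 2], n, p)
            assert lo <= k <= hi
            zs.append((k - n * p) / np.sqrt(n * p * (1 - p)))
    chi2 = float(np.sum(np.square(zs)))
    assert sps.chi2.ppf(0.0005, len(zs)) < chi2 < sps.chi2.ppf(0.9995, len(zs))


def test_long_roundtrip_preserves_ground_truth(wt_preset):
    segs = sc.sample_cohort(wt_preset, TRAIN_REST, seed=2, n_segments=6, n_mice=2)
    long = sc.ground_truth_long(segs)
    rebuilt = sc.segments_from_long(long, sc.segments_frame(segs))
    pd.testing.assert_frame_equal(
        sc.lineage_table(segs).sort_values("lineage_id", ignore_index=True),
        sc.lineage_table(rebuilt).sort_values("lineage_id", ignore_index=True),
    )


def test_preset_yaml_roundtrip(tmp_path, wt_preset):
    path = tmp_path / "p.yaml"
    wt_preset.to_yaml(path)
    assert sc.CohortPreset.from_yaml(path) == wt_preset
    spath = tmp_path / "s.yaml"
    TRAIN_REST.to_yaml(spath)
    assert StudySchedule.from_yaml(spath) == TRAIN_REST


def test_rejects_degenerate_inputs(wt_preset):
    with pytest.raises(ValueError):
        sc.sample_segment(wt_preset, TRAIN_REST, seed=0, length=0.0)
    bad = dataclasses.replace(wt_preset, beta_density=0.0)
    with pytest.raises(ValueError):
        sc.sample_segment(bad, TRAIN_REST, seed=0)
    bad = dataclasses.replace(wt_preset, p_survive_training=1.4)
    with pytest.raises(ValueError):
        sc.sample_segment(bad, TRAIN_REST, seed=0)


class TestCalibration:
    def test_zero_change_targets_are_a_fixed_point(self):
        targets = sc.CalibrationTargets(0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 0.0)
        preset, report = sc.calibrate_preset(targets, seed=0, n_segments=50)
        assert preset.p_survive_training == 1.0
        assert preset.p_survive_rest_pre == 1.0
        assert preset.formation_intensity_training == 0.0
        assert preset.formation_intensity_rest == 0.0
        assert report.converged

    def test_infeasible_targets_name_binding_constraint(self):
        bad = sc.CalibrationTargets(
            elimination_training=0.40,  # > 1 - survival_d4
            elimination_rest=0.05,
            formation_training=0.1,
            formation_rest=0.1,
            survival_d4=0.8,
            survival_d8=0.7,
            stabilization=0.3,
        )
        with pytest.raises(ValueError, match="elimination_training"):
            sc.calibrate_preset(bad)
        with pytest.raises(ValueError, match="survival_d8"):
            sc.CalibrationTargets(0.1, 0.05, 0.1, 0.1, 0.7, 0.8, 0.3).validate()

    def test_roundtrip_on_self_consistent_targets(self):
        """Measure a known preset's emergent fractions on a large cohort,
        calibrate to them, and check the calibrated preset reproduces every
        target within +-0.01 (the module's own acceptance oracle)."""
        source = sc.CohortPreset(
            p_survive_training=0.80,
            p_survive_rest_pre=0.90,
            p_stabilize_new=0.40,
            formation_intensity_training=0.12,
            formation_intensity_rest=0.10,
        )
        # cohorts large enough that the Monte-Carlo noise of the source and
        # verification simulations (~0.005 on the stabilization fraction) sits
        # well inside the +-0.01 calibration contract
        n_check = 12_000
        segs = sc.sample_cohort(source, TRAIN_REST, seed=77, n_segments=n_check, n_mice=6)
        tab = ts.segment_statistics(sc.lineage_table(segs), sc.segments_frame(segs))
        targets = sc.CalibrationTargets(
            elimination_training=tab.elimination_training.mean(),
            elimination_rest=tab.elimination_rest.mean(),
            formation_training=tab.formation_training.mean(),
            formation_rest=tab.formation_rest.mean(),
            survival_d4=tab.survival_d4.mean(),
            survival_d8=tab.survival_d8.mean(),
            stabilization=tab.stabilization_new.mean(),
        )
        preset, report = sc.calibrate_preset(targets, seed=5, n_segments=1500)
        assert report.converged
        check = sc.sample_cohort(preset, TRAIN_REST, seed=123, n_segments=n_check, n_mice=6)
        got = ts.segment_statistics(sc.lineage_table(check), sc.segments_frame(check))
        achieved = {
            "elimination_training": got.elimination_training.mean(),
            "elimination_rest": got.elimination_rest.mean(),
            "formation_training": got.formation_training.mean(),
            "formation_rest": got.formation_rest.mean(),
            "survival_d4": got.survival_d4.mean(),
            "survival_d8": got.survival_d8.mean(),
            "stabilization": got.stabilization_new.mean(),
        }
        for key, want in dataclasses.asdict(targets).items():
            assert achieved[key] == pytest.approx(want, abs=0.012), key

    def test_rest_only_schedule_uses_rest_parameters(self, wt_preset):
        segs = sc.sample_cohort(wt_preset, REST_ONLY, seed=3, n_segments=1500, n_mice=6)
        lin = sc.lineage_table(segs, REST_ONLY)
        base = lin[(lin.size_class == "beta") & lin.present_d0]
        p = base.present_d4.mean()
        e = wt_preset.p_survive_rest_pre
        assert abs(p - e) < 3 * np.sqrt(e * (1 - e) / len(base))
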
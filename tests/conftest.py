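import numpy as np
import pytest

from boutonflux import imagesim, synthcohort
from boutonflux.schedule import TRAIN_REST
from boutonflux.synthcohort import BoutonGroundTruth, CohortPreset, SegmentGroundTruth


@pytest.fixture(scope="session")
def wt_preset():
    """Wild-type preset calibrated once per session."""
    return synthcohort.wt_preset(seed=0)


@pytest.fixture(scope="session")
def mecp2_preset():
    return synthcohort.mecp2dup_preset(seed=0)


@pytest.fixture
def static_preset():
    """No dynamics at all: every bouton persists, nothing forms."""
    return CohortPreset(
        p_survive_training=1.0,
        p_survive_rest_pre=1.0,
        p_stabilize_new=1.0,
        formation_intensity_training=0.0,
        formation_intensity_rest=0.0,
        alpha_p_survive_4d=1.0,
        alpha_formation_intensity=0.0,
    )


@pytest.fixture
def noise_free_spec():
    return imagesim.ImagingSpec(
        noise_model="none", slow_drift_amplitude_px=0.0, fast_jitter_amplitude_px=0.0
    )


def make_spaced_segment(segment_id: str = "spaced", length: float = 120.0) -> SegmentGroundTruth:
    """Hand-built segment with >=5 um spacing and known per-day dynamics."""
    spec = [
        # (arc, diameter, birth_day, death_day)
        (10.0, 1.2, -1, None),
        (17.0, 1.5, -1, 4),  # eliminated during training
        (25.0, 2.5, -1, None),  # stable alpha
        (33.0, 1.1, -1, None),
        (41.0, 3.0, -1, None),  # stable alpha
        (52.0, 1.8, -1, 8),  # eliminated during rest
        (64.0, 2.2, -1, None),
        (78.0, 1.3, 4, None),  # training-formed, stabilized
        (95.0, 1.4, 4, 8),  # training-formed, not stabilized
        (110.0, 1.6, 8, None),  # rest-formed
    ]
    seg = SegmentGroundTruth(segment_id, "m0", "WT", length)
    for i, (pos, diam, birth, death) in enumerate(spec):
        seg.boutons.append(
            BoutonGroundTruth(
                bouton_id=f"{segment_id}:b{i}",
                segment_id=segment_id,
                arc_position=pos,
                diameter=diam,
                size_class="alpha" if diam > 2.0 else "beta",
                birth_day=birth,
                death_day=death,
            )
        )
    return seg


@pytest.fixture
def spaced_segment():
    return make_spaced_segment()


def truth_calls(segment: SegmentGroundTruth, day: int):
    """Per-day call table straight from ground truth (no detection noise)."""
    import pandas as pd

    present = segment.present(day)
    return pd.DataFrame(
        {
            "arc_position_um": [b.arc_position for b in present],
            "diameter_um": [b.diameter for b in present],
            "size_class": [b.size_class for b in present],
        }
    ).sort_values("arc_position_um", ignore_index=True)
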
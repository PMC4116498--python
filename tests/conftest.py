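"""Shared fixtures: pulse/phantom, a fast small-geometry design, and a
session-scoped batch of analyzed default cohorts for the heavy end-to-end
checks (computed once, shared by several tests)."""

import numpy as np
import pytest

import qustex as qx
from qustex.pipeline import group_mean_shifts
from qustex.simulate import CohortDesign

#: reduced geometry for unit tests that only need a working pipeline
SMALL_DESIGN = CohortDesign(
    extent=(12.0, 12.0),
    n_planes=1,
    plane_spacing=4.0,
    tumor_radius_range=(4.0, 4.5),
    focal_depth=6.0,
)


@pytest.fixture(scope="session")
def pulse():
    return qx.make_pulse(7.0, 0.6, 40.0)


@pytest.fixture(scope="session")
def phantom(pulse):
    return qx.simulate_phantom_frame(pulse, qx.AcquisitionSettings(), seed=7)


@pytest.fixture(scope="session")
def small_phantom(pulse):
    settings = qx.AcquisitionSettings(
        extent=SMALL_DESIGN.extent,
        lateral_pitch=SMALL_DESIGN.lateral_pitch,
        focal_depth=SMALL_DESIGN.focal_depth,
    )
    return qx.simulate_phantom_frame(pulse, settings, seed=11)


@pytest.fixture(scope="session")
def cohort_batch():
    """20 analyzed default-condition cohorts (15 responders / 5 non-responders).

    Keeps only light summaries (measured group shifts, programmed shifts,
    classification table) so memory stays bounded.
    """
    out = []
    for seed in range(100, 120):
        patients = qx.simulate_cohort(15, 5, seed=seed)
        res = qx.analyze_cohort(patients)
        drawn = {}
        for lab in ("responder", "non-responder"):
            drawn[lab] = {}
            for visit in ("wk1", "wk4"):
                vals = [
                    p.true_shifts[visit][0]
                    for p in patients
                    if p.true_label == lab and visit in p.true_shifts
                ]
                drawn[lab][visit] = float(np.mean(vals))
        out.append(
            {
                "seed": seed,
                "drawn_mbf": drawn,
                "shifts": group_mean_shifts(res.visit_table, "mbf"),
                "classification": res.classification,
            }
        )
    return out
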
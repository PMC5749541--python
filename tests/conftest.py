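import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def bundle():
    """One full simulated screen (study-shaped defaults), shared across tests."""
    from pace.synthetic_cohort import simulate_screen

    return simulate_screen(seed=7, with_omics=True)


@pytest.fixture(scope="session")
def cll_view(bundle):
    """CLL-only slice of the shared screen: tensor, features, annotation, survival."""
    from pace.screen_core import qc_exclude_drugs

    cll = bundle.cohort.cll_ids
    tensor = qc_exclude_drugs(bundle.tensor, ["bortezomib"]).select_samples(cll)
    features = bundle.cohort.features.loc[cll]
    annotation = bundle.cohort.annotation.loc[cll]
    surv_os = (
        bundle.survival[bundle.survival["endpoint"] == "OS"]
        .set_index("sample_id")[["time_days", "event"]]
    )
    return dict(
        tensor=tensor,
        features=features,
        annotation=annotation,
        surv_os=surv_os,
        truth=bundle.cohort.truth,
    )


def make_plate(plate_id="P1", sample_id="S1", controls=(1000.0,) * 32, treated=None):
    """Small plate builder used by several screen_core tests."""
    from pace.screen_core import PlateReading, WellAssignment

    treated = treated or {}
    wells, layout = {}, {}
    i = 0
    coords = [f"{r}{c}" for r in "ABCDEFGHIJKLMNOP" for c in range(1, 25)]
    for (drug, conc), rlu in treated.items():
        w = coords[i]
        wells[w] = rlu
        layout[w] = WellAssignment("treated", drug, conc)
        i += 1
    for rlu in controls:
        w = coords[i]
        wells[w] = rlu
        layout[w] = WellAssignment("dmso_control")
        i += 1
    return PlateReading(plate_id, sample_id, wells, layout)
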
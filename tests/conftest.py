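import numpy as np
import pandas as pd
import pytest

from ceeagree import PairedTrialData, SimConfig, simulate_paired_trial


def make_data(control, intervention, adverse=True):
    """Build a PairedTrialData from per-arm lists of (c1, y1, c2, y2)."""
    rows = []
    for arm, recs in (("control", control), ("intervention", intervention)):
        for j, (c1, y1, c2, y2) in enumerate(recs):
            rows.append(
                {
                    "patient_id": f"{arm}-{j}",
                    "arm": arm,
                    "cost_1": c1,
                    "outcome_1": y1,
                    "cost_2": c2,
                    "outcome_2": y2,
                }
            )
    return PairedTrialData(frame=pd.DataFrame(rows), adverse_outcome=adverse)


def random_paired_data(rng, n_min=5, n_max=40):
    """Random valid paired dataset with nondegenerate arms."""
    rows = []
    for arm in ("control", "intervention"):
        n = int(rng.integers(n_min, n_max + 1))
        c = rng.gamma(2.0, 500.0, size=n)
        y = (rng.random(n) < rng.uniform(0.2, 0.8)).astype(float)
        c2 = np.maximum(c + rng.normal(0, 100.0, size=n), 0.0)
        y2 = np.where(rng.random(n) < 0.1, 1 - y, y)
        for j in range(n):
            rows.append((arm, c[j], y[j], c2[j], y2[j]))
    frame = pd.DataFrame(
        rows, columns=["arm", "cost_1", "outcome_1", "cost_2", "outcome_2"]
    )
    frame.insert(0, "patient_id", [f"p{j}" for j in range(len(frame))])
    return PairedTrialData(frame=frame, adverse_outcome=bool(rng.integers(0, 2)))


@pytest.fixture
def toy_data():
    """4-patient dataset small enough to verify by hand."""
    return make_data(
        control=[(100.0, 0, 110.0, 0), (200.0, 1, 190.0, 1)],
        intervention=[(50.0, 1, 60.0, 1), (150.0, 1, 140.0, 1)],
        adverse=False,
    )


@pytest.fixture
def identical_sources_data():
    """Sources 1 and 2 exactly equal per patient (noiseless linkage)."""
    cfg = SimConfig(
        n_control=80,
        n_intervention=80,
        source_cost_sd_1=0.0,
        source_cost_sd_2=0.0,
        misclass_1=0.0,
        misclass_2=0.0,
        seed=42,
    )
    return simulate_paired_trial(cfg)


@pytest.fixture
def mirror_arms_data():
    """Intervention arm is an exact copy of the control arm (true INB 0)."""
    cfg = SimConfig(
        n_control=150,
        n_intervention=2,  # placeholder; replaced by the copy below
        source_cost_sd_1=0.0,
        source_cost_sd_2=0.0,
        misclass_1=0.0,
        misclass_2=0.0,
        seed=7,
    )
    base = simulate_paired_trial(cfg)
    ctl = base.frame[base.frame["arm"] == "control"].copy()
    mirror = ctl.copy()
    mirror["arm"] = "intervention"
    mirror["patient_id"] = "m-" + mirror["patient_id"]
    frame = pd.concat([ctl, mirror], ignore_index=True)
    return PairedTrialData(frame=frame, adverse_outcome=True)
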
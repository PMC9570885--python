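import numpy as np
import pytest

from esngait.core_io import TimeseriesRecord
from esngait.labeling import (
    LabelingConfig,
    label_events_from_force,
    middle_stance_indices,
    split_train_test,
)
from esngait.synthgait import GaitSimSpec, make_dataset


def heel_toe(forces: TimeseriesRecord) -> tuple[TimeseriesRecord, TimeseriesRecord]:
    heel = TimeseriesRecord(forces.data[:1], forces.fs, ["heel"])
    toe = TimeseriesRecord(forces.data[1:2], forces.fs, ["toe"])
    return heel, toe


def nearest_errors(true_idx: np.ndarray, found_idx: np.ndarray) -> np.ndarray:
    """Distance (samples) from each true index to its nearest found index."""
    if found_idx.size == 0:
        return np.full(true_idx.size, np.inf)
    return np.abs(true_idx[:, None] - found_idx[None, :]).min(axis=1)


def build_split_dataset(n_series: int = 10, duration_s: float = 120.0,
                        noise_sd: float = 0.01, seed0: int = 100,
                        frac: float = 0.7):
    """Simulate, label from forces and MSP-split a mixed-cadence dataset."""
    cadences = np.linspace(0.8, 1.2, n_series)
    specs = [GaitSimSpec(duration_s=duration_s, cadence_hz=float(c),
                         cycle_jitter=0.02, amp_jitter=0.05,
                         noise_sd=noise_sd, seed=seed0 + i)
             for i, c in enumerate(cadences)]
    train_set, test_set = [], []
    for accel, forces, _truth in make_dataset(specs):
        heel, toe = heel_toe(forces)
        targets = label_events_from_force(heel, toe, LabelingConfig())
        msp = middle_stance_indices(targets, "HS_TO_mean")
        tr, te = split_train_test(accel, targets, msp, frac)
        train_set.append(tr)
        test_set.append(te)
    return train_set, test_set


@pytest.fixture(scope="session")
def clean_recording():
    """One noiseless, jitter-free recording with its forces and truth."""
    spec = GaitSimSpec(duration_s=60.0, cadence_hz=1.0, seed=1)
    from esngait.synthgait import generate_gait
    return (spec,) + generate_gait(spec)
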
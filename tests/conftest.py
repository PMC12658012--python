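import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from fibseg.synthetic_ct import PhantomParams, generate_phantom
from fibseg.volume_io import CaseRecord, Manifest


@pytest.fixture(scope="session")
def noiseless_phantom():
    return generate_phantom(PhantomParams(noise_sd=0.0, seed=3))


@pytest.fixture(scope="session")
def noisy_phantom():
    return generate_phantom(PhantomParams(seed=4))


def make_cohort_manifest(n_right_only: int, n_left_only: int, n_both: int) -> Manifest:
    """In-memory manifest with the given laterality profile (paths are symbolic)."""
    records = []
    i = 0
    for _ in range(n_right_only):
        records.append(CaseRecord(f"c{i:03d}", f"c{i:03d}.nii", None, f"c{i:03d}_r.nii"))
        i += 1
    for _ in range(n_left_only):
        records.append(CaseRecord(f"c{i:03d}", f"c{i:03d}.nii", f"c{i:03d}_l.nii", None))
        i += 1
    for _ in range(n_both):
        records.append(
            CaseRecord(f"c{i:03d}", f"c{i:03d}.nii", f"c{i:03d}_l.nii", f"c{i:03d}_r.nii")
        )
        i += 1
    return Manifest(records, provenance="in-memory")


@pytest.fixture(scope="session")
def clinical_profile_manifest():
    """The laterality profile of the motivating cohort: 13 right-only,
    26 left-only, 36 both-sided."""
    return make_cohort_manifest(13, 26, 36)
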
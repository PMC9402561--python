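"""Shared fixtures: a session-scoped phantom dataset and its ground truth."""

from pathlib import Path

import nibabel as nib
import numpy as np
import pytest

import qmribids as q


@pytest.fixture(scope="session")
def phantom_root(tmp_path_factory) -> Path:
    """A noiseless default-phantom dataset covering all 14 suffixes."""
    base = tmp_path_factory.mktemp("phantom")
    return q.generate_dataset(
        q.default_phantom_spec(), q.default_protocols(), base / "ds"
    )


@pytest.fixture(scope="session")
def truth(phantom_root) -> dict[str, np.ndarray]:
    truth_dir = phantom_root.parent / f"{phantom_root.name}_truth"
    return {
        p.name.split(".")[0]: np.asanyarray(nib.load(str(p)).dataobj).astype(float)
        for p in truth_dir.glob("*.nii.gz")
    }


@pytest.fixture(scope="session")
def collections_by_suffix(phantom_root):
    out: dict[str, list] = {}
    for c in q.group_collections(phantom_root):
        out.setdefault(c.suffix, []).append(c)
    return out
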
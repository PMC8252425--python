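"""Shared fixtures: presets and one fully generated synthetic volume.

Generation is deterministic (fixed seeds), so session-scoped fixtures
are safe and keep the suite fast.
"""

import numpy as np
import pytest

from cortimorph import (
    build_reference_frame,
    build_support_index,
    generate_annotation,
    load_preset,
    measure_all_yshapes,
)


@pytest.fixture(scope="session")
def cba1():
    return load_preset("cba1")


@pytest.fixture(scope="session")
def cba1_volume(cba1):
    """Full CBA1 synthetic volume (seed 1): annotation + ground truth."""
    return generate_annotation(cba1, 1)


@pytest.fixture(scope="session")
def cba1_frame(cba1, cba1_volume):
    aset, _ = cba1_volume
    return build_reference_frame(aset, cba1.basal_hint)


@pytest.fixture(scope="session")
def cba1_yshapes(cba1_volume, cba1_frame):
    aset, _ = cba1_volume
    return measure_all_yshapes(aset, cba1_frame)


@pytest.fixture(scope="session")
def cba1_support(cba1_volume):
    aset, _ = cba1_volume
    return build_support_index(
        aset.trees_of_class("DC") + aset.trees_of_class("OPC")
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
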
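"""Shared fixtures: phantoms and dose grids reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from sctqa.dose import compute_plan_dose, default_plan
from sctqa.phantom import ErrorMode, PhantomSpec, generate_phantom_pair


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A coarser head phantom (same anatomy, 3 mm voxels) for fast tests."""
    return PhantomSpec(grid_shape=(64, 64, 64), spacing_mm=(3.0, 3.0, 3.0))


@pytest.fixture(scope="session")
def phantom_pair(default_spec):
    return generate_phantom_pair(default_spec, ErrorMode.none())


@pytest.fixture(scope="session")
def small_pair(small_spec):
    return generate_phantom_pair(small_spec, ErrorMode.none())


@pytest.fixture(scope="session")
def small_plan(small_spec):
    return default_plan(small_spec.ptv_center, small_spec.ptv_radius_mm)


@pytest.fixture(scope="session")
def small_ct_dose(small_pair, small_plan):
    """(dose volume, mu_factor) of the small CT phantom."""
    return compute_plan_dose(small_pair.ct, small_plan, ptv=small_pair.structure("PTV"))
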
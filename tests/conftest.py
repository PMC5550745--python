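"""Shared fixtures.

The expensive fixture is the full 160-cell study cohort run end-to-end
through the pipeline; it is computed once per session and shared by the
cluster-recovery, discriminant, tree and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gliamorph.synthetic import default_cohort, generate_cohort, load_presets, cell_rng, render_cell
from gliamorph.workflow import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def presets():
    return load_presets()


@pytest.fixture(scope="session")
def cohort_run():
    """Full default cohort (160 cells, seed 42) through every stage."""
    return run_pipeline(default_cohort(seed=42), PipelineConfig(seed=42))


@pytest.fixture(scope="session")
def small_cells(presets):
    """Two rendered cells per archetype (fixed sub-seeds) for shape tests."""
    out = {}
    for name, spec in presets.items():
        out[name] = [render_cell(spec, cell_rng(7, 1000 + i)) for i in range(2)]
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
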
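"""Shared fixtures: the canonical phantom (seed 1) and its pipeline run."""

from __future__ import annotations

import numpy as np
import pytest

from ratioimg.core_io import write_regions, write_stack
from ratioimg.pipeline import PipelineConfig, run_pipeline_arrays
from ratioimg.synthetic import default_neuron_phantom, default_neuron_regions

PHANTOM_SEED = 1


@pytest.fixture(scope="session")
def phantom():
    """(donor, acceptor, truth) for the canonical default phantom."""
    return default_neuron_phantom(PHANTOM_SEED)


@pytest.fixture(scope="session")
def phantom_regions():
    return default_neuron_regions()


@pytest.fixture(scope="session")
def phantom_pipeline(phantom, phantom_regions):
    """Full default pipeline run (in memory) on the canonical phantom."""
    donor, acceptor, _ = phantom
    config = PipelineConfig(donor="", acceptor="", regions="", out_dir="")
    (donor_masked, acceptor_clean, masks, ratio, drange, table, log) = run_pipeline_arrays(
        donor.copy(), acceptor.copy(), phantom_regions, config
    )
    return {
        "donor_masked": donor_masked,
        "acceptor_clean": acceptor_clean,
        "masks": masks,
        "ratio": ratio,
        "display_range": drange,
        "table": table,
        "log": log,
    }


@pytest.fixture(scope="session")
def phantom_dir(tmp_path_factory, phantom, phantom_regions):
    """Phantom written to disk (D.tif, A.tif, regions.json) for file-based tests."""
    donor, acceptor, _truth = phantom
    path = tmp_path_factory.mktemp("phantom")
    write_stack(donor, path / "D.tif", depth="32-bit-float")
    write_stack(acceptor, path / "A.tif", depth="32-bit-float")
    write_regions(phantom_regions, path / "regions.json")
    return path


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
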
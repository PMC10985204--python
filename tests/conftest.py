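"""Shared fixtures: synthetic scenes sized so the whole suite stays fast."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from micsflow import synth, workflow


@pytest.fixture(scope="session")
def seg_scene():
    """Well-separated SNR-10 scene with >=200 cells and one marker.

    SNR = nuclear DAPI rate / read-noise sd = 30 / 3 = 10.
    """
    types = (
        synth.CellType("pos", 0.5, synth.profile({"M"}, ["M"])),
        synth.CellType("neg", 0.5, synth.profile(set(), ["M"])),
    )
    spec = synth.TissueSpec(
        width_px=640, height_px=640, n_cells=220, pixel_size_um=0.5,
        cell_types=types, noise_sd=3.0, dapi_rate=30.0, seed=42,
    )
    stack, truth = synth.generate_tissue(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def tiny_config(tmp_path_factory):
    out = tmp_path_factory.mktemp("tiny_run")
    return workflow.RunConfig(
        out_dir=str(out / "run"),
        seed=11,
        synth=workflow.SynthConfig(n_cells=60, width_px=384, height_px=384),
    )


@pytest.fixture(scope="session")
def tiny_run(tiny_config):
    """One small end-to-end pipeline run shared by the workflow tests."""
    run_dir = workflow.run_pipeline(tiny_config)
    return tiny_config, run_dir


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
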
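"""Shared fixtures: simulated cells reused across the suite."""

import numpy as np
import pytest

from ecckymo import AnalysisConfig, SimCellParams, analyze_run, simulate_cell

LINE_MS = 1.24  # acquisition line period of the emulated recordings


def run_cell(params, beats=1):
    """Simulate and analyze one cell with the operator-style search window."""
    kymo, truth = simulate_cell(params, cell_id="cell")
    cfg = AnalysisConfig(beats_to_analyze=beats,
                         search_start_ms=max(params.first_stim_ms - 50.0, 0.0))
    result = analyze_run(kymo, cfg)
    return kymo, truth, result


@pytest.fixture(scope="session")
def representative_cell():
    """Noiseless cell with the representative female parameter set."""
    params = SimCellParams(noise_sd=0.0, n_lines=2000, first_stim_ms=250.0,
                           seed=0)
    kymo, truth, result = run_cell(params)
    assert result.status == "ok"
    return params, kymo, truth, result


@pytest.fixture(scope="session")
def representative_row(representative_cell):
    _, _, truth, result = representative_cell
    return result.to_rows()[0], truth.beats.iloc[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
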
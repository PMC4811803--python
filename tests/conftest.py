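"""Shared fixtures: synthetic movies at test scale and their measurements.

Scenario movies are generated once per session (the Potts runs are the
expensive part) and measured with a single patch covering the whole cell
group, which is the natural frame for single-process validation runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from epimorph.kinematics import measure_movie, window_average, rates_tensor
from epimorph.morphosim import ScenarioConfig, run_scenario
from epimorph.tensors import SymTensor2, tensor_norm

SYMBOLS = ("G", "S", "D", "R", "A", "N", "C", "J")

#: test-scale study conditions: 61 frames (5 min apart, a 5 h movie) of a
#: patch of ~80 cells; lattice sizes leave room for growth or stretching
SCENARIO_PARAMS = {
    "rearrangements": dict(frames=61, size=220, n_cells=80,
                           steps_per_frame=30, seed=1, force_x=6.0),
    "divisions": dict(frames=61, size=260, n_cells=80,
                      steps_per_frame=30, seed=2, force_x=6.0),
    "delamination": dict(frames=61, size=220, n_cells=80,
                         steps_per_frame=30, seed=3),
    "fusion": dict(frames=61, size=220, n_cells=80,
                   steps_per_frame=30, seed=4),
    "flux": dict(frames=61, size=220, n_cells=80,
                 steps_per_frame=30, seed=5),
    "integration": dict(frames=61, size=220, n_cells=80,
                        steps_per_frame=30, seed=3),
    "shape_affine": dict(frames=21, size=600, n_cells=100, seed=11,
                         dilation_rate=1e-2, ce_rate=1e-2),
    "rotation": dict(frames=21, size=420, n_cells=80, seed=12),
    "ce_roundtrip": dict(frames=21, size=420, n_cells=80, seed=12,
                         ce_rate=1e-2),
}

DT_MIN = 5.0


class MeasuredScenario:
    def __init__(self, name: str):
        cfg = ScenarioConfig(scenario=name, **SCENARIO_PARAMS[name])
        self.config = cfg
        self.result = run_scenario(cfg)
        self.rates = measure_movie(
            self.result.stack, self.result.lineage,
            pixel_size=1.0, dt_min=DT_MIN, box_px=1 << 14, overlap=0.0,
        )
        self.window = window_average(self.rates).iloc[0]

    def tensor(self, symbol: str) -> SymTensor2:
        return rates_tensor(self.window, symbol)

    @property
    def balance_residual_rel(self) -> float:
        """Relative balance residual of the window-averaged tensors."""
        g = self.tensor("G")
        total = SymTensor2.zero()
        scale = tensor_norm(g)
        psum = 0.0
        for s in SYMBOLS[1:]:
            t = self.tensor(s)
            total = total + t
            psum += tensor_norm(t)
        scale = max(scale, psum)
        if scale == 0:
            return 0.0
        return tensor_norm(g - total) / scale


_cache: dict[str, MeasuredScenario] = {}


def get_scenario(name: str) -> MeasuredScenario:
    if name not in _cache:
        _cache[name] = MeasuredScenario(name)
    return _cache[name]


@pytest.fixture(scope="session")
def scenario():
    return get_scenario


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


# ---------------------------------------------------------------------------
# small hand-built label images
# ---------------------------------------------------------------------------

def block_grid(nx: int = 5, ny: int = 5, cell: int = 6) -> np.ndarray:
    """A (ny*cell, nx*cell) label image of rectangular cells labelled
    row-major starting at 1."""
    img = np.zeros((ny * cell, nx * cell), dtype=np.uint32)
    lab = 1
    for j in range(ny):
        for i in range(nx):
            img[j * cell:(j + 1) * cell, i * cell:(i + 1) * cell] = lab
            lab += 1
    return img


def trivial_lineage_df(labels, last_frame: int) -> pd.DataFrame:
    return pd.DataFrame([
        dict(cell_id=int(c), mother_id=-1, first_frame=0,
             last_frame=last_frame, fate="survives", fate_partner=-1)
        for c in labels
    ])


@pytest.fixture()
def block_image():
    return block_grid()
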
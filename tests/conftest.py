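import numpy as np
import pandas as pd
import pytest

import tetrascreen as ts
from tetrascreen.simulate import IntensityModel, TruthConfig


@pytest.fixture(scope="session")
def base_profile():
    return ts.dcd_default_profile()


@pytest.fixture(scope="session")
def noiseless_model():
    return IntensityModel(dapi_cv=0.0, fucci_cv=0.0)


@pytest.fixture(scope="session")
def small_screen():
    """A compact simulated screen shared by pipeline-level tests."""
    design = ts.build_screen_design(60, 384, n_replicates=2, seed=42)
    cfg = TruthConfig(hit_fraction=0.05, effect_size=1.5, n_cells_per_well=300)
    cells, truth = ts.simulate_screen(design, cfg, seed=42)
    return design, cells, truth


@pytest.fixture(scope="session")
def small_screen_scored(small_screen):
    design, cells, truth = small_screen
    _, profiles = ts.classify_wells(cells)
    zscores = ts.plate_zscores(profiles, design.table)
    return design, truth, profiles, zscores


def inset_core_ranges(dapi_cv: float = 0.12) -> dict[str, tuple[float, float]]:
    """S-phase content ranges kept clear of the gate boundaries.

    The core of each S window is the band at least two log-noise SDs inside
    its boundaries (binucleated classes use the per-nucleus noise reduced by
    sqrt(2), since their DAPI is a two-draw sum); where a window is narrower
    than four SDs, its geometric midpoint is used.
    """
    sig = float(np.sqrt(np.log1p(dapi_cv**2)))

    def band(lo, hi, s):
        llo, lhi = np.log(lo) + 2 * s, np.log(hi) - 2 * s
        if llo >= lhi:
            mid = 0.5 * (np.log(lo) + np.log(hi))
            llo = lhi = mid
        return float(np.exp(llo)), float(np.exp(lhi) + 1e-12)

    return {"2CS": band(1.25, 1.75, sig), "4CS": band(2.25, 3.5, sig / np.sqrt(2))}
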
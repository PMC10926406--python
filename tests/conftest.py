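"""Shared fixtures: small synthetic worlds and scalar reference oracles."""

from __future__ import annotations

import numpy as np
import pytest

from perilmap.params import faw_default
from perilmap.synthetic_world import WorldConfig, make_climate_world
from perilmap.engine import run_scenarios


@pytest.fixture(scope="session")
def small_config() -> WorldConfig:
    # same +/-40 deg window as the default world, 8x coarser cells;
    # irrigation patches sit inside the two desert belts (|lat| 15-25)
    return WorldConfig(
        n_lon=60,
        n_lat=30,
        resolution=160.0,
        irrigation_patches=((21, 24, 10, 20), (6, 9, 35, 50)),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    return make_climate_world(small_config)


@pytest.fixture(scope="session")
def small_surface(small_world):
    return run_scenarios(small_world.climate, faw_default(), small_world.irrigation_mask)


# ---------------------------------------------------------------------------
# independent scalar reference for the suitability engine (plain python loops)


def scalar_cell_suitability(rain, temp, params, topup):
    """Per-cell scalar reference: (GI, EI, generations) from weekly lists."""
    cap = params.bucket_capacity
    store = cap / 2.0
    sm = [0.0] * 52
    for cycle in range(2):
        for w in range(52):
            evap = max(0.0, params.evap_coeff * temp[w])
            store = store + rain[w] + 7.0 * topup - evap
            store = min(max(store, 0.0), 2.0 * cap)
            if cycle == 1:
                sm[w] = store / cap

    def trap(x, a, b, c, d):
        if x <= a or x >= d:
            return 0.0
        if x < b:
            return (x - a) / (b - a)
        if x <= c:
            return 1.0
        return (d - x) / (d - c)

    gi = 0.0
    cs = ds = hs = ws = 0.0
    dd = 0.0
    for w in range(52):
        ti = trap(temp[w], params.DV0, params.DV1, params.DV2, params.DV3)
        mi = trap(sm[w], params.SM0, params.SM1, params.SM2, params.SM3)
        gi += ti * mi
        cs += params.THCS * max(0.0, params.TTCS - temp[w])
        hs += params.THHS * max(0.0, temp[w] - params.TTHS)
        ds += params.HDS * max(0.0, params.SMDS - sm[w])
        ws += params.HWS * max(0.0, sm[w] - params.SMWS)
        dd += 7.0 * max(0.0, temp[w] - params.DV0)
    gi = 100.0 * gi / 52.0
    ei = gi
    for s in (cs, ds, hs, ws):
        ei *= 1.0 - min(100.0, s) / 100.0
    return gi, ei, int(dd // params.PDD)


@pytest.fixture(scope="session")
def scalar_engine():
    return scalar_cell_suitability
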
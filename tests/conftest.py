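"""Shared fixtures: generated programmatically, nothing read from disk."""

from __future__ import annotations

import numpy as np
import pytest

import waterpet as wp


@pytest.fixture(scope="session")
def schedule():
    return wp.FrameSchedule.default()


@pytest.fixture(scope="session")
def aif():
    return wp.make_aif()


@pytest.fixture(scope="session")
def brain_phantom():
    return wp.make_brain_phantom()


@pytest.fixture(scope="session")
def small_phantom():
    """Small brain phantom for Monte-Carlo loops."""
    return wp.make_brain_phantom(
        shape=(32, 32, 20), gm_volume_cm3=55.0, wm_volume_cm3=35.0, deep_gm_volume_cm3=6.0
    )


@pytest.fixture(scope="session")
def nema_1mm():
    return wp.make_nema_phantom(voxel_size=1.0)


@pytest.fixture(scope="session")
def nema_2mm():
    return wp.make_nema_phantom(voxel_size=2.0)


@pytest.fixture(scope="session")
def recovery_library_1mm(nema_1mm):
    """Full 131-point recovery library on the 1 mm phantom (cached)."""
    return wp.simulate_recovery_library(nema_1mm)


def synth_cbf_table(rng=None, n_subjects=8, methods=("A", "B", "C")):
    """Small random long-format CBF table with a complete crossing."""
    import pandas as pd

    rng = rng or np.random.default_rng(7)
    rows = []
    for s in range(n_subjects):
        base = rng.uniform(0.4, 0.7)
        for m in methods:
            for region, scale in (("WB", 1.0), ("GM", 1.15), ("CWM", 0.5)):
                for quant in ("regional", "voxelwise"):
                    rows.append(
                        {
                            "subject": s,
                            "method": m,
                            "region": region,
                            "quantification": quant,
                            "cbf": base * scale * rng.uniform(0.95, 1.05),
                        }
                    )
    return pd.DataFrame(rows)
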
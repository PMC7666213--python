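"""Shared fixtures: small simulated fields and table builders.

Everything is generated programmatically with fixed seeds; no data
files are used.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from barrelpaint.geometry import external_diameter, get_preset
from barrelpaint.simulate import (
    LocalizationTable,
    SimConfig,
    place_particles,
    simulate_experiment,
)


def make_table(
    frame: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray | None = None,
    n_frames: int | None = None,
    round_id: str = "R1",
) -> LocalizationTable:
    """LocalizationTable from bare arrays, with decorative columns filled."""
    n = len(frame)
    df = pd.DataFrame(
        {
            "frame": np.asarray(frame, dtype=np.int64),
            "round": round_id,
            "x": np.asarray(x, dtype=float),
            "y": np.asarray(y, dtype=float),
            "z": np.zeros(n) if z is None else np.asarray(z, dtype=float),
            "photons": np.full(n, 1000.0),
            "background": np.full(n, 10.0),
            "sx": np.full(n, 130.0),
            "sy": np.full(n, 130.0),
        }
    )
    df = df.sort_values("frame", kind="stable").reset_index(drop=True)
    meta = {"round": round_id, "n_frames": int(n_frames or (df["frame"].max() + 1))}
    return LocalizationTable(df, meta)


def blinking_sites_table(
    sigma: float,
    seed: int,
    n_sites: int = 36,
    n_frames: int = 600,
    p_on: float = 0.35,
    field: float = 2000.0,
) -> LocalizationTable:
    """Fixed sites re-localized in many frames: the NeNA test fixture."""
    rng = np.random.default_rng(seed)
    sites = rng.uniform(0.0, field, (n_sites, 2))
    frames, xs, ys = [], [], []
    for s in sites:
        on = np.flatnonzero(rng.random(n_frames) < p_on)
        xy = s + rng.normal(0.0, sigma, (len(on), 2))
        frames.append(on)
        xs.append(xy[:, 0])
        ys.append(xy[:, 1])
    return make_table(
        np.concatenate(frames), np.concatenate(xs), np.concatenate(ys), n_frames=n_frames
    )


@pytest.fixture(scope="session")
def monomer_field():
    """A simulated field of 40 upright 30-nm barrels with full labeling."""
    spec = get_preset("30-27")
    cfg = SimConfig(
        field_size=(1500.0, 1500.0), n_frames=1000, binding_rate=0.015,
        mean_bright_time=2.0, sigma_xy=4.0, labeling_p=1.0, seed=11,
    )
    truth = place_particles(spec, 40, "upright", cfg)
    table = simulate_experiment(truth, cfg)["R1"]
    return spec, cfg, truth, table


@pytest.fixture(scope="session")
def ring_particles():
    """Twenty ring-shaped particles (localization arrays) of radius 15.5."""
    rng = np.random.default_rng(7)
    parts = []
    for _ in range(20):
        ang = rng.uniform(0.0, 2 * np.pi, 300)
        ring = np.c_[15.5 * np.cos(ang), 15.5 * np.sin(ang), np.zeros(300)]
        parts.append(ring + rng.normal(0.0, 4.0, (300, 3)))
    return parts
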
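"""Synthetic multi-round Exchange-PAINT localization data.

Generates the record type the processing chain consumes: per-round
localization tables (frame, x, y, z, photons, fitted widths) from
fields of barrel particles carrying docking sites at designed
positions, with the statistical structure of DNA-PAINT data:

* per-site Bernoulli labeling (a docking strand is either incorporated
  and available, or not),
* transient imager binding as a Poisson process per occupied site with
  geometric bright-time, one localization per bright frame,
* isotropic Gaussian localization error (sigma_xy in the plane,
  sigma_z axially); z is generated directly rather than through
  astigmatic width fitting, which keeps the ground truth exact,
* a Gaussian random-walk stage drift shared by all emitters of a
  round, plus a rigid per-round misregistration (offset and rotation
  about the field centre) emulating Exchange-PAINT round changes,
* optional co-deposited registration-marker particles (compact site
  clusters with a high event rate) visible in every round.

All randomness flows through a single ``numpy.random.Generator`` seeded
from the config, so outputs are bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import (
    BarrelSpec,
    PixelSite,
    StackSpec,
    docking_ring,
    external_diameter,
    stack_positions,
)

__all__ = [
    "NENA_SIGMA_RANGE_NM",
    "SimConfig",
    "GroundTruth",
    "LocalizationTable",
    "SimulationError",
    "place_particles",
    "simulate_round",
    "simulate_experiment",
    "add_markers",
    "apply_field_z_aberration",
    "stack_sites",
]

#: Printed range of in-plane NeNA localization precisions (nm); the
#: default sigma_xy sits inside it.
NENA_SIGMA_RANGE_NM = (3.6, 6.3)

LOC_COLUMNS = ["frame", "round", "x", "y", "z", "photons", "background", "sx", "sy"]


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated Exchange-PAINT experiment.

    Rates are per frame; lengths in nm.  ``binding_rate`` times
    ``mean_bright_time`` times ``n_frames`` is the expected number of
    localizations per occupied site and round.
    """

    field_size: tuple[float, float] = (2000.0, 2000.0)
    n_frames: int = 2000
    rounds: tuple[str, ...] = ("R1",)
    binding_rate: float = 0.01
    mean_bright_time: float = 2.0
    sigma_xy: float = 4.0
    sigma_z: float = 7.2
    labeling_p: float = 0.71
    drift_step: float = 0.0
    round_offset_range: float = 0.0
    round_rotation_range_deg: float = 0.0
    n_markers: int = 0
    marker_n_sites: int = 4
    marker_site_spread: float = 5.0
    marker_rate_factor: float = 10.0
    photon_mean: float = 5000.0
    photon_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.labeling_p <= 1.0):
            raise ValueError("labeling_p must be in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for name in ("binding_rate", "mean_bright_time", "sigma_xy", "sigma_z",
                     "drift_step", "round_offset_range", "marker_site_spread"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    @property
    def expected_locs_per_site(self) -> float:
        return self.n_frames * self.binding_rate * self.mean_bright_time


@dataclass
class LocalizationTable:
    """Per-localization records of one Exchange-PAINT round."""

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "LocalizationTable":
        return LocalizationTable(self.df.copy(), dict(self.metadata))

    def coords(self, plane: str = "xy") -> np.ndarray:
        cols = {"xy": ["x", "y"], "xz": ["x", "z"], "yz": ["y", "z"]}[plane]
        return self.df[cols].to_numpy()

    @property
    def xyz(self) -> np.ndarray:
        return self.df[["x", "y", "z"]].to_numpy()


@dataclass
class GroundTruth:
    """Everything the simulator knows and the estimators must recover."""

    poses: pd.DataFrame          # particle, x, y, z, orientation, azimuth, axis_azimuth
    sites: pd.DataFrame          # particle, site, x, y, z, docking_id, occupied
    config: SimConfig
    geometry_name: str = ""
    drift: dict = field(default_factory=dict)          # round -> (n_frames, 3) cumulative
    round_offsets: dict = field(default_factory=dict)  # round -> (dx, dy, dz, theta_rad)
    markers: pd.DataFrame | None = None                # marker site coordinates

    def occupied_sites(self, round_id: str | None = None) -> pd.DataFrame:
        s = self.sites[self.sites.occupied]
        if round_id is not None:
            s = s[s.docking_id == round_id]
        return s


def _rot_z(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def stack_sites(stack: StackSpec, docking_id: str = "R1") -> list[PixelSite]:
    """Docking-ring sites of a decorated stack, in the stack frame with
    the origin at the stack's axial centre."""
    positions = stack_positions(stack)
    half = stack.height / 2.0
    sites: list[PixelSite] = []
    for pos in positions:
        spec, _ = stack.monomers[pos.monomer_index]
        for z in pos.ring_z:
            ring = docking_ring(spec, docking_id=docking_id, z=z - half)
            for s in ring:
                sites.append(
                    PixelSite(
                        surface=s.surface,
                        row_index=pos.monomer_index,
                        azimuth_index=s.azimuth_index,
                        position=s.position,
                        docking_id=docking_id,
                    )
                )
    return sites


def _geometry_sites(geometry, config: SimConfig) -> tuple[list[PixelSite], float, float]:
    """Default decoration, external diameter and height for a geometry."""
    if isinstance(geometry, StackSpec):
        sites = stack_sites(geometry)
        spec = geometry.monomers[0][0]
        return sites, external_diameter(spec, rounded=False), geometry.height
    if isinstance(geometry, BarrelSpec):
        sites = docking_ring(geometry, docking_id=config.rounds[0])
        return sites, external_diameter(geometry, rounded=False), geometry.monomer_height
    raise TypeError(f"geometry must be BarrelSpec or StackSpec, got {type(geometry)!r}")


def place_particles(
    geometry,
    n: int,
    orientation: str,
    config: SimConfig,
    sites: Sequence[PixelSite] | None = None,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Place ``n`` particles uniformly at random in the field without
    overlap and transform their docking sites to the world frame.

    Upright particles have the barrel axis parallel to optical z and
    rest with their base on the coverslip (z = 0); sideways particles
    lie with the axis in the xy plane at a random in-plane direction,
    resting on the surface.  Every particle gets a random azimuth about
    its own axis.  Site occupancy is drawn per site as
    Bernoulli(labeling_p).  Per-round drift traces and misregistration
    transforms are drawn here so a ground truth fully determines the
    experiment.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if orientation not in ("upright", "sideways"):
        raise ValueError("orientation must be 'upright' or 'sideways'")
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    if sites is None:
        sites, ext_d, height = _geometry_sites(geometry, config)
        geometry_name = getattr(geometry, "name", "stack")
    else:
        _, ext_d, height = _geometry_sites(geometry, config)
        geometry_name = getattr(geometry, "name", "stack")
    site_xyz = np.asarray([s.position for s in sites], dtype=float).reshape(-1, 3)
    site_ids = [s.docking_id or config.rounds[0] for s in sites]

    footprint = max(ext_d, height if orientation == "sideways" else ext_d)
    min_sep = 2.0 * ext_d if orientation == "upright" else footprint + ext_d
    margin = footprint / 2.0 + 1.0
    fx, fy = config.field_size
    if fx <= 2 * margin or fy <= 2 * margin:
        raise SimulationError("field too small for particle footprint")
    # crude capacity check before rejection sampling
    if n * min_sep**2 > 2.0 * (fx - 2 * margin) * (fy - 2 * margin):
        raise SimulationError(f"field too small to place {n} particles at separation {min_sep:.0f} nm")

    centers = np.empty((0, 2))
    attempts = 0
    while len(centers) < n:
        attempts += 1
        if attempts > 200 * n:
            raise SimulationError(f"could not place {n} non-overlapping particles")
        cand = rng.uniform([margin, margin], [fx - margin, fy - margin])
        if len(centers) and np.min(np.linalg.norm(centers - cand, axis=1)) < min_sep:
            continue
        centers = np.vstack([centers, cand])

    pose_rows = []
    site_rows = []
    for p in range(n):
        azimuth = rng.uniform(0.0, 2.0 * math.pi)
        axis_azimuth = rng.uniform(0.0, 2.0 * math.pi) if orientation == "sideways" else 0.0
        if orientation == "upright":
            R = _rot_z(azimuth)
            cz = height / 2.0  # base on the coverslip
        else:
            R = _rot_z(axis_azimuth) @ _rot_y(math.pi / 2.0) @ _rot_z(azimuth)
            cz = ext_d / 2.0  # cylinder resting on the surface
        center = np.array([centers[p, 0], centers[p, 1], cz])
        world = site_xyz @ R.T + center
        occ = rng.random(len(world)) < config.labeling_p
        pose_rows.append(
            dict(particle=p, x=center[0], y=center[1], z=center[2],
                 orientation=orientation, azimuth=azimuth, axis_azimuth=axis_azimuth)
        )
        for j, (w, o) in enumerate(zip(world, occ)):
            site_rows.append(
                dict(particle=p, site=j, x=w[0], y=w[1], z=w[2],
                     docking_id=site_ids[j], occupied=bool(o))
            )

    drift = {}
    offsets = {}
    for i, r in enumerate(config.rounds):
        steps = rng.normal(0.0, config.drift_step, size=(config.n_frames, 3))
        steps[0] = 0.0
        drift[r] = np.cumsum(steps, axis=0)
        if i == 0:
            offsets[r] = (0.0, 0.0, 0.0, 0.0)
        else:
            d = rng.uniform(-config.round_offset_range, config.round_offset_range, size=3)
            theta = math.radians(
                rng.uniform(-config.round_rotation_range_deg, config.round_rotation_range_deg)
            )
            offsets[r] = (float(d[0]), float(d[1]), float(d[2]), theta)

    markers = None
    if config.n_markers > 0:
        mrows = []
        for m in range(config.n_markers):
            c = rng.uniform([margin, margin], [fx - margin, fy - margin])
            local = rng.normal(0.0, config.marker_site_spread, size=(config.marker_n_sites, 3))
            for j, d3 in enumerate(local):
                mrows.append(dict(marker=m, site=j, x=c[0] + d3[0], y=c[1] + d3[1],
                                  z=50.0 + d3[2]))
        markers = pd.DataFrame(mrows)

    return GroundTruth(
        poses=pd.DataFrame(pose_rows),
        sites=pd.DataFrame(site_rows),
        config=config,
        geometry_name=geometry_name,
        drift=drift,
        round_offsets=offsets,
        markers=markers,
    )


def _emit_site(rng: np.random.Generator, n_frames: int, rate: float, mean_bright: float) -> np.ndarray:
    """Frames (sorted, possibly repeated across events) in which one
    site is bright.  Events arrive as a Poisson process; durations are
    geometric with the given mean and truncate at the movie end."""
    n_events = rng.poisson(n_frames * rate)
    if n_events == 0:
        return np.empty(0, dtype=np.int64)
    starts = rng.integers(0, n_frames, size=n_events)
    durations = rng.geometric(1.0 / max(mean_bright, 1.0), size=n_events)
    frames = [np.arange(s, min(s + d, n_frames)) for s, d in zip(starts, durations)]
    return np.sort(np.concatenate(frames))


def _localize(
    rng: np.random.Generator,
    positions: np.ndarray,
    frames: np.ndarray,
    config: SimConfig,
    drift: np.ndarray,
    offset: tuple[float, float, float, float],
    round_id: str,
) -> pd.DataFrame:
    n = len(frames)
    err = np.empty((n, 3))
    err[:, :2] = rng.normal(0.0, config.sigma_xy, size=(n, 2))
    err[:, 2] = rng.normal(0.0, config.sigma_z, size=n)
    pos = positions + err
    dx, dy, dz, theta = offset
    if theta != 0.0:
        cx, cy = config.field_size[0] / 2.0, config.field_size[1] / 2.0
        c, s = math.cos(theta), math.sin(theta)
        x = pos[:, 0] - cx
        y = pos[:, 1] - cy
        pos[:, 0] = cx + c * x - s * y
        pos[:, 1] = cy + s * x + c * y
    pos += np.array([dx, dy, dz])
    pos += drift[frames]
    photons = rng.lognormal(math.log(config.photon_mean), config.photon_sigma, size=n)
    return pd.DataFrame(
        {
            "frame": frames.astype(np.int64),
            "round": round_id,
            "x": pos[:, 0],
            "y": pos[:, 1],
            "z": pos[:, 2],
            "photons": photons,
            "background": rng.poisson(50.0, size=n).astype(float),
            "sx": rng.normal(130.0, 5.0, size=n),
            "sy": rng.normal(130.0, 5.0, size=n),
        }
    )


def simulate_round(
    truth: GroundTruth,
    round_id: str,
    config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> LocalizationTable:
    """Simulate one Exchange-PAINT round.

    Only occupied sites whose docking_id matches the round emit.  Each
    bright frame contributes one localization: the site position plus
    Gaussian localization error, the round's rigid misregistration and
    the cumulative drift at that frame.
    """
    config = config or truth.config
    if round_id not in config.rounds:
        raise ValueError(f"unknown round {round_id!r}; configured rounds: {config.rounds}")
    rng = rng if rng is not None else np.random.default_rng(
        np.random.SeedSequence([config.seed, 1 + config.rounds.index(round_id)])
    )
    sites = truth.occupied_sites(round_id)
    drift = truth.drift.get(round_id, np.zeros((config.n_frames, 3)))
    offset = truth.round_offsets.get(round_id, (0.0, 0.0, 0.0, 0.0))

    chunks = []
    for _, s in sites.iterrows():
        frames = _emit_site(rng, config.n_frames, config.binding_rate, config.mean_bright_time)
        if len(frames) == 0:
            continue
        pos = np.tile([s.x, s.y, s.z], (len(frames), 1))
        chunks.append(_localize(rng, pos, frames, config, drift, offset, round_id))
    if chunks:
        df = pd.concat(chunks, ignore_index=True).sort_values("frame", kind="stable")
        df = df.reset_index(drop=True)
    else:
        df = pd.DataFrame({c: pd.Series(dtype="float64") for c in LOC_COLUMNS})
        df["frame"] = df["frame"].astype(np.int64)
        df["round"] = df["round"].astype(str)
    meta = {
        "round": round_id,
        "field_size": list(config.field_size),
        "n_frames": config.n_frames,
        "seed": config.seed,
        "config_hash": config.hash(),
    }
    return LocalizationTable(df, meta)


def simulate_experiment(
    truth: GroundTruth, config: SimConfig | None = None
) -> dict[str, LocalizationTable]:
    """All configured rounds, plus registration markers if configured."""
    config = config or truth.config
    tables = {r: simulate_round(truth, r, config) for r in config.rounds}
    if config.n_markers > 0:
        tables = add_markers(tables, truth, config)
    return tables


def add_markers(
    tables: Mapping[str, LocalizationTable],
    truth: GroundTruth,
    config: SimConfig | None = None,
) -> dict[str, LocalizationTable]:
    """Append registration-marker localizations to every round.

    Markers sit at fixed world positions, blink at ``marker_rate_factor``
    times the per-site binding rate, and experience the same drift and
    round misregistration as the barrel particles, which is what makes
    them usable for inter-round alignment.
    """
    config = config or truth.config
    if truth.markers is None or len(truth.markers) == 0:
        return dict(tables)
    out = {}
    for i, (round_id, table) in enumerate(tables.items()):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1000 + i]))
        drift = truth.drift.get(round_id, np.zeros((config.n_frames, 3)))
        offset = truth.round_offsets.get(round_id, (0.0, 0.0, 0.0, 0.0))
        chunks = [table.df]
        for _, m in truth.markers.iterrows():
            frames = _emit_site(
                rng, config.n_frames,
                config.binding_rate * config.marker_rate_factor,
                config.mean_bright_time,
            )
            if len(frames) == 0:
                continue
            pos = np.tile([m.x, m.y, m.z], (len(frames), 1))
            chunks.append(_localize(rng, pos, frames, config, drift, offset, round_id))
        df = pd.concat(chunks, ignore_index=True).sort_values("frame", kind="stable")
        out[round_id] = LocalizationTable(df.reset_index(drop=True), dict(table.metadata))
    return out


def apply_field_z_aberration(
    table: LocalizationTable, radial_coefficient: float, center: tuple[float, float] | None = None
) -> LocalizationTable:
    """Inject a field-dependent z error: z += c * r^2 with r the
    distance from the field centre.

    Emulates the apparent z-height varying with the radial position of
    a particle in the field of view; off by default, used only to test
    robustness of downstream estimators.
    """
    if not np.isfinite(radial_coefficient):
        raise ValueError("radial_coefficient must be finite")
    out = table.copy()
    if center is None:
        fs = table.metadata.get("field_size", [0.0, 0.0])
        center = (fs[0] / 2.0, fs[1] / 2.0)
    r2 = (out.df["x"] - center[0]) ** 2 + (out.df["y"] - center[1]) ** 2
    out.df["z"] = out.df["z"] + radial_coefficient * r2
    return out
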
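"""End-to-end scenario pipelines: simulate -> process -> measure.

Each scenario mirrors one of the characterisation experiments:

* ``monomer_diameter`` — upright monomers with a docking ring, picked
  and pooled by centre-of-mass alignment, radial-histogram diameter.
* ``polymer_spacing`` — sideways alpha/beta polymers with rings on the
  alpha monomers; per-particle axial profiles and frequency-count
  spacing analysis.
* ``trimer_z`` — upright stack with two same-channel rings; axial
  two-component fit for the peak-to-peak distance and z FWHM.
* ``decamer_12round`` — 12-round Exchange-PAINT on a decamer with
  registration markers; drift correction, coarse + fine round
  alignment, composite sum, NeNA precision.
* ``availability`` — field of monomers with Bernoulli site occupancy;
  per-site staple availability.
* ``tem`` — synthetic micrographs measured by circular Hough
  (diameter) and rectangle templates (height).

All scenarios are deterministic under a fixed seed, and every artifact
records the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import geometry, morphometry, process, simulate, tem
from .geometry import docking_ring, external_diameter, get_preset, make_stack
from .io import write_experiment
from .morphometry import MeasurementReport
from .simulate import SimConfig, place_particles, simulate_experiment

__all__ = ["RunConfig", "run_scenario", "SCENARIOS"]


@dataclass(frozen=True)
class RunConfig:
    scenario: str
    preset: str = "30-27"
    seed: int = 0
    n_particles: int = 100
    sim_overrides: Mapping[str, object] = field(default_factory=dict)
    processing: Mapping[str, object] = field(default_factory=dict)
    out_dir: str | None = None

    def hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)  # where artifacts land does not change them
        return hashlib.sha1(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _report_dict(reports: Mapping[str, MeasurementReport], config: RunConfig) -> dict:
    return {
        "scenario": config.scenario,
        "preset": config.preset,
        "seed": config.seed,
        "config_hash": config.hash(),
        "reports": {
            name: dataclasses.asdict(r) for name, r in sorted(reports.items())
        },
    }


def _field_size_for(n: int, min_sep: float, margin: float) -> float:
    side = margin * 2 + math.sqrt(n * min_sep**2 * 2.5)
    return max(side, 800.0)


# ---------------------------------------------------------------------------


def monomer_diameter(config: RunConfig) -> dict:
    """Upright monomers -> pick -> centre-of-mass sum -> radial diameter."""
    spec = get_preset(config.preset)
    ext = external_diameter(spec, rounded=False)
    side = _field_size_for(config.n_particles, 2 * ext, ext)
    sim = SimConfig(
        field_size=(side, side),
        n_frames=1500,
        binding_rate=0.015,
        mean_bright_time=2.0,
        sigma_xy=4.0,
        labeling_p=1.0,
        seed=config.seed,
        **config.sim_overrides,
    )
    truth = place_particles(spec, config.n_particles, "upright", sim)
    tables = simulate_experiment(truth, sim)
    table = tables[sim.rounds[0]]

    pick_radius = float(config.processing.get("pick_radius", ext))
    min_locs = int(config.processing.get("min_locs", 50))
    picks = process.pick_particles(table, pick_radius, min_locs)
    locs = process.extract_pick_locs(table, picks)
    # centre-of-mass sum image
    pooled = np.vstack([l - l.mean(axis=0) for l in locs])
    report = morphometry.radial_diameter(pooled, bin_width=1.0)
    report.method["n_particles"] = len(picks)
    return {"reports": {"diameter": report}, "picks": picks, "pooled": pooled,
            "truth": truth, "table": table}


def polymer_spacing(config: RunConfig) -> dict:
    """Sideways alpha/beta polymers -> axial profiles -> ring spacing."""
    spec = get_preset(config.preset)
    n_monomers = int(config.processing.get("n_monomers", 8))
    stack = make_stack(spec, n_monomers, decorated="alpha")
    repeat = 2.0 * (spec.polymer_monomer_height or spec.monomer_height)
    length = stack.height
    side = _field_size_for(config.n_particles, length + external_diameter(spec), length)
    sim = SimConfig(
        field_size=(side, side),
        n_frames=1200,
        binding_rate=0.015,
        mean_bright_time=2.0,
        sigma_xy=5.0,
        labeling_p=1.0,
        seed=config.seed,
        **config.sim_overrides,
    )
    truth = place_particles(stack, config.n_particles, "sideways", sim)
    tables = simulate_experiment(truth, sim)
    table = tables[sim.rounds[0]]

    # per-particle axial profile along the fitted in-plane axis
    arr = table.xyz
    tree_xy = arr[:, :2]
    peak_lists = []
    for p in range(config.n_particles):
        pose = truth.poses.iloc[p]
        center = np.array([pose.x, pose.y])
        mask = np.linalg.norm(tree_xy - center, axis=1) < 0.75 * length
        locs = arr[mask]
        if len(locs) < 50:
            continue
        xy = locs[:, :2] - locs[:, :2].mean(axis=0)
        _, _, vt = np.linalg.svd(xy, full_matrices=False)
        axis3 = np.array([vt[0, 0], vt[0, 1], 0.0])
        _, _, peaks = morphometry.axial_profile(
            locs - locs.mean(axis=0), axis=axis3, bin_width=2.0,
            prominence=0.25, min_peak_locs=15,
        )
        if len(peaks):
            peak_lists.append(peaks)
    report = morphometry.spacing_frequency(peak_lists, bin_width=2.0)
    report.method["designed_repeat"] = repeat
    return {"reports": {"ring_spacing": report}, "truth": truth, "table": table,
            "peak_lists": peak_lists}


def trimer_z(config: RunConfig) -> dict:
    """Two same-channel rings spaced by the designed axial distance."""
    spec = get_preset(config.preset if config.preset.startswith("90") else "90-23")
    separation = float(config.processing.get("ring_separation", 52.0))
    sigma_z = float(config.processing.get("sigma_z", 17.0 / morphometry.GAUSS_FWHM_FACTOR))
    sim = SimConfig(
        field_size=(800.0, 800.0),
        n_frames=1500,
        binding_rate=0.02,
        mean_bright_time=2.0,
        sigma_xy=4.0,
        sigma_z=sigma_z,
        labeling_p=1.0,
        seed=config.seed,
        **config.sim_overrides,
    )
    sites = docking_ring(spec, z=0.0) + docking_ring(spec, z=separation)
    truth = place_particles(spec, 1, "upright", sim, sites=sites)
    tables = simulate_experiment(truth, sim)
    table = tables[sim.rounds[0]]
    report = morphometry.z_resolution(table.df["z"].to_numpy(), two_component=True)
    return {"reports": {"z_peak_distance": report}, "truth": truth, "table": table}


def availability(config: RunConfig) -> dict:
    """Bernoulli site occupancy -> per-site staple availability."""
    spec = get_preset(config.preset)
    ext = external_diameter(spec, rounded=False)
    p = float(config.processing.get("labeling_p", 0.71))
    side = _field_size_for(config.n_particles, 2 * ext, ext)
    sim = SimConfig(
        field_size=(side, side),
        n_frames=1000,
        binding_rate=0.02,
        mean_bright_time=2.0,
        sigma_xy=4.0,
        labeling_p=p,
        seed=config.seed,
        **config.sim_overrides,
    )
    truth = place_particles(spec, config.n_particles, "upright", sim)
    tables = simulate_experiment(truth, sim)
    table = tables[sim.rounds[0]]

    pick_radius = float(config.processing.get("pick_radius", ext))
    picks = process.pick_particles(table, pick_radius, min_locs=10)
    locs = process.extract_pick_locs(table, picks)
    template = np.array(
        [s.position[:2] for s in docking_ring(spec)], dtype=float
    )
    report = morphometry.labeling_efficiency(
        locs, template, sigma_xy=sim.sigma_xy, min_locs_per_site=10
    )
    report.method["labeling_p"] = p
    report.method["n_picked"] = len(picks)
    return {"reports": {"availability": report}, "truth": truth, "table": table,
            "picks": picks}


def decamer_12round(config: RunConfig) -> dict:
    """12-round Exchange-PAINT on a decorated decamer with markers."""
    spec = get_preset(config.preset if config.preset.startswith("90") else "90-23")
    rounds = tuple(f"R{i + 1}" for i in range(12))
    stack = make_stack(spec, 10, decorated="all", monomer_height=spec.monomer_height)
    sites = []
    base = simulate.stack_sites(stack)
    # distribute decorated rings over the 12 rounds, one pseudocolor per ring
    ring_of = {}
    for s in base:
        ring_of.setdefault((s.row_index,), []).append(s)
    for i, (key, ring) in enumerate(sorted(ring_of.items())):
        rid = rounds[i % len(rounds)]
        sites.extend(dataclasses.replace(s, docking_id=rid) for s in ring)
    sim = SimConfig(
        field_size=(1500.0, 1500.0),
        n_frames=400,
        rounds=rounds,
        binding_rate=0.008,
        mean_bright_time=4.0,
        sigma_xy=4.0,
        sigma_z=7.2,
        labeling_p=0.9,
        drift_step=0.02,
        round_offset_range=10.0,
        n_markers=3,
        seed=config.seed,
        **config.sim_overrides,
    )
    truth = place_particles(stack, int(config.processing.get("n_stacks", 4)), "upright", sim)
    tables = simulate_experiment(truth, sim)

    corrected = {}
    for r, t in tables.items():
        _, corrected[r] = process.rcc_drift_correct(t, segment_frames=100)
    shifts = process.align_rounds_coarse(corrected)
    coarse = process.apply_round_shifts(corrected, shifts)
    marker_picks = {
        r: [p for p in process.pick_particles(coarse[r], 60.0, 50)
            if _near_marker(p, truth)] for r in rounds
    }
    fine = process.align_rounds_fine(coarse, marker_picks)
    aligned = process.apply_round_shifts(coarse, fine)

    reports = {}
    ref = aligned[rounds[0]]
    nena = morphometry.nena_precision(ref)
    reports["nena_sigma"] = nena
    reports["fwhm_xy"] = MeasurementReport(
        quantity="fwhm_xy",
        estimate=morphometry.fwhm_from_sigma(nena.estimate),
        units="nm", dispersion=0.0, n=nena.n,
        method={"from": "nena_sigma"},
    )
    pooled = pd.concat([aligned[r].df for r in rounds], ignore_index=True)
    composite = simulate.LocalizationTable(pooled, {"round": "composite"})
    return {"reports": reports, "tables": aligned, "composite": composite,
            "truth": truth}


def _near_marker(pick: process.Pick, truth, radius: float = 80.0) -> bool:
    if truth.markers is None:
        return False
    centers = truth.markers.groupby("marker")[["x", "y"]].mean().to_numpy()
    return bool(np.min(np.linalg.norm(centers - np.array(pick.center), axis=1)) < radius)


def tem_scenario(config: RunConfig) -> dict:
    """Synthetic TEM: Hough diameter of upright rings and template
    height of sideways rectangles."""
    spec = get_preset(config.preset if config.preset.startswith("90") else "90-23")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    ext = external_diameter(spec, rounded=False)
    mic_up, truth_up = tem.synth_micrograph(
        spec, n=4, orientation="upright", noise=0.03, pixel_size=1.0, rng=rng
    )
    det_up = tem.hough_diameter(mic_up, radius_range=(0.6 * ext / 2, 1.4 * ext / 2))
    h = spec.polymer_monomer_height or spec.monomer_height
    mic_side, truth_side = tem.synth_micrograph(
        spec, n=3, orientation="sideways", flatten_factor=1.0, noise=0.03,
        pixel_size=1.0, height=h, rng=rng,
    )
    det_side = tem.rect_height(mic_side)
    diam = float(np.median([d.diameter for d in det_up])) if det_up else float("nan")
    height_est = float(np.median([d.height for d in det_side])) if det_side else float("nan")
    reports = {
        "tem_diameter": MeasurementReport(
            quantity="diameter", estimate=diam, units="nm", dispersion=0.0,
            n=max(len(det_up), 1), method={"method": "hough", "designed": ext},
        ),
        "tem_height": MeasurementReport(
            quantity="monomer_height", estimate=height_est, units="nm", dispersion=0.0,
            n=max(len(det_side), 1), method={"method": "rect-template", "designed": h},
        ),
    }
    return {"reports": reports, "micrographs": (mic_up, mic_side),
            "detections": (det_up, det_side)}


SCENARIOS = {
    "monomer_diameter": monomer_diameter,
    "polymer_spacing": polymer_spacing,
    "trimer_z": trimer_z,
    "decamer_12round": decamer_12round,
    "availability": availability,
    "tem": tem_scenario,
}


def run_scenario(config: RunConfig) -> dict:
    """Execute a scenario and, if an output directory is configured,
    write the localization tables and a machine-readable summary whose
    bytes depend only on the config (including the seed)."""
    if config.scenario not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {config.scenario!r}; available: {sorted(SCENARIOS)}"
        )
    try:
        result = SCENARIOS[config.scenario](config)
    except Exception as exc:
        raise RuntimeError(
            f"scenario {config.scenario!r} failed (config {config.hash()}): {exc}"
        ) from exc
    summary = _report_dict(result["reports"], config)
    result["summary"] = summary
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=1))
        if "table" in result:
            write_experiment({"R1": result["table"]}, out / "localizations.h5")
        if "tables" in result:
            write_experiment(result["tables"], out / "localizations.h5")
        if "micrographs" in result:
            for i, mic in enumerate(result["micrographs"]):
                tem.write_micrograph(mic, out / f"micrograph_{i}.tif")
    return result
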
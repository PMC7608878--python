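"""Sensing scenarios: sonar trajectories over simulated trees and forests.

Two demonstration set-ups are provided.  In the static scenario a sonar at a
fixed pose sweeps its −3 dB beamwidth, showing how a wider mainlobe admits
more leaves and densifies the impulse response.  In the fly-through scenario
a sonar follows a figure-eight (Gerono lemniscate) around the canopies of a
two-species forest, firing at a fixed number of sampling poses with the
beamwidth drawn uniformly from an interval (30–65° by default, a range
typical of bat biosonar).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .acoustics import EchoSpectrum, FrequencyBand, ImpulseResponse, SonarBeam, echo
from .forest import Forest, SpeciesSpec, build_forest
from .geometry import JitterConfig, Tree, assemble_tree, make_branch_template
from .lsystem import GeometryParams, expand, interpret, canonical_grammar


@dataclass
class Trajectory:
    poses: list[SonarBeam]
    path_kind: str = "explicit"

    def __post_init__(self) -> None:
        if not self.poses:
            raise ValueError("a trajectory needs at least one pose")
        if self.path_kind != "static":
            for a, b in zip(self.poses, self.poses[1:]):
                if np.allclose(a.position, b.position):
                    raise ValueError("consecutive poses of a moving path must be distinct")


def _aimed_beam(position: np.ndarray, aim: np.ndarray, **beam_kwargs) -> SonarBeam:
    return SonarBeam(position=position, boresight=np.asarray(aim, float) - position, **beam_kwargs)


def circular_path(
    center,
    radius: float,
    height: float,
    n_points: int,
    aim=None,
    **beam_kwargs,
) -> Trajectory:
    """Poses equally spaced on a circle, each boresight aimed at ``aim``
    (default: the circle centre)."""
    if n_points < 1 or radius <= 0:
        raise ValueError("need n_points >= 1 and radius > 0")
    center = np.asarray(center, dtype=float)
    aim = center if aim is None else np.asarray(aim, dtype=float)
    poses = []
    for k in range(n_points):
        ang = 2 * math.pi * k / n_points
        pos = center + np.array([radius * math.cos(ang), radius * math.sin(ang), 0.0])
        pos[2] = height
        poses.append(_aimed_beam(pos, aim, **beam_kwargs))
    return Trajectory(poses=poses, path_kind="circular" if n_points > 1 else "static")


def figure_eight_path(
    center,
    lobe: float,
    height: float,
    n_points: int,
    aim_points=None,
    **beam_kwargs,
) -> Trajectory:
    """Poses sampled uniformly in parameter along a Gerono lemniscate
    x = lobe·sin t, y = lobe·sin t·cos t, at a fixed flight height.

    Each boresight aims at the nearest point of ``aim_points`` (e.g. canopy
    centroids); without aim points the sonar looks along the flight direction.
    """
    if n_points < 1:
        raise ValueError("need n_points >= 1")
    cx, cy = np.asarray(center, dtype=float)[:2]
    ts = np.arange(n_points) * 2 * math.pi / n_points
    positions = np.column_stack(
        [
            cx + lobe * np.sin(ts),
            cy + lobe * np.sin(ts) * np.cos(ts),
            np.full(n_points, height),
        ]
    )
    aim_arr = None if aim_points is None else np.atleast_2d(np.asarray(aim_points, float))
    poses = []
    for k, pos in enumerate(positions):
        if aim_arr is not None:
            aim = aim_arr[np.argmin(np.linalg.norm(aim_arr - pos, axis=1))]
        else:
            t2 = ts[k]
            tangent = np.array([math.cos(t2), math.cos(2 * t2), 0.0])
            aim = pos + lobe * tangent
        poses.append(_aimed_beam(pos, aim, **beam_kwargs))
    return Trajectory(poses=poses, path_kind="figure-eight")


# ---------------------------------------------------------------------------
# Tree construction defaults
# ---------------------------------------------------------------------------

DEFAULT_TREE_CONFIG = {
    "iterations": 1,
    "geometry": {},
    "template": {"sub_branches": 3, "curvature": 0.15, "leaf_count": 40, "leaf_size": 0.05},
    "n_templates": 1,
    "leaf_radius_mean": 0.05,
    "leaf_radius_sd": 0.01,
    "keep_mesh": False,
}


def default_tree_builder(label: str, location, tree_config: dict, rng: np.random.Generator) -> Tree:
    """Build one tree: L-system skeleton (first-level branching) plus
    procedural branch templates carrying the leaves."""
    cfg = {**DEFAULT_TREE_CONFIG, **(tree_config or {})}
    grammar = cfg.get("grammar") or canonical_grammar()
    symbols = expand(grammar, cfg["iterations"])
    params = cfg["geometry"]
    if not isinstance(params, GeometryParams):
        params = GeometryParams(**params)
    skeleton = interpret(symbols, params, rng)
    templates = [
        make_branch_template(seed=rng, **cfg["template"]) for _ in range(cfg["n_templates"])
    ]
    return assemble_tree(
        skeleton,
        templates,
        seed=rng,
        jitter=JitterConfig(),
        radius_mean=cfg["leaf_radius_mean"],
        radius_sd=cfg["leaf_radius_sd"],
        species=label,
        location=location,
        keep_mesh=cfg["keep_mesh"],
    )


# ---------------------------------------------------------------------------
# Scenario runner
# ---------------------------------------------------------------------------


@dataclass
class BeamwidthSchedule:
    """Fixed beamwidth, or a uniform draw from [lo, hi] (degrees) per pose."""

    fixed: float | None = None
    interval: tuple[float, float] | None = (30.0, 65.0)

    def __post_init__(self) -> None:
        if self.fixed is None and self.interval is None:
            raise ValueError("either a fixed beamwidth or an interval is required")
        for v in ([self.fixed] if self.fixed is not None else self.interval):
            if not 0.0 < v < 180.0:
                raise ValueError("beamwidths must lie in (0, 180) degrees")

    def draw(self, rng: np.random.Generator) -> float:
        if self.fixed is not None:
            return math.radians(self.fixed)
        return math.radians(float(rng.uniform(*self.interval)))


@dataclass
class PoseResult:
    pose_index: int
    impulse: ImpulseResponse
    spectrum: EchoSpectrum
    beam: SonarBeam
    m: int  # in-mainlobe leaf count

    def manifest(self) -> dict:
        return {
            "pose_index": self.pose_index,
            "m_in_mainlobe": self.m,
            "position": [float(v) for v in self.beam.position],
            "boresight": [float(v) for v in self.beam.boresight],
            "beamwidth_az_deg": math.degrees(self.beam.beamwidth_az),
            "beamwidth_el_deg": math.degrees(self.beam.beamwidth_el),
            "fs": self.impulse.fs,
            "n_samples": len(self.impulse.samples),
        }


@dataclass
class ScenarioConfig:
    """Everything needed for one end-to-end run."""

    species_specs: list[SpeciesSpec] | None = None  # forest scenario
    trees: list[Tree] | None = None  # or an explicit scene
    trajectory: Trajectory | None = None
    band: FrequencyBand = field(default_factory=FrequencyBand)
    beamwidths: BeamwidthSchedule = field(default_factory=BeamwidthSchedule)
    min_spacing: float = 1.0
    master_seed: int = 0


def _pose_rng(master_seed: int, pose_index: int) -> np.random.Generator:
    """Stable per-pose sub-stream: SeedSequence keyed by (master, pose)."""
    return np.random.default_rng(np.random.SeedSequence(entropy=(master_seed, pose_index)))


def run_scenario(config: ScenarioConfig):
    """Build the scene once, then echo at every pose of the trajectory.

    Per-pose beamwidths come from the schedule, drawn from a sub-stream keyed
    by (master seed, pose index), so results are reproducible and independent
    of evaluation order.  Returns (list of PoseResult, manifest dict).
    """
    if config.trajectory is None:
        raise ValueError("a trajectory is required")
    if config.trees is not None:
        trees = config.trees
        forest = None
    elif config.species_specs is not None:
        forest = build_forest(
            config.species_specs, min_spacing=config.min_spacing, seed=config.master_seed
        )
        trees = forest.trees
    else:
        raise ValueError("provide either species_specs or an explicit tree list")

    discs = [d for t in trees for d in t.leaf_discs]
    results: list[PoseResult] = []
    for k, pose in enumerate(config.trajectory.poses):
        rng = _pose_rng(config.master_seed, k)
        bw = config.beamwidths.draw(rng)
        beam = SonarBeam(
            position=pose.position,
            boresight=pose.boresight,
            beamwidth_az=bw,
            beamwidth_el=bw,
            A0=pose.A0,
            up_reference=pose.up_reference,
        )
        try:
            ir, spec = echo(beam, discs, config.band)
        except Exception as exc:
            raise RuntimeError(f"echo synthesis failed at pose {k}") from exc
        results.append(PoseResult(pose_index=k, impulse=ir, spectrum=spec, beam=beam, m=spec.m))

    manifest = {
        "master_seed": config.master_seed,
        "path_kind": config.trajectory.path_kind,
        "n_poses": len(results),
        "n_trees": len(trees),
        "n_leaf_discs": len(discs),
        "band": {
            "f_lo": config.band.f_lo,
            "f_hi": config.band.f_hi,
            "fs": config.band.fs,
            "n_fft": config.band.n_fft,
            "sound_speed": config.band.sound_speed,
            "taper": config.band.taper,
        },
        "species_counts": _species_counts(trees),
        "poses": [r.manifest() for r in results],
    }
    return results, manifest


def _species_counts(trees) -> dict:
    counts: dict[str, int] = {}
    for t in trees:
        counts[t.species] = counts.get(t.species, 0) + 1
    return counts


def write_outputs(results, manifest: dict, out_dir, write_wav: bool = True) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for r in results:
        stem = out / f"pose_{r.pose_index:03d}"
        if write_wav:
            r.impulse.to_wav(stem.with_suffix(".wav"))
        r.impulse.to_csv(stem.with_suffix(".csv"))
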
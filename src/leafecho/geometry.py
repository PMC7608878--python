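"""Triangular meshes, branch templates, and leaf-disc extraction.

Trees carry their geometry as triangle meshes (STL in/out via :mod:`trimesh`).
For echo synthesis each leaf is reduced to a circular disc: centre at the
centroid of its triangular facet, normal equal to the facet normal, radius
drawn from a truncated normal distribution.

The branch templates attached to an L-system skeleton are procedural —
tapered, optionally curved tubes with sub-branches and triangular leaf facets
— but any user STL can serve as a template instead (leaf facets identified by
an index list or by loading a dedicated leaf mesh).
"""

from __future__ import annotations

import json
import logging
import math
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .lsystem import BranchSkeleton, _perpendicular, _rotate_about

log = logging.getLogger(__name__)


class STLFormatError(ValueError):
    pass


@dataclass
class TriMesh:
    """A triangle mesh: vertices (n,3), faces (m,3) and unit face normals."""

    vertices: np.ndarray
    faces: np.ndarray
    face_normals: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face index out of range")
        if self.face_normals is None or len(self.face_normals) != len(self.faces):
            self.face_normals = self._compute_normals()

    def _compute_normals(self) -> np.ndarray:
        if not len(self.faces):
            return np.zeros((0, 3))
        tri = self.vertices[self.faces]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norms = np.linalg.norm(n, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return n / norms

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def face_areas(self) -> np.ndarray:
        tri = self.vertices[self.faces]
        return 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )

    def drop_degenerate_faces(self, area_tol: float = 0.0) -> np.ndarray:
        """Remove zero-area faces in place; returns the kept-face index map."""
        keep = np.flatnonzero(self.face_areas() > area_tol)
        dropped = self.n_faces - len(keep)
        if dropped:
            log.info("dropped %d degenerate faces", dropped)
        self.faces = self.faces[keep]
        self.face_normals = self.face_normals[keep]
        return keep

    def transformed(self, rotation: np.ndarray, scale: float, translation: np.ndarray) -> "TriMesh":
        """Similarity transform v -> R (s v) + t; normals rotate only."""
        verts = (rotation @ (scale * self.vertices.T)).T + translation
        normals = (rotation @ self.face_normals.T).T
        return TriMesh(verts, self.faces.copy(), normals)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )


def read_stl(path) -> TriMesh:
    """Read an STL file (binary or ASCII); welds duplicate vertices and drops
    degenerate faces, recomputing normals from the geometry."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_stl_layout(path)
    try:
        loaded = trimesh.load(str(path), file_type="stl", process=False)
    except Exception as exc:  # trimesh raises assorted types on truncated input
        raise STLFormatError(f"cannot parse STL file {path}: {exc}") from exc
    if isinstance(loaded, trimesh.Scene):
        # a header-only STL (zero triangles) loads as an empty scene
        if not loaded.geometry:
            log.warning("%s contains no triangles", path)
            return TriMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        loaded = trimesh.util.concatenate(list(loaded.geometry.values()))
    loaded.merge_vertices(digits_vertex=9)
    mesh = TriMesh(np.asarray(loaded.vertices), np.asarray(loaded.faces))
    mesh.drop_degenerate_faces()
    return mesh


def _validate_stl_layout(path: Path) -> None:
    """Reject structurally truncated files (trimesh is lenient about them)."""
    raw = path.read_bytes()
    head = raw[:512].lstrip()
    if head.startswith(b"solid") and (b"facet" in raw or len(raw) < 84):
        if raw.count(b"facet normal") != raw.count(b"endfacet"):
            raise STLFormatError(
                f"{path}: truncated ASCII STL (unterminated facet near byte {len(raw)})"
            )
        return
    if len(raw) < 84:
        raise STLFormatError(f"{path}: binary STL shorter than its 84-byte preamble")
    (count,) = struct.unpack("<I", raw[80:84])
    expected = 84 + 50 * count
    if len(raw) < expected:
        raise STLFormatError(
            f"{path}: binary STL declares {count} triangles "
            f"({expected} bytes) but ends at byte {len(raw)}"
        )


def write_stl(mesh: TriMesh, path, dialect: str = "binary") -> None:
    """Write ``mesh`` as binary (84 + 50·F bytes) or ASCII STL."""
    if dialect not in ("binary", "ascii"):
        raise ValueError(f"unknown STL dialect {dialect!r}")
    tm = mesh.to_trimesh()
    file_type = "stl" if dialect == "binary" else "stl_ascii"
    Path(path).write_bytes(
        tm.export(file_type=file_type).encode()
        if dialect == "ascii"
        else tm.export(file_type="stl")
    )


@dataclass
class BranchTemplate:
    """A reusable branch mesh: surface triangles plus marked leaf facets.

    ``root_point`` / ``root_axis`` define where and in which direction the
    template attaches to a skeleton branch.
    """

    mesh: TriMesh
    leaf_faces: np.ndarray  # indices into mesh.faces
    root_point: np.ndarray
    root_axis: np.ndarray

    def __post_init__(self) -> None:
        self.leaf_faces = np.asarray(self.leaf_faces, dtype=int)
        self.root_point = np.asarray(self.root_point, dtype=float)
        axis = np.asarray(self.root_axis, dtype=float)
        self.root_axis = axis / np.linalg.norm(axis)


@dataclass
class LeafDisc:
    """Circular-disc reflector standing in for one leaf."""

    center: np.ndarray
    radius: float
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        nn = np.linalg.norm(n)
        if nn == 0:
            raise ValueError("disc normal must be nonzero")
        self.normal = n / nn
        if self.radius <= 0:
            raise ValueError("disc radius must be positive")


@dataclass
class Tree:
    """A placed tree: skeleton, leaf discs, and (optionally) its full mesh."""

    species: str
    location: np.ndarray
    skeleton: BranchSkeleton
    leaf_discs: list[LeafDisc]
    mesh: TriMesh | None = None

    def disc_centers(self) -> np.ndarray:
        return np.array([d.center for d in self.leaf_discs]).reshape(-1, 3)

    def canopy_centroid(self) -> np.ndarray:
        if self.leaf_discs:
            return self.disc_centers().mean(axis=0)
        tops = np.array([s.end for s in self.skeleton.segments])
        return tops.mean(axis=0)

    def leaf_discs_to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["cx", "cy", "cz", "radius", "nx", "ny", "nz"])
            for d in self.leaf_discs:
                w.writerow([*d.center, d.radius, *d.normal])

    def metadata(self) -> dict:
        return {
            "species": self.species,
            "location": list(map(float, self.location)),
            "n_segments": len(self.skeleton.segments),
            "n_leaf_discs": len(self.leaf_discs),
        }

    def metadata_to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.metadata(), indent=2))


# ---------------------------------------------------------------------------
# Procedural templates
# ---------------------------------------------------------------------------


def _tube(
    start: np.ndarray,
    direction: np.ndarray,
    length: float,
    radius0: float,
    radius1: float,
    curvature: float,
    n_rings: int = 5,
    n_sides: int = 6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tapered tube along a quadratically bent centreline.

    Returns (vertices, faces, centreline points).  ``curvature`` is the
    sideways deflection of the tip as a fraction of the length.
    """
    direction = direction / np.linalg.norm(direction)
    side = _perpendicular(direction)
    t = np.linspace(0.0, 1.0, n_rings)
    centers = (
        start[None, :]
        + np.outer(t, direction) * length
        + np.outer(t**2, side) * (curvature * length)
    )
    radii = radius0 + (radius1 - radius0) * t
    verts = []
    for k in range(n_rings):
        if k < n_rings - 1:
            axis = centers[k + 1] - centers[k]
        else:
            axis = centers[k] - centers[k - 1]
        axis = axis / np.linalg.norm(axis)
        u = _perpendicular(axis)
        w = np.cross(axis, u)
        for j in range(n_sides):
            ang = 2 * math.pi * j / n_sides
            verts.append(centers[k] + radii[k] * (math.cos(ang) * u + math.sin(ang) * w))
    verts = np.array(verts)
    faces = []
    for k in range(n_rings - 1):
        for j in range(n_sides):
            a = k * n_sides + j
            b = k * n_sides + (j + 1) % n_sides
            c = (k + 1) * n_sides + j
            d = (k + 1) * n_sides + (j + 1) % n_sides
            faces.append([a, b, d])
            faces.append([a, d, c])
    return verts, np.array(faces, dtype=int), centers


def make_branch_template(
    sub_branches: int = 3,
    curvature: float = 0.15,
    leaf_count: int = 30,
    leaf_size: float = 0.05,
    length: float = 1.0,
    radius: float = 0.04,
    seed: int | np.random.Generator = 0,
) -> BranchTemplate:
    """Build a procedural branch template.

    A curved, tapered main tube with ``sub_branches`` smaller side tubes and
    ``leaf_count`` triangular leaf facets (equilateral, side ``2*leaf_size``)
    scattered along the sub-branches.  Deterministic per seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root = np.zeros(3)
    axis = np.array([0.0, 0.0, 1.0])
    verts, faces, centers = _tube(root, axis, length, radius, 0.35 * radius, curvature)
    all_verts = [verts]
    all_faces = [faces]
    offset = len(verts)

    # attachment sites for leaves: along sub-branch centrelines (or the main
    # tube when there are none)
    leaf_sites: list[tuple[np.ndarray, np.ndarray]] = []
    for i in range(sub_branches):
        t = 0.35 + 0.6 * (i + rng.uniform(0.2, 0.8)) / max(sub_branches, 1)
        t = min(t, 0.98)
        base_idx = min(int(t * (len(centers) - 1)), len(centers) - 2)
        base = centers[base_idx]
        az = rng.uniform(0, 2 * math.pi)
        tilt = rng.uniform(math.radians(30), math.radians(70))
        d = _rotate_about(axis, _perpendicular(axis), tilt)
        d = _rotate_about(d, axis, az)
        sub_len = length * rng.uniform(0.3, 0.5)
        sv, sf, sc = _tube(base, d, sub_len, 0.45 * radius, 0.15 * radius, curvature)
        all_verts.append(sv)
        all_faces.append(sf + offset)
        offset += len(sv)
        for c in sc[1:]:
            leaf_sites.append((c, d))
    if not leaf_sites:
        leaf_sites = [(c, axis) for c in centers[1:]]

    leaf_face_idx = []
    if leaf_count == 0:
        log.warning("template generated with no leaves")
    for _ in range(leaf_count):
        site, d = leaf_sites[rng.integers(len(leaf_sites))]
        n = rng.normal(size=3)
        n /= np.linalg.norm(n)
        u = _perpendicular(n)
        w = np.cross(n, u)
        ang = rng.uniform(0, 2 * math.pi, size=3) + np.array([0, 2 * math.pi / 3, 4 * math.pi / 3])
        center = site + 0.5 * leaf_size * (d + rng.normal(scale=0.3, size=3))
        tri = np.array(
            [center + leaf_size * (math.cos(a) * u + math.sin(a) * w) for a in ang[:3]]
        )
        base = offset
        all_verts.append(tri)
        all_faces.append(np.array([[base, base + 1, base + 2]]))
        leaf_face_idx.append(sum(len(f) for f in all_faces) - 1)
        offset += 3

    mesh = TriMesh(np.vstack(all_verts), np.vstack(all_faces))
    return BranchTemplate(
        mesh=mesh,
        leaf_faces=np.array(leaf_face_idx, dtype=int),
        root_point=root,
        root_axis=axis,
    )


# ---------------------------------------------------------------------------
# Leaf discs and tree assembly
# ---------------------------------------------------------------------------


def leaf_discs_from_mesh(
    mesh: TriMesh,
    leaf_faces: np.ndarray,
    radius_mean: float = 0.05,
    radius_sd: float = 0.01,
    seed: int | np.random.Generator = 0,
) -> list[LeafDisc]:
    """One disc per leaf facet: centre at the triangle centroid, normal equal
    to the facet normal, radius ~ Normal(mean, sd) truncated to (0, ∞) by
    redrawing non-positive values."""
    if radius_mean <= 0:
        raise ValueError("radius_mean must be positive")
    if radius_sd < 0:
        raise ValueError("radius_sd must be >= 0")
    leaf_faces = np.asarray(leaf_faces, dtype=int)
    if leaf_faces.size == 0:
        log.warning("no leaf faces; returning no discs")
        return []
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    centers = mesh.face_centroids()[leaf_faces]
    normals = mesh.face_normals[leaf_faces]
    radii = np.full(len(leaf_faces), radius_mean)
    if radius_sd > 0:
        radii = rng.normal(radius_mean, radius_sd, size=len(leaf_faces))
        bad = radii <= 0
        while bad.any():
            radii[bad] = rng.normal(radius_mean, radius_sd, size=bad.sum())
            bad = radii <= 0
    return [LeafDisc(c, float(r), n) for c, r, n in zip(centers, radii, normals)]


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # opposite: rotate pi about any perpendicular
        p = _perpendicular(a)
        return _axis_angle(p, math.pi)
    return _axis_angle(v / np.linalg.norm(v), math.atan2(np.linalg.norm(v), c))


def _axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


@dataclass
class JitterConfig:
    """Randomisation applied when placing templates on a skeleton."""

    angle_sd: float = math.radians(5.0)  # tilt jitter of the branch axis
    scale_range: tuple[float, float] = (0.8, 1.25)  # isotropic, log-uniform
    enabled: bool = True


def assemble_tree(
    skeleton: BranchSkeleton,
    templates: list[BranchTemplate],
    seed: int | np.random.Generator = 0,
    jitter: JitterConfig | None = None,
    radius_mean: float = 0.05,
    radius_sd: float = 0.01,
    species: str = "generic",
    location=(0.0, 0.0),
    keep_mesh: bool = True,
) -> Tree:
    """Attach branch templates to the first-level attachment points of a skeleton.

    With as many templates as attachment points (n = N) the match is
    one-to-one with slight random jitter; otherwise each branch reuses a
    randomly selected template, randomised by rotation, translation and
    isotropic scaling.  Template roots land exactly on their attachment
    points; root axes align with the skeleton branch directions.
    """
    if not templates:
        raise ValueError("at least one branch template is required")
    if jitter is None:
        jitter = JitterConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    attachments = skeleton.first_level_attachments()
    if not attachments:
        # single-segment skeletons: attach at the trunk tip
        trunk = skeleton.segments[0]
        attachments = [(trunk.end.copy(), trunk.direction)]
    N, n = len(attachments), len(templates)
    one_to_one = n == N

    discs: list[LeafDisc] = []
    mesh_parts: list[TriMesh] = []
    for i, (point, direction) in enumerate(attachments):
        tpl = templates[i] if one_to_one else templates[rng.integers(n)]
        axis_target = direction
        scale = 1.0
        if jitter.enabled:
            lo, hi = jitter.scale_range
            if not one_to_one:
                scale = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            if jitter.angle_sd > 0:
                tilt_ax = _perpendicular(direction)
                tilt_ax = _rotate_about(tilt_ax, direction, rng.uniform(0, 2 * math.pi))
                axis_target = _rotate_about(
                    direction, tilt_ax, rng.normal(0.0, jitter.angle_sd)
                )
        R = _rotation_between(tpl.root_axis, axis_target)
        spin = _axis_angle(axis_target, float(rng.uniform(0, 2 * math.pi)))
        R = spin @ R
        t = point - R @ (scale * tpl.root_point)
        placed = tpl.mesh.transformed(R, scale, t)
        mesh_parts.append(placed)
        discs.extend(
            leaf_discs_from_mesh(placed, tpl.leaf_faces, radius_mean, radius_sd, rng)
        )

    mesh = None
    if keep_mesh:
        verts = np.vstack([m.vertices for m in mesh_parts])
        offsets = np.cumsum([0] + [len(m.vertices) for m in mesh_parts[:-1]])
        faces = np.vstack([m.faces + o for m, o in zip(mesh_parts, offsets)])
        mesh = TriMesh(verts, faces)

    loc = np.asarray(location, dtype=float)
    if loc.size == 2:
        shift = np.array([loc[0], loc[1], 0.0])
        for d in discs:
            d.center = d.center + shift
        if mesh is not None:
            mesh.vertices = mesh.vertices + shift
    return Tree(
        species=species, location=loc, skeleton=skeleton, leaf_discs=discs, mesh=mesh
    )
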
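"""Random forests: tree locations from an inhomogeneous Poisson process (IPP).

The spatial intensity λ(s) over a rectangular field D is a mixture of
squared-exponential (Gaussian) kernels,

    λ(s) = Σ_i C_i exp{ −(s_x − cx_i)² / h_i² − (s_y − cy_i)² / l_i² },

with per-component amplitude C_i (trees·m⁻²), centre (cx_i, cy_i) and scales
(h_i, l_i) — note the denominators are h², l² with no factor 2.  The number
of trees is Poisson with mean ∫_D λ, and locations are drawn exactly by
thinning: a homogeneous process at the bound λ_max = Σ C_i is generated and
each point kept with probability λ(s)/λ_max.

Multi-species forests sample each species independently and then enforce a
minimum spacing between trees of *different* species, deleting the offender
from the later-sampled species.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import erf

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Domain:
    """Axis-aligned rectangular field [x0, x1] × [y0, y1] in metres."""

    x0: float
    x1: float
    y0: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError("domain must be nondegenerate")

    @property
    def area(self) -> float:
        return (self.x1 - self.x0) * (self.y1 - self.y0)

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        xy = rng.uniform(size=(n, 2))
        xy[:, 0] = self.x0 + xy[:, 0] * (self.x1 - self.x0)
        xy[:, 1] = self.y0 + xy[:, 1] * (self.y1 - self.y0)
        return xy


@dataclass(frozen=True)
class Component:
    """One squared-exponential kernel: C·exp{−(x−cx)²/h² −(y−cy)²/l²}."""

    C: float
    cx: float
    cy: float
    h: float
    l: float

    def __post_init__(self) -> None:
        if self.C < 0:
            raise ValueError("amplitude C must be >= 0")
        if self.h <= 0 or self.l <= 0:
            raise ValueError("scales h, l must be positive")


@dataclass(frozen=True)
class SquaredExponentialMixture:
    """Mixture-of-Gaussian-kernel intensity over a rectangular domain."""

    components: tuple[Component, ...]
    domain: Domain

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.zeros(len(pts))
        for c in self.components:
            out += c.C * np.exp(
                -((pts[:, 0] - c.cx) ** 2) / c.h**2 - ((pts[:, 1] - c.cy) ** 2) / c.l**2
            )
        return out

    def max_bound(self) -> float:
        """Upper bound of λ on D: the sum of component amplitudes."""
        return float(sum(c.C for c in self.components))

    def integral(self) -> float:
        """∫_D λ(s) ds via the exact separable Gaussian-times-erf form."""
        d = self.domain
        total = 0.0
        for c in self.components:
            ix = (math.sqrt(math.pi) * c.h / 2.0) * (
                erf((d.x1 - c.cx) / c.h) - erf((d.x0 - c.cx) / c.h)
            )
            iy = (math.sqrt(math.pi) * c.l / 2.0) * (
                erf((d.y1 - c.cy) / c.l) - erf((d.y0 - c.cy) / c.l)
            )
            total += c.C * ix * iy
        return total

    def marginal_x_cdf(self, x_grid: np.ndarray) -> np.ndarray:
        """CDF of the normalised x-marginal of λ on D (for distributional checks)."""
        d = self.domain
        x_grid = np.asarray(x_grid, dtype=float)
        vals = np.zeros_like(x_grid)
        for c in self.components:
            iy = (math.sqrt(math.pi) * c.l / 2.0) * (
                erf((d.y1 - c.cy) / c.l) - erf((d.y0 - c.cy) / c.l)
            )
            ix = (math.sqrt(math.pi) * c.h / 2.0) * (
                erf((x_grid - c.cx) / c.h) - erf((d.x0 - c.cx) / c.h)
            )
            vals += c.C * ix * iy
        total = self.integral()
        return vals / total if total > 0 else vals


@dataclass(frozen=True)
class UniformIntensity:
    """Homogeneous intensity λ ≡ rate on a rectangular domain."""

    rate: float
    domain: Domain

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be >= 0")

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.full(len(pts), self.rate)

    def max_bound(self) -> float:
        return self.rate

    def integral(self) -> float:
        return self.rate * self.domain.area


#: either intensity flavour; both expose __call__, max_bound, integral, domain
IntensityMixture = SquaredExponentialMixture


def intensity(mixture, s) -> float | np.ndarray:
    """Evaluate λ at one point (scalar) or an (n,2) array of points."""
    vals = mixture(s)
    return float(vals[0]) if np.asarray(s).ndim == 1 else vals


def intensity_integral(mixture) -> float:
    """Mean of the Poisson count on D: ∫_D λ(s) ds."""
    return mixture.integral()


def sample_locations(mixture, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw one exact IPP realisation by thinning.

    N ~ Poisson(λ_max·|D|) candidate points are placed uniformly on D and each
    is retained independently with probability λ(s)/λ_max.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam_max = mixture.max_bound()
    if lam_max == 0:
        return np.zeros((0, 2))
    n = rng.poisson(lam_max * mixture.domain.area)
    pts = mixture.domain.sample_uniform(n, rng)
    keep = rng.uniform(size=n) < mixture(pts) / lam_max
    return pts[keep]


@dataclass
class SpeciesSpec:
    """A species: its label, intensity, and how to build each tree."""

    label: str
    mixture: object  # SquaredExponentialMixture or UniformIntensity
    tree_config: dict = field(default_factory=dict)


@dataclass
class Forest:
    trees: list
    locations: np.ndarray
    species_map: list[str]
    seed: int

    def __len__(self) -> int:
        return len(self.species_map)

    def locations_to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["x", "y", "species", "seed"])
            for (x, y), sp in zip(self.locations, self.species_map):
                w.writerow([x, y, sp, self.seed])


def merge_species_locations(
    per_species: list[np.ndarray], min_spacing: float
) -> list[np.ndarray]:
    """Pool species, deleting any tree of a *later* species that lies within
    ``min_spacing`` of a surviving earlier-species tree.  Same-species pairs
    are never deleted."""
    kept: list[np.ndarray] = []
    accepted: list[np.ndarray] = []  # all surviving points from earlier species
    n_deleted = 0
    for locs in per_species:
        if accepted and len(locs):
            tree = cKDTree(np.vstack(accepted))
            dist, _ = tree.query(locs, k=1)
            ok = dist >= min_spacing
            n_deleted += int((~ok).sum())
            locs = locs[ok]
        kept.append(locs)
        if len(locs):
            accepted.append(locs)
    if n_deleted:
        log.info("merging removed %d trees closer than %.2f m to another species", n_deleted, min_spacing)
    return kept


def build_forest(
    species_specs: list[SpeciesSpec],
    min_spacing: float = 1.0,
    seed: int = 0,
    tree_builder=None,
) -> Forest:
    """Sample every species independently, merge with the cross-species
    spacing restriction, and instantiate a tree at each surviving location.

    ``tree_builder(label, location, tree_config, rng)`` constructs a single
    tree; the default builds an L-system skeleton with procedural templates
    (see :func:`leafecho.scenario.default_tree_builder`).
    """
    if not species_specs:
        raise ValueError("at least one species is required")
    if tree_builder is None:
        from .scenario import default_tree_builder

        tree_builder = default_tree_builder
    root_seq = np.random.SeedSequence(seed)
    sample_seqs = root_seq.spawn(len(species_specs) + 1)
    per_species = [
        sample_locations(spec.mixture, np.random.default_rng(sq))
        for spec, sq in zip(species_specs, sample_seqs)
    ]
    per_species = merge_species_locations(per_species, min_spacing)

    trees, species_map = [], []
    all_locs = []
    tree_rng = np.random.default_rng(sample_seqs[-1])
    for spec, locs in zip(species_specs, per_species):
        for loc in locs:
            trees.append(tree_builder(spec.label, loc, spec.tree_config, tree_rng))
            species_map.append(spec.label)
            all_locs.append(loc)
    locations = np.array(all_locs).reshape(-1, 2)
    return Forest(trees=trees, locations=locations, species_map=species_map, seed=seed)
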
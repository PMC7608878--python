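"""Lindenmayer-system grammars and their turtle interpretation as branch skeletons.

The branching pattern of a tree is described by a parallel string-rewriting
grammar: a set of variables, an axiom string, and production rules mapping
variables to replacement strings.  Four special symbols drive the geometric
interpretation: ``(`` opens a child branch, ``)`` marks a branch end, ``+``
opens a branch mirrored in azimuth against the previous branch, and ``[``
raises the attachment point along the trunk before opening a branch.

A subtlety of the notation: an end-branch variable is written together with
its trailing end marker (``g)``), and rewriting consumes the marker — the
production replaces the two-character token as a whole.  Tokenisation below
implements exactly that, so expansions of the canonical rule
``g -> d(g)[g)+g)`` read, e.g.::

    iteration 1: d(g)[g)+g)
    iteration 2: d(d(g)[g)+g)[d(g)[g)+g)+d(g)[g)+g)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

SPECIALS = frozenset("()+[")

#: golden angle in radians, used to stagger branch azimuths
GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


class GrammarError(ValueError):
    """Raised for malformed grammars or symbol strings."""


@dataclass(frozen=True)
class Token:
    """One parsed symbol: a variable (optionally with its end marker) or a special."""

    symbol: str
    end: bool = False  # True when a variable carries a trailing ")"

    def render(self) -> str:
        return self.symbol + (")" if self.end else "")


@dataclass(frozen=True)
class Grammar:
    """An L-system: variables, axiom and production rules over Σ = variables ∪ specials."""

    variables: frozenset[str]
    axiom: str
    productions: dict[str, str]

    def __post_init__(self) -> None:
        if not self.axiom:
            raise GrammarError("axiom must be nonempty")
        for v in self.variables:
            if len(v) != 1:
                raise GrammarError(f"variables must be single characters, got {v!r}")
            if v in SPECIALS:
                raise GrammarError(f"variable {v!r} collides with a special symbol")
        for key, out in self.productions.items():
            if key not in self.variables:
                raise GrammarError(f"production key {key!r} is not a variable")
            tokenize(out, self.variables)  # validates symbols
        tokenize(self.axiom, self.variables)


def tokenize(symbols: str, variables: frozenset[str] | set[str]) -> list[Token]:
    """Parse a symbol string into tokens; a variable immediately followed by ``)``
    absorbs it as an end marker."""
    tokens: list[Token] = []
    i = 0
    n = len(symbols)
    while i < n:
        c = symbols[i]
        if c in variables:
            if i + 1 < n and symbols[i + 1] == ")":
                tokens.append(Token(c, end=True))
                i += 2
            else:
                tokens.append(Token(c))
                i += 1
        elif c in SPECIALS:
            tokens.append(Token(c))
            i += 1
        else:
            raise GrammarError(f"unknown symbol {c!r} at position {i}")
    return tokens


def expand(grammar: Grammar, iterations: int) -> str:
    """Apply all productions simultaneously ``iterations`` times to the axiom.

    Rewriting a variable consumes its end marker (the production's own output
    carries the markers), so printed strings match the conventional notation.
    Variables without a production and all specials are copied unchanged.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    prod_tokens = {
        k: tokenize(out, grammar.variables) for k, out in grammar.productions.items()
    }
    tokens = tokenize(grammar.axiom, grammar.variables)
    for _ in range(iterations):
        nxt: list[Token] = []
        for tok in tokens:
            if tok.symbol in prod_tokens:
                nxt.extend(prod_tokens[tok.symbol])
            else:
                nxt.append(tok)
        tokens = nxt
    return "".join(t.render() for t in tokens)


# ---------------------------------------------------------------------------
# Geometric interpretation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeometryParams:
    """Parameters of the turtle interpretation.

    Lengths are in metres, angles in radians.  Child branches contract the
    parent's length and radius by ``length_ratio`` / ``radius_ratio``, each
    perturbed by zero-mean Gaussian noise (sd ``ratio_noise_sd``, truncated so
    the perturbed ratio stays in (0, 1)); the branch tilt angle is perturbed
    with sd ``angle_noise_sd``.  ``raise_fraction_range`` bounds the uniform
    draw that lifts the attachment point of ``+`` and ``[`` branches along the
    parent.  Azimuths of successive branches follow the golden-angle sequence
    or are drawn uniformly at random.
    """

    initial_length: float = 2.0
    initial_radius: float = 0.15
    length_ratio: float = 0.7
    radius_ratio: float = 0.6
    branch_angle: float = math.radians(35.0)
    ratio_noise_sd: float = 0.05
    angle_noise_sd: float = math.radians(5.0)
    raise_fraction_range: tuple[float, float] = (0.2, 0.5)
    azimuth_rule: str = "golden-angle"  # or "uniform-random"

    def __post_init__(self) -> None:
        if self.initial_length <= 0 or self.initial_radius <= 0:
            raise ValueError("lengths must be positive")
        if not (0 < self.length_ratio < 1 and 0 < self.radius_ratio < 1):
            raise ValueError("contraction ratios must lie in (0, 1)")
        if self.ratio_noise_sd < 0 or self.angle_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        lo, hi = self.raise_fraction_range
        if not (0 < lo <= hi < 1):
            raise ValueError("raise_fraction_range must be an interval within (0, 1)")
        if self.azimuth_rule not in ("golden-angle", "uniform-random"):
            raise ValueError(f"unknown azimuth_rule {self.azimuth_rule!r}")


@dataclass
class BranchSegment:
    """A straight, tapered branch piece between two points."""

    start: np.ndarray
    end: np.ndarray
    radius_start: float
    radius_end: float
    depth: int
    kind: str  # "d" trunk/branch, "g" end branch
    heading: np.ndarray | None = None  # growth direction; kept exact even for
    # segments so short that end − start loses precision

    @property
    def direction(self) -> np.ndarray:
        if self.heading is not None:
            return self.heading
        d = self.end - self.start
        return d / np.linalg.norm(d)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))


@dataclass
class BranchSkeleton:
    """An ordered collection of connected branch segments rooted at ``root``."""

    segments: list[BranchSegment] = field(default_factory=list)
    root: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def first_level_attachments(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(point, direction) pairs where depth-1 branches leave the trunk."""
        return [
            (seg.start.copy(), seg.direction) for seg in self.segments if seg.depth == 1
        ]

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                ["x0", "y0", "z0", "x1", "y1", "z1", "radius_start", "radius_end", "depth", "kind"]
            )
            for s in self.segments:
                w.writerow([*s.start, *s.end, s.radius_start, s.radius_end, s.depth, s.kind])


@dataclass
class _TurtleState:
    position: np.ndarray
    heading: np.ndarray
    length: float
    radius: float
    depth: int
    parent: BranchSegment | None
    branch_count: int = 0  # branches opened at this node, drives the azimuth sequence
    last_azimuth: float = 0.0
    last_tilt: float = 0.0


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis."""
    c, s = math.cos(angle), math.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1 - c)


def _perpendicular(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = np.cross(v, ref)
    return p / np.linalg.norm(p)


def _branch_heading(parent_dir: np.ndarray, tilt: float, azimuth: float) -> np.ndarray:
    """Rotate the parent direction by ``tilt`` towards a perpendicular chosen by ``azimuth``."""
    perp0 = _perpendicular(parent_dir)
    perp = _rotate_about(perp0, parent_dir, azimuth)
    h = _rotate_about(parent_dir, np.cross(parent_dir, perp) / np.linalg.norm(np.cross(parent_dir, perp)), -tilt)
    return h / np.linalg.norm(h)


def interpret(
    symbols: str,
    params: GeometryParams | None = None,
    seed: int | np.random.Generator = 0,
) -> BranchSkeleton:
    """Turtle-interpret a symbol string as a 3-D branch skeleton.

    Each ``d``/``g`` token draws one segment.  ``(``, ``[`` and ``+`` push the
    turtle state and open a contracted child branch (``[`` first advances the
    attachment point up the parent, ``+`` mirrors the previous branch's azimuth
    and raises the attachment by a random height); a branch-end marker pops.
    Deterministic for a fixed seed; with all noise off and the golden-angle
    azimuth rule the result is seed-independent.
    """
    if params is None:
        params = GeometryParams()
    if not symbols:
        raise GrammarError("empty symbol string")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    variables = {c for c in symbols if c not in SPECIALS}
    tokens = tokenize(symbols, variables)

    skeleton = BranchSkeleton(root=np.zeros(3))
    state = _TurtleState(
        position=np.zeros(3),
        heading=np.array([0.0, 0.0, 1.0]),
        length=params.initial_length,
        radius=params.initial_radius,
        depth=0,
        parent=None,
    )
    stack: list[_TurtleState] = []

    def noisy_ratio(ratio: float) -> float:
        if params.ratio_noise_sd == 0:
            return ratio
        for _ in range(100):  # redraw until inside (0, 1)
            r = ratio + rng.normal(0.0, params.ratio_noise_sd)
            if 0.0 < r < 1.0:
                return r
        return ratio

    def next_azimuth(st: _TurtleState) -> float:
        if params.azimuth_rule == "uniform-random":
            return float(rng.uniform(0.0, 2.0 * math.pi))
        return (st.branch_count * GOLDEN_ANGLE) % (2.0 * math.pi)

    def open_branch(st: _TurtleState, azimuth: float, attach: np.ndarray) -> _TurtleState:
        tilt = params.branch_angle
        if params.angle_noise_sd > 0:
            tilt += rng.normal(0.0, params.angle_noise_sd)
        heading = _branch_heading(st.heading, tilt, azimuth)
        child = _TurtleState(
            position=attach,
            heading=heading,
            length=st.length * noisy_ratio(params.length_ratio),
            radius=st.radius * noisy_ratio(params.radius_ratio),
            depth=st.depth + 1,
            parent=st.parent,
        )
        st.branch_count += 1
        st.last_azimuth = azimuth
        st.last_tilt = tilt
        return child

    def raised_attachment(st: _TurtleState) -> np.ndarray:
        """Attachment advanced up the parent; the parent segment is extended
        in place when the point would pass its current endpoint (the trunk
        'grows' as branches stack up), keeping the skeleton connected."""
        lo, hi = params.raise_fraction_range
        u = float(rng.uniform(lo, hi))
        parent = st.parent
        if parent is None:
            return st.position.copy()
        step = u * parent.length
        attach = st.position + parent.direction * step
        along = float(np.dot(attach - parent.start, parent.direction))
        if along > parent.length:
            parent.end = parent.start + parent.direction * along
        return attach

    for tok in tokens:
        if tok.symbol == "(":
            stack.append(state)
            state = open_branch(state, next_azimuth(state), state.position.copy())
        elif tok.symbol == "[":
            stack.append(state)
            attach = raised_attachment(state)
            new = open_branch(state, next_azimuth(state), attach)
            state = new
        elif tok.symbol == "+":
            stack.append(state)
            mirror = (state.last_azimuth + math.pi) % (2.0 * math.pi)
            attach = raised_attachment(state)
            state = open_branch(state, mirror, attach)
        elif tok.symbol == ")":
            if not stack:
                raise GrammarError("branch end marker with no open branch")
            state = stack.pop()
        else:  # a variable: draw one segment
            end = state.position + state.heading * state.length
            taper = params.radius_ratio if tok.symbol != "g" else 0.5 * params.radius_ratio
            seg = BranchSegment(
                start=state.position.copy(),
                end=end,
                radius_start=state.radius,
                radius_end=state.radius * taper,
                depth=state.depth,
                kind="g" if tok.end or tok.symbol == "g" else "d",
                heading=state.heading.copy(),
            )
            skeleton.segments.append(seg)
            state.position = end.copy()
            state.parent = seg
            if tok.end:
                if not stack:
                    raise GrammarError("branch end marker with no open branch")
                state = stack.pop()

    return skeleton


def canonical_grammar() -> Grammar:
    """The canonical two-variable grammar ``g -> d(g)[g)+g)`` with axiom ``g``."""
    return Grammar(
        variables=frozenset({"g", "d"}),
        axiom="g",
        productions={"g": "d(g)[g)+g)"},
    )
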
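"""Self-excluding random walk for super-CG system building.

Each molecule is represented one bead per residue.  Beads interact through
a Lennard-Jones potential (epsilon fixed at 1 kJ/mol, sigma from residue
size) and a trial placement is rejected when any pair force exceeds
``f_max``, when a geometric or dimension predicate fails, or when a
distance-restraint bound is violated.  Growth follows a breadth-first
traversal of the molecular graph so that graph-adjacent residues are
placed spatially close, which also handles branched molecules.  When a bead
cannot be placed within ``max_attempts`` tries, the walk backtracks by
removing the last ``backtrack`` placed beads (default ten) and regrowing.

Chain stiffness is imposed by sampling an end-to-end distance from the
worm-like-chain distribution for a requested persistence length and
enforcing it through the distance-restraint machinery: while growing
towards a restrained node, each step must keep the bead within
``target +/- (g * step + tol)`` of the anchor, where ``g`` is the number of
graph edges still to walk; the bounds tighten to the bare tolerance at the
restrained node itself.

All distances honor rectangular periodic boundary conditions via the
minimum-image convention; neighbor searches use scipy's periodic cKDTree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .errors import BuildError, InputError

EPSILON = 1.0  # kJ/mol, fixed well depth of the super-CG model
CUTOFF_FACTOR = 2.5  # force cutoff at 2.5 sigma


# ---------------------------------------------------------------------------
# build specification
# ---------------------------------------------------------------------------

@dataclass
class GeomConstraint:
    """Sphere / rectangle / cylinder region, inside or outside."""

    kind: str            # sphere | rectangle | cylinder
    inside: bool
    params: tuple        # sphere: cx cy cz r; rectangle: x0 x1 y0 y1 z0 z1
                         # cylinder (z-axis): cx cy r z0 z1

    def allows(self, point):
        p = np.asarray(point)
        if self.kind == "sphere":
            cx, cy, cz, r = self.params
            hit = np.sum((p - (cx, cy, cz)) ** 2) <= r * r
        elif self.kind == "rectangle":
            x0, x1, y0, y1, z0, z1 = self.params
            hit = (x0 <= p[0] <= x1) and (y0 <= p[1] <= y1) \
                and (z0 <= p[2] <= z1)
        elif self.kind == "cylinder":
            cx, cy, r, z0, z1 = self.params
            hit = ((p[0] - cx) ** 2 + (p[1] - cy) ** 2 <= r * r) \
                and (z0 <= p[2] <= z1)
        else:
            raise InputError(f"unknown constraint kind {self.kind!r}")
        return hit if self.inside else not hit


@dataclass
class AxisSlab:
    """Dimension constraint: one coordinate confined to [lo, hi]."""

    axis: int
    lo: float
    hi: float

    def allows(self, point):
        return self.lo <= point[self.axis] <= self.hi


@dataclass
class DistanceRestraint:
    u: int
    v: int
    target: float
    tol: float = 0.1


@dataclass
class PersistenceSpec:
    lp: float            # persistence length, nm
    start: int           # first node of the restrained span
    stop: int            # last node of the restrained span
    tol: float = None    # defaults to a quarter step length
    model: str = "WLC"


@dataclass
class BuildEntry:
    """Build options attached to a molecule name and instance range."""

    molname: str
    first: int = 0
    last: int = None     # exclusive; None = all instances
    geometry: list = field(default_factory=list)
    dimension: list = field(default_factory=list)
    restraints: list = field(default_factory=list)
    persistence: list = field(default_factory=list)
    start: np.ndarray = None
    step_length: float = None

    def covers(self, idx):
        return idx >= self.first and (self.last is None or idx < self.last)


@dataclass
class MoleculeOptions:
    geometry: list = field(default_factory=list)
    dimension: list = field(default_factory=list)
    restraints: list = field(default_factory=list)
    persistence: list = field(default_factory=list)
    start: np.ndarray = None
    step_length: float = None


@dataclass
class BuildSpec:
    """Everything steering a build: box, grid, rejection and backtracking
    parameters, plus per-molecule constraint entries."""

    box: np.ndarray = None
    grid_spacing: float = None
    fmax: float = 5.0e4          # kJ/(mol nm)
    step_factor: float = 0.8     # default bonded step = 0.8 * sigma_ij
    backtrack: int = 10
    max_attempts: int = 100
    max_restarts: int = 50
    entries: list = field(default_factory=list)

    def validate(self):
        if self.box is not None and (len(self.box) != 3
                                     or np.any(np.asarray(self.box) <= 0)):
            raise InputError("box must be three positive lengths")
        if self.backtrack < 1:
            raise InputError("backtrack depth must be >= 1")
        for entry in self.entries:
            for r in entry.restraints:
                if r.target < 0 or r.tol < 0:
                    raise InputError("restraint target/tol must be >= 0")
            for p in entry.persistence:
                if p.lp <= 0:
                    raise InputError("persistence length must be positive")

    def options_for(self, molname, idx):
        opts = MoleculeOptions()
        for entry in self.entries:
            if entry.molname == molname and entry.covers(idx):
                opts.geometry += entry.geometry
                opts.dimension += entry.dimension
                opts.restraints += entry.restraints
                opts.persistence += entry.persistence
                if entry.start is not None:
                    opts.start = np.asarray(entry.start, dtype=float)
                if entry.step_length is not None:
                    opts.step_length = entry.step_length
        return opts


# ---------------------------------------------------------------------------
# periodic geometry and forces
# ---------------------------------------------------------------------------

def minimum_image(p, q, box):
    """Minimum-image displacement p - q under a rectangular box."""
    box = np.asarray(box, dtype=float)
    disp = np.asarray(p, dtype=float) - np.asarray(q, dtype=float)
    return disp - box * np.round(disp / box)


def lj_force(r, sigma, eps=EPSILON):
    """Radial LJ force magnitude F(r) = 24 eps [2 (s/r)^12 - (s/r)^6] / r,
    zero beyond the 2.5 sigma cutoff; positive = repulsive."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise InputError("lj_force: r must be positive (overlap)")
    sr6 = (sigma / r) ** 6
    force = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r
    return np.where(r > CUTOFF_FACTOR * sigma, 0.0, force)


def _max_pair_force(candidate, positions, rho_other, rho_c, box):
    """Largest (signed, repulsive-positive) pair force on a candidate bead;
    +inf on exact overlap."""
    if len(positions) == 0:
        return 0.0
    disp = positions - candidate
    disp -= box * np.round(disp / box)
    r = np.sqrt(np.sum(disp * disp, axis=1))
    sigma = rho_other + rho_c
    near = r < CUTOFF_FACTOR * sigma
    if not np.any(near):
        return 0.0
    r = r[near]
    if np.any(r == 0.0):
        return np.inf
    sr6 = (sigma[near] / r) ** 6
    return float(np.max(24.0 * EPSILON * (2.0 * sr6 * sr6 - sr6) / r))


class ExclusionField:
    """Placed beads of *finished* molecules (and frozen coordinates),
    queried through a periodic KD-tree."""

    def __init__(self, box):
        self.box = np.asarray(box, dtype=float)
        self.positions = np.empty((0, 3))
        self.rho = np.empty(0)
        self._tree = None

    def add(self, positions, rho):
        if len(positions) == 0:
            return
        pos = np.mod(np.asarray(positions, dtype=float), self.box)
        self.positions = np.vstack([self.positions, pos])
        self.rho = np.concatenate([self.rho, np.asarray(rho, dtype=float)])
        self._tree = None

    @property
    def rho_max(self):
        return float(self.rho.max()) if len(self.rho) else 0.0

    def max_force(self, candidate, rho_c):
        if len(self.positions) == 0:
            return 0.0
        if self._tree is None:
            # boxsize requires points strictly inside [0, box)
            self._tree = cKDTree(
                np.clip(self.positions, 0.0,
                        np.nextafter(self.box, 0.0)),
                boxsize=self.box,
            )
        cutoff = CUTOFF_FACTOR * (rho_c + self.rho_max)
        cand = np.mod(np.asarray(candidate, dtype=float), self.box)
        idx = self._tree.query_ball_point(cand, cutoff)
        if not idx:
            return 0.0
        return _max_pair_force(cand, self.positions[idx], self.rho[idx],
                               rho_c, self.box)


# ---------------------------------------------------------------------------
# worm-like-chain end-to-end sampler
# ---------------------------------------------------------------------------

def wlc_mean_square_ee(L, lp):
    """Closed-form WLC mean-square end-to-end distance
    <R^2> = 2 l_p L - 2 l_p^2 (1 - exp(-L / l_p))."""
    if L <= 0 or lp <= 0:
        raise InputError("contour and persistence lengths must be positive")
    return 2.0 * lp * L - 2.0 * lp ** 2 * (1.0 - np.exp(-L / lp))


def _frc_mean_square_ee(n, b, g):
    """Freely-rotating-chain <R^2> = b^2 [n + 2 sum_k (n-k) g^k]
    (summation form: numerically stable for g -> +-1)."""
    k = np.arange(1, n)
    return b * b * (n + 2.0 * np.sum((n - k) * np.power(g, k)))


def _calibrate_frc(L, lp, n):
    """Bond-correlation g such that the discrete freely rotating chain of n
    segments reproduces the WLC mean-square end-to-end exactly."""
    b = L / n
    target = wlc_mean_square_ee(L, lp)
    lo, hi = -0.999999999, 1.0 - 1e-12
    f = lambda g: _frc_mean_square_ee(n, b, g) - target
    if f(hi) <= 0.0:   # effectively rigid
        return hi
    return brentq(f, lo, hi, xtol=1e-13)


def sample_wlc_end_to_end(L, lp, rng, n_segments=100, size=None):
    """Sample end-to-end distances consistent with the worm-like chain.

    Draws from a discrete freely rotating chain of ``n_segments`` bonds
    whose correlation is moment-matched to the WLC closed form, so the
    sampled second moment converges to ``wlc_mean_square_ee(L, lp)`` and
    every sample is bounded by the contour length L.
    """
    if n_segments < 1:
        raise InputError("n_segments must be >= 1")
    scalar = size is None
    m = 1 if scalar else int(size)
    n = int(n_segments)
    b = L / n
    if n == 1:
        out = np.full(m, L)
        return float(out[0]) if scalar else out
    g = _calibrate_frc(L, lp, n)
    dist = _sample_frc_distance(n, b, g, rng, m)
    return float(dist[0]) if scalar else dist


def _sample_frc_distance(n, b, g, rng, m):
    """End-to-end distances of m freely rotating chains (n bonds of length
    b, bond correlation g)."""
    ct = np.clip(g, -1.0, 1.0)
    st = np.sqrt(max(0.0, 1.0 - ct * ct))
    t = _random_unit(rng, m)
    ends = b * t.copy()
    for _ in range(n - 1):
        phi = rng.uniform(0.0, 2.0 * np.pi, m)
        # orthonormal frame around each current direction t
        helper = np.where(np.abs(t[:, 2:3]) < 0.9,
                          np.array([0.0, 0.0, 1.0]),
                          np.array([1.0, 0.0, 0.0]))
        u = np.cross(t, helper)
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        v = np.cross(t, u)
        t = ct * t + st * (np.cos(phi)[:, None] * u + np.sin(phi)[:, None] * v)
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        ends += b * t
    return np.linalg.norm(ends, axis=1)


def _random_unit(rng, size=None):
    """Uniform random unit vector(s)."""
    shape = (3,) if size is None else (size, 3)
    vec = rng.normal(size=shape)
    norm = np.linalg.norm(vec, axis=-1, keepdims=True)
    return vec / norm


# ---------------------------------------------------------------------------
# distance-restraint bounds
# ---------------------------------------------------------------------------

def restraint_bounds(target, tol, remaining_edges, step_length):
    """Bounds on the distance to the restraint anchor while ``g`` tree
    edges remain to the restrained partner: the partner can still move at
    most ``g * step`` away, so
    ``lower = max(0, d* - g s - tol)``, ``upper = d* + g s + tol``."""
    slack = remaining_edges * step_length + tol
    lower = max(0.0, target - slack)
    upper = target + slack
    if lower > upper:
        raise InputError("infeasible restraint bounds")
    return lower, upper


# ---------------------------------------------------------------------------
# the walk
# ---------------------------------------------------------------------------

class WalkState:
    """Mutable state of one molecule's random walk."""

    def __init__(self, graph, box, rng, exclusion=None):
        self.graph = graph
        self.box = np.asarray(box, dtype=float)
        self.rng = rng
        self.exclusion = exclusion
        root = min(graph.nodes)
        tree = nx.bfs_tree(graph, root)
        self.order = [root] + [v for _, v in nx.bfs_edges(graph, root)]
        self.parent = {v: u for u, v in tree.edges}
        self.positions = {}          # node -> wrapped position
        self.placed_order = []       # traversal order of placed nodes
        self.attempts = 0
        self.rejections = 0

    def rho(self, node):
        return self.graph.nodes[node]["rho"]

    def placed(self, node):
        return node in self.positions

    def _local_arrays(self, node):
        """Positions/rho of placed beads excluding graph neighbors of
        ``node`` (bonded pairs are not checked against f_max)."""
        adjacent = set(self.graph[node])
        rows = [n for n in self.placed_order if n not in adjacent]
        if not rows:
            return np.empty((0, 3)), np.empty(0)
        return (np.array([self.positions[n] for n in rows]),
                np.array([self.rho(n) for n in rows]))

    def max_force(self, node, candidate):
        rho_c = self.rho(node)
        force = 0.0
        if self.exclusion is not None:
            force = self.exclusion.max_force(candidate, rho_c)
        pos, rho = self._local_arrays(node)
        if len(pos):
            force = max(force, _max_pair_force(candidate, pos, rho, rho_c,
                                               self.box))
        return force


def _cone_direction(axis, cos_theta, rng):
    """Unit vector at fixed polar angle to ``axis``, uniform azimuth."""
    x = np.clip(cos_theta, -1.0, 1.0)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    helper = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 \
        else np.array([1.0, 0.0, 0.0])
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    sin_t = np.sqrt(max(0.0, 1.0 - x * x))
    return x * axis + sin_t * (np.cos(phi) * u + np.sin(phi) * v)


def try_place(state, node, from_position, step_length, options, fmax,
              restraint_ctx=None, direction=None):
    """One placement attempt; returns the accepted (wrapped) position or
    ``None`` on rejection.

    Unless a ``direction`` proposal is given, the step direction is
    uniform on the unit sphere, restricted to the spherical cap satisfying
    the tightest active distance-restraint bound (an exact conditional
    draw: for uniform directions the cosine towards any axis is uniform,
    so sampling the cosine uniformly inside its feasible interval equals
    rejection sampling of uniform directions)."""
    rng = state.rng
    state.attempts += 1
    if from_position is None:
        raise InputError("try_place needs a from_position")
    from_position = np.asarray(from_position, dtype=float)
    if direction is None and restraint_ctx is not None:
        direction = restraint_ctx.guided_direction(state, node,
                                                   from_position,
                                                   step_length, rng)
        if direction is _INFEASIBLE:
            state.rejections += 1
            return None
    if direction is None:
        direction = _random_unit(rng)
    candidate = np.mod(from_position + step_length * direction, state.box)
    if _accept(state, node, candidate, options, fmax, restraint_ctx):
        return candidate
    state.rejections += 1
    return None


def _accept(state, node, candidate, options, fmax, restraint_ctx):
    for constraint in options.geometry:
        if not constraint.allows(candidate):
            return False
    for slab in options.dimension:
        if not slab.allows(candidate):
            return False
    if restraint_ctx is not None and not restraint_ctx.check(state, node,
                                                             candidate):
        return False
    if fmax is not None and np.isfinite(fmax):
        if state.max_force(node, candidate) > fmax:
            return False
    return True


_INFEASIBLE = object()


class _RestraintContext:
    """Precomputed graph distances for the active distance restraints."""

    def __init__(self, graph, restraints, bound_step):
        self.restraints = list(restraints)
        self.bound_step = bound_step
        self.dist = {}
        for r in self.restraints:
            for end in (r.u, r.v):
                if end not in self.dist:
                    self.dist[end] = nx.single_source_shortest_path_length(
                        graph, end
                    )

    def _active(self, state, node):
        """(anchor position reference, lower, upper) per restraint with
        exactly one placed endpoint and a finite graph distance."""
        out = []
        for r in self.restraints:
            u_placed, v_placed = state.placed(r.u), state.placed(r.v)
            if node == r.u:
                u_placed = False
            if node == r.v:
                v_placed = False
            if u_placed == v_placed:
                continue
            anchor, other = (r.u, r.v) if u_placed else (r.v, r.u)
            g = self.dist[other].get(node)
            if g is None:
                continue
            lower, upper = restraint_bounds(r.target, r.tol, g,
                                            self.bound_step)
            out.append((anchor, lower, upper))
        return out

    def guided_direction(self, state, node, from_position, step, rng):
        """Uniform direction on the feasible cap of the tightest active
        bound; ``None`` when no bound restricts the step, ``_INFEASIBLE``
        when a bound cannot be met from here."""
        best = None
        for anchor, lower, upper in self._active(state, node):
            axis = minimum_image(from_position, state.positions[anchor],
                                 state.box)
            a = float(np.linalg.norm(axis))
            if a < 1e-12:
                # step lands at distance `step` regardless of direction
                if not lower <= step <= upper:
                    return _INFEASIBLE
                continue
            # |a + s u|^2 = a^2 + s^2 + 2 a s x with x = cos(angle to axis)
            denom = 2.0 * a * step
            x_lo = (lower * lower - a * a - step * step) / denom
            x_hi = (upper * upper - a * a - step * step) / denom
            x_lo, x_hi = max(-1.0, x_lo), min(1.0, x_hi)
            if x_lo > x_hi:
                return _INFEASIBLE
            width = x_hi - x_lo
            if width >= 2.0 - 1e-12:
                continue  # bound never binds for this step
            if best is None or width < best[0]:
                best = (width, x_lo, x_hi, axis / a)
        if best is None:
            return None
        _width, x_lo, x_hi, axis = best
        x = rng.uniform(x_lo, x_hi)
        phi = rng.uniform(0.0, 2.0 * np.pi)
        helper = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 \
            else np.array([1.0, 0.0, 0.0])
        u = np.cross(axis, helper)
        u /= np.linalg.norm(u)
        v = np.cross(axis, u)
        sin_t = np.sqrt(max(0.0, 1.0 - x * x))
        return x * axis + sin_t * (np.cos(phi) * u + np.sin(phi) * v)

    def check(self, state, node, candidate):
        for r in self.restraints:
            u_placed, v_placed = state.placed(r.u), state.placed(r.v)
            if node == r.u:
                u_placed = False
            if node == r.v:
                v_placed = False
            if u_placed == v_placed:   # both or neither: nothing to bound
                continue
            anchor, other = (r.u, r.v) if u_placed else (r.v, r.u)
            g = self.dist[other].get(node)
            if g is None:
                continue
            lower, upper = restraint_bounds(r.target, r.tol, g,
                                            self.bound_step)
            d = float(np.linalg.norm(
                minimum_image(candidate, state.positions[anchor], state.box)
            ))
            if not lower <= d <= upper:
                return False
        return True


def _step_length(graph, u, v, options, spec):
    if options.step_length is not None:
        return options.step_length
    rho_u = graph.nodes[u]["rho"]
    rho_v = graph.nodes[v]["rho"]
    return spec.step_factor * (rho_u + rho_v)


class StartRejected(BuildError):
    """The start point itself violates constraints or forces."""


def walk_molecule(graph, start, spec, rng, options=None, exclusion=None,
                  box=None):
    """Grow one molecule; returns ``{node: position}`` (wrapped).

    ``graph`` is the molecule's super-CG residue graph with a ``rho`` node
    attribute (bead radius, nm).  Persistence specs are converted to
    distance restraints whose targets are drawn from the WLC end-to-end
    sampler.  Raises :class:`StartRejected` if the start point is invalid
    and :class:`BuildError` when placement fails after all restarts.
    """
    options = options or MoleculeOptions()
    box = np.asarray(box if box is not None else spec.box, dtype=float)
    state = WalkState(graph, box, rng, exclusion=exclusion)

    steps = {
        (u, v): _step_length(graph, u, v, options, spec)
        for u, v in graph.edges
    }
    steps.update({(v, u): s for (u, v), s in list(steps.items())})
    max_step = max(steps.values()) if steps else 0.0

    # Persistence specs become (a) a fixed-angle bond-direction correlation
    # along the restrained span (the discrete worm-like chain) and (b) an
    # end-to-end distance restraint whose target is drawn from the same
    # moment-matched chain, so walk statistics and target distribution are
    # mutually consistent.
    restraints = list(options.restraints)
    stiffness = {}
    for pspec in options.persistence:
        path = nx.shortest_path(graph, pspec.start, pspec.stop)
        seg_lengths = [steps[(a, b)] for a, b in zip(path, path[1:])]
        contour = float(np.sum(seg_lengths))
        if contour <= 0:
            continue
        n_seg = len(seg_lengths)
        corr = _calibrate_frc(contour, pspec.lp, n_seg) if n_seg > 1 else 1.0
        target = float(_sample_frc_distance(n_seg, contour / n_seg, corr,
                                            rng, 1)[0]) if n_seg > 1 \
            else contour
        for node in path[1:]:
            stiffness[node] = corr
        tol = pspec.tol if pspec.tol is not None else 0.25 * np.mean(seg_lengths)
        restraints.append(
            DistanceRestraint(pspec.start, pspec.stop, target, tol)
        )
    for r in restraints:
        reach = nx.shortest_path_length(graph, r.u, r.v) * max_step
        if r.target - r.tol > reach:
            raise InputError(
                f"restraint ({r.u}, {r.v}) target {r.target:.3g} nm cannot "
                f"be reached through {reach:.3g} nm of bonds"
            )
    rctx = _RestraintContext(graph, restraints, max_step) if restraints \
        else None

    start = np.mod(np.asarray(start, dtype=float), box)
    if not _accept(state, state.order[0], start, options, spec.fmax, rctx):
        raise StartRejected("start point rejected")
    state.positions[state.order[0]] = start
    state.placed_order.append(state.order[0])

    restarts = 0
    i = 1
    while i < len(state.order):
        node = state.order[i]
        parent = state.parent[node]
        step = steps[(parent, node)]
        corr = stiffness.get(node)
        grandparent = state.parent.get(parent)
        pos = None
        for attempt in range(spec.max_attempts):
            direction = None
            if (corr is not None and grandparent is not None
                    and grandparent in state.positions
                    and attempt < spec.max_attempts // 2):
                prev = minimum_image(state.positions[parent],
                                     state.positions[grandparent], box)
                norm = np.linalg.norm(prev)
                if norm > 1e-12:
                    direction = _cone_direction(prev / norm, corr, rng)
            pos = try_place(state, node, state.positions[parent], step,
                            options, spec.fmax, rctx, direction=direction)
            if pos is not None:
                break
        if pos is not None:
            state.positions[node] = pos
            state.placed_order.append(node)
            i += 1
            continue
        # backtrack: drop the last k placed beads and regrow
        restarts += 1
        if restarts > spec.max_restarts:
            raise BuildError(
                f"failed to place bead {node} after {spec.max_restarts} "
                f"restarts ({len(state.placed_order)} of "
                f"{len(state.order)} beads placed)"
            )
        k = min(spec.backtrack, len(state.placed_order) - 1)
        for _ in range(k):
            dropped = state.placed_order.pop()
            del state.positions[dropped]
        i = len(state.placed_order)
    return state


# ---------------------------------------------------------------------------
# system building
# ---------------------------------------------------------------------------

@dataclass
class SystemCoordinates:
    """Super-CG bead positions for every molecule instance."""

    molecules: list        # of (molname, {node: position})
    box: np.ndarray
    log: dict = field(default_factory=dict)


def _grid_points(box, spacing, rng):
    axes = []
    for d in range(3):
        n = max(1, int(box[d] // spacing))
        h = box[d] / n
        axes.append(h / 2.0 + h * np.arange(n))
    pts = np.array(np.meshgrid(*axes, indexing="ij")).reshape(3, -1).T
    return pts[rng.permutation(len(pts))]


def build_system(top_model, supercg, spec, rng, frozen=None):
    """Grow every molecule of the composition sequentially.

    ``supercg`` maps molecule name to its super-CG residue graph (node
    attribute ``rho``).  ``frozen`` is an optional ``(positions, rho)``
    pair of pre-existing beads that enter the exclusion set but are never
    moved.  Fully deterministic for a fixed ``rng`` state.
    """
    if spec.box is None:
        raise InputError("build spec must define a box")
    box = np.asarray(spec.box, dtype=float)
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng

    graphs = {
        name: getattr(model, "graph", model) for name, model in supercg.items()
    }
    volume = 0.0
    rho_all = []
    for name, count in top_model.composition:
        graph = graphs[name]
        rhos = [graph.nodes[n]["rho"] for n in graph.nodes]
        rho_all += rhos
        volume += count * np.sum(4.0 / 3.0 * np.pi * np.power(rhos, 3))
    if volume > np.prod(box):
        raise InputError(
            f"total bead volume {volume:.1f} nm^3 exceeds the box volume "
            f"{np.prod(box):.1f} nm^3"
        )

    exclusion = ExclusionField(box)
    if frozen is not None:
        exclusion.add(*frozen)

    spacing = spec.grid_spacing or max(
        2.0 * max(rho_all), min(box) / 64.0
    )
    grid = list(_grid_points(box, spacing, rng))
    n_molecules = sum(c for _, c in top_model.composition)
    if len(grid) < n_molecules:
        raise InputError(
            f"start grid has {len(grid)} points for {n_molecules} molecules"
        )

    placed = []
    log = {"attempts": 0, "rejections": 0, "molecules": 0}
    for name, count in top_model.composition:
        graph = graphs[name]
        for idx in range(count):
            options = spec.options_for(name, idx)
            state = None
            if options.start is not None:
                state = walk_molecule(graph, options.start, spec, rng,
                                      options=options, exclusion=exclusion,
                                      box=box)
            else:
                while state is None:
                    if not grid:
                        raise BuildError(
                            f"start grid exhausted while placing {name!r}"
                        )
                    point = grid.pop()
                    try:
                        state = walk_molecule(graph, point, spec, rng,
                                              options=options,
                                              exclusion=exclusion, box=box)
                    except StartRejected:
                        continue
            coords = dict(state.positions)
            placed.append((name, coords))
            nodes = sorted(coords)
            exclusion.add([coords[n] for n in nodes],
                          [graph.nodes[n]["rho"] for n in nodes])
            log["attempts"] += state.attempts
            log["rejections"] += state.rejections
            log["molecules"] += 1
    return SystemCoordinates(molecules=placed, box=box, log=log)
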
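"""Residue templates and the generic super-CG model.

Each unique residue gets 3-D coordinates by a two-step graph embedding:
a Kamada-Kawai layout of the residue's bonded graph (edge lengths set to
the equilibrium bond lengths) provides the initial guess, which is then
relaxed by an L-BFGS minimization of the bonded energy (bonds, angles,
dihedrals, impropers, plus a short-range soft repulsion that keeps
nonbonded atoms apart).  Chirality is maintained by signed improper
dihedrals: if a minimized improper has the wrong sign the offending atom
is reflected through the plane of the other three and the template is
re-minimized.

From the template the one-bead super-CG parameters are derived: the bead
radius is ``rho = sqrt(5/3) R_g + r_a`` (the uniform-sphere conversion of
the radius of gyration to a hard radius plus an atomic radius ``r_a``,
default 0.21 nm) and the pair diameter is the Lorentz combination
``sigma_ij = rho_i + rho_j``.  The LJ well depth is always 1 kJ/mol; the
model exists only to steer the random walk, not to run dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.optimize import minimize

from .errors import BuildError, InputError
from .residue_graphs import graph_from_topology

DEFAULT_ATOM_RADIUS = 0.21  # nm
_REPULSION_DIST = 0.10      # nm; soft floor for nonbonded intra-residue pairs
_REPULSION_K = 1.0e4


@dataclass
class ResidueTemplate:
    """Target-resolution coordinates of one residue plus derived size."""

    resname: str
    positions: dict                  # atom name -> np.ndarray (nm), COG at 0
    rg: float = 0.0
    rho: float = 0.0                 # super-CG bead radius (nm)
    atom_radius: float = DEFAULT_ATOM_RADIUS

    @property
    def sigma(self):
        """Self pair diameter sigma_ii."""
        return 2.0 * self.rho

    def array(self, names=None):
        names = names if names is not None else list(self.positions)
        return np.array([self.positions[n] for n in names])


def radius_of_gyration(positions):
    """Unit-weight radius of gyration: sqrt(mean |r - cog|^2)."""
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    if pos.size == 0:
        raise InputError("radius_of_gyration needs at least one position")
    delta = pos - pos.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(delta * delta, axis=1))))


def derive_sigma(rg, r_a=DEFAULT_ATOM_RADIUS, rg_other=None):
    """Bead radius and pair sigma from radii of gyration.

    rho = sqrt(5/3) R_g + r_a; sigma_ij = rho_i + rho_j.  Monotone
    increasing in R_g.  ``rg`` may also be a template."""
    if r_a <= 0:
        raise InputError("atomic radius must be positive")
    if isinstance(rg, ResidueTemplate):
        rg = rg.rg
    rho_i = np.sqrt(5.0 / 3.0) * rg + r_a
    if rg_other is None:
        return rho_i, 2.0 * rho_i
    rho_j = np.sqrt(5.0 / 3.0) * rg_other + r_a
    return rho_i, rho_i + rho_j


# ---------------------------------------------------------------------------
# bonded energy of a block
# ---------------------------------------------------------------------------

_CONSTRAINT_K = 5.0e4


def _bonded_terms(block):
    """(bonds, angles, propers, impropers) as index-based parameter lists."""
    index = {name: i for i, name in enumerate(block.atom_names())}
    bonds, angles, propers, impropers = [], [], [], []
    for term in block.interactions.get("bonds", []):
        b0 = term.params[0] if term.params else 0.15
        k = term.params[1] if len(term.params) > 1 else 1.0e4
        bonds.append((index[term.atoms[0]], index[term.atoms[1]], b0, k))
    for term in block.interactions.get("constraints", []):
        b0 = term.params[0] if term.params else 0.15
        bonds.append((index[term.atoms[0]], index[term.atoms[1]], b0,
                      _CONSTRAINT_K))
    for term in block.interactions.get("angles", []):
        theta0 = np.deg2rad(term.params[0]) if term.params else np.deg2rad(109.5)
        k = term.params[1] if len(term.params) > 1 else 100.0
        i, j, l = (index[a] for a in term.atoms)
        angles.append((i, j, l, theta0, k))
    for term in block.interactions.get("dihedrals", []):
        i, j, l, m = (index[a] for a in term.atoms)
        phi0 = np.deg2rad(term.params[0]) if term.params else 0.0
        k = term.params[1] if len(term.params) > 1 else 5.0
        mult = term.params[2] if len(term.params) > 2 else 1.0
        propers.append((i, j, l, m, phi0, k, mult))
    for term in block.interactions.get("impropers", []):
        i, j, l, m = (index[a] for a in term.atoms)
        xi0 = np.deg2rad(term.params[0]) if term.params else 0.0
        k = term.params[1] if len(term.params) > 1 else 100.0
        impropers.append((i, j, l, m, xi0, k))
    return bonds, angles, propers, impropers


def _dihedral_angle(p0, p1, p2, p3):
    """Signed dihedral (rad) of four points."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / (np.linalg.norm(b1) + 1e-30))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.arctan2(y, x))


def _wrap_angle(angle):
    return (angle + np.pi) % (2.0 * np.pi) - np.pi


def _block_energy(x, n, bonds, angles, propers, impropers, nonbonded):
    pos = x.reshape(n, 3)
    energy = 0.0
    for i, j, b0, k in bonds:
        r = np.linalg.norm(pos[i] - pos[j])
        energy += 0.5 * k * (r - b0) ** 2
    for i, j, l, theta0, k in angles:
        v1 = pos[i] - pos[j]
        v2 = pos[l] - pos[j]
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)
                                   + 1e-30)
        theta = np.arccos(np.clip(cosang, -1.0, 1.0))
        energy += 0.5 * k * (theta - theta0) ** 2
    for i, j, l, m, phi0, k, mult in propers:
        phi = _dihedral_angle(pos[i], pos[j], pos[l], pos[m])
        energy += k * (1.0 + np.cos(mult * phi - phi0))
    for i, j, l, m, xi0, k in impropers:
        xi = _dihedral_angle(pos[i], pos[j], pos[l], pos[m])
        energy += 0.5 * k * _wrap_angle(xi - xi0) ** 2
    for i, j in nonbonded:
        r = np.linalg.norm(pos[i] - pos[j])
        if r < _REPULSION_DIST:
            energy += 0.5 * _REPULSION_K * (r - _REPULSION_DIST) ** 2
    return energy


def _minimize_block(pos, bonds, angles, propers, impropers, nonbonded,
                    gtol=1e-6, maxiter=2000):
    n = len(pos)
    result = minimize(
        _block_energy, pos.ravel(),
        args=(n, bonds, angles, propers, impropers, nonbonded),
        method="L-BFGS-B",
        options={"gtol": gtol, "maxiter": maxiter, "ftol": 1e-14},
    )
    return result.x.reshape(n, 3), result


def embed_residue(block, seed=42):
    """Two-step graph embedding: seeded Kamada-Kawai layout in 3-D with
    edge lengths at the equilibrium bond lengths, then bonded-energy
    minimization.  Deterministic for a fixed seed."""
    names = block.atom_names()
    n = len(names)
    if n == 1:
        return {names[0]: np.zeros(3)}
    bonds, angles, propers, impropers = _bonded_terms(block)
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    for i, j, b0, _k in bonds:
        graph.add_edge(i, j, dist=b0)
    if not nx.is_connected(graph):
        raise InputError(f"block {block.resname!r}: bonded graph disconnected")
    rng = np.random.default_rng(seed)
    init = {i: rng.normal(scale=0.1, size=3) for i in range(n)}
    layout = nx.kamada_kawai_layout(graph, dim=3, weight=None, pos=init,
                                    dist=dict(nx.all_pairs_dijkstra_path_length(
                                        graph, weight="dist")))
    pos = np.array([layout[i] for i in range(n)])
    bonded_pairs = {frozenset((i, j)) for i, j, *_ in bonds}
    nonbonded = [(i, j) for i in range(n) for j in range(i + 1, n)
                 if frozenset((i, j)) not in bonded_pairs]
    pos, result = _minimize_block(pos, bonds, angles, propers, impropers,
                                  nonbonded)
    grad_norm = float(np.max(np.abs(result.jac))) if result.jac is not None \
        else np.inf
    for i, j, b0, _k in bonds:
        r = np.linalg.norm(pos[i] - pos[j])
        if abs(r - b0) > 0.1 * b0:
            raise BuildError(
                f"block {block.resname!r}: minimization left bond "
                f"{names[i]}-{names[j]} at {r:.3f} nm (b0 {b0:.3f} nm); "
                f"residual gradient {grad_norm:.2e}"
            )
    pos = pos - pos.mean(axis=0)
    return {names[i]: pos[i] for i in range(n)}


def enforce_chirality(block, positions, max_passes=5):
    """Flip mirror images until every signed improper matches the sign of
    its target angle; identity when the block carries no impropers."""
    impropers = [t for t in block.interactions.get("impropers", [])
                 if t.params and t.params[0] != 0.0]
    if not impropers:
        return positions
    names = block.atom_names()
    index = {name: i for i, name in enumerate(names)}
    bonds, angles, propers, imp_terms = _bonded_terms(block)
    bonded_pairs = {frozenset((i, j)) for i, j, *_ in bonds}
    n = len(names)
    nonbonded = [(i, j) for i in range(n) for j in range(i + 1, n)
                 if frozenset((i, j)) not in bonded_pairs]
    pos = np.array([positions[name] for name in names])
    for _ in range(max_passes):
        wrong = None
        for term in impropers:
            i, j, l, m = (index[a] for a in term.atoms)
            xi = _dihedral_angle(pos[i], pos[j], pos[l], pos[m])
            if np.sign(xi) != np.sign(np.deg2rad(term.params[0])) and xi != 0:
                wrong = (i, j, l, m)
                break
        if wrong is None:
            pos = pos - pos.mean(axis=0)
            return {names[i]: pos[i] for i in range(n)}
        i, j, l, m = wrong
        # reflect the first atom through the plane of the other three
        normal = np.cross(pos[l] - pos[j], pos[m] - pos[j])
        normal /= np.linalg.norm(normal) + 1e-30
        pos[i] = pos[i] - 2.0 * np.dot(pos[i] - pos[j], normal) * normal
        pos, _ = _minimize_block(pos, bonds, angles, propers, imp_terms,
                                 nonbonded)
    raise BuildError(
        f"block {block.resname!r}: could not enforce improper signs after "
        f"{max_passes} reflection passes"
    )


def make_template(block, r_a=DEFAULT_ATOM_RADIUS, seed=42):
    """Embed, fix chirality, and derive the super-CG size of one block."""
    positions = embed_residue(block, seed=seed)
    positions = enforce_chirality(block, positions)
    rg = radius_of_gyration(list(positions.values()))
    rho, _sigma = derive_sigma(rg, r_a=r_a)
    return ResidueTemplate(resname=block.resname, positions=positions,
                           rg=rg, rho=rho, atom_radius=r_a)


def make_templates(library, r_a=DEFAULT_ATOM_RADIUS, seed=42):
    return {name: make_template(block, r_a=r_a, seed=seed)
            for name, block in library.blocks.items()}


def templates_from_molecule(mol, r_a=DEFAULT_ATOM_RADIUS, seed=42):
    """Templates for every unique residue type of a parsed molecule, built
    by converting each residue back into a block."""
    from .topology_gen import Block, Interaction

    templates = {}
    residues = mol.residue_atoms()
    for resid, atom_map in residues.items():
        resname = mol.atoms[next(iter(atom_map.values()))].resname
        if resname in templates:
            continue
        indices = sorted(atom_map.values())
        local = {g: mol.atoms[g].name for g in indices}
        block = Block(resname=resname,
                      atoms=[{"name": mol.atoms[g].name,
                              "type": mol.atoms[g].type,
                              "charge": mol.atoms[g].charge,
                              "mass": mol.atoms[g].mass} for g in indices])
        for directive, terms in mol.interactions.items():
            for term in terms:
                if all(a in local for a in term.atoms):
                    block.interactions.setdefault(directive, []).append(
                        Interaction(tuple(local[a] for a in term.atoms),
                                    term.func, term.params)
                    )
        templates[resname] = make_template(block, r_a=r_a, seed=seed)
    return templates


# ---------------------------------------------------------------------------
# super-CG model
# ---------------------------------------------------------------------------

@dataclass
class SuperCGModel:
    """One-bead-per-residue model of a molecule: the residue graph with a
    ``rho`` attribute per node; epsilon is fixed at 1 kJ/mol."""

    name: str
    graph: nx.Graph
    epsilon: float = 1.0

    def sigma(self, u, v):
        return self.graph.nodes[u]["rho"] + self.graph.nodes[v]["rho"]


def build_supercg(mol, templates):
    """Super-CG graph of a molecule from its topology and templates."""
    graph = graph_from_topology(mol)
    for node, attrs in graph.nodes(data=True):
        template = templates.get(attrs["resname"])
        if template is None:
            raise InputError(
                f"no template for resname {attrs['resname']!r} "
                f"(molecule {mol.name!r})"
            )
        graph.nodes[node]["rho"] = template.rho
    return SuperCGModel(name=mol.name, graph=graph)
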
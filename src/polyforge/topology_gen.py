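"""Graph transformation from residue graphs to molecule topologies.

A molecule is described at two resolutions.  At the *residue* level it is a
graph whose nodes are residues; at the *target* level it is a graph of atoms
(or coarse-grained beads) carrying the full set of bonded interactions.  The
transformation proceeds in three steps:

1. for every residue-graph node the matching :class:`Block` is instantiated,
   yielding a disconnected target-resolution graph;
2. every :class:`Link` pattern is matched onto the residue graph by induced
   subgraph isomorphism, honoring residue-name patterns and optional node or
   edge attribute constraints (chirality tags, linkage types, ...);
3. each match resolves the link's ``(offset, atom-name)`` references to
   global atom indices and appends the inter-residue interactions, gradually
   connecting the target-resolution graph.

Blocks and links are force-field agnostic: the same machinery serves
all-atom and coarse-grained libraries alike.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
from networkx.algorithms import isomorphism as nx_iso

from .errors import InputError

#: number of atoms referenced by an interaction of each directive
ARITY = {
    "bonds": 2,
    "constraints": 2,
    "pairs": 2,
    "angles": 3,
    "dihedrals": 4,
    "impropers": 4,
    "exclusions": 2,
}

#: directives whose interactions imply a bonded edge in the molecular graph
EDGE_DIRECTIVES = ("bonds", "constraints")

WILDCARD = "*"


@dataclass(frozen=True)
class Interaction:
    """A single bonded interaction.

    ``atoms`` holds atom references whose type depends on context: atom
    names inside a block, ``(offset, name)`` pairs inside a link, and
    0-based global indices inside a molecule.
    """

    atoms: tuple
    func: int
    params: tuple = ()
    meta: dict = field(default_factory=dict, compare=False, hash=False)

    def canonical_atoms(self):
        """Direction-invariant key: an interaction and its reverse are the
        same physical term."""
        rev = tuple(reversed(self.atoms))
        return min(self.atoms, rev)


@dataclass
class Block:
    """All atoms and intra-residue interactions of one residue."""

    resname: str
    atoms: list  # of dicts: name, type, charge, mass
    interactions: dict = field(default_factory=dict)  # directive -> [Interaction]

    def atom_names(self):
        return [a["name"] for a in self.atoms]

    def validate(self):
        names = self.atom_names()
        if len(set(names)) != len(names):
            raise InputError(
                f"block {self.resname!r}: duplicate atom names {names}"
            )
        known = set(names)
        for directive, terms in self.interactions.items():
            arity = ARITY.get(directive)
            for term in terms:
                if arity is not None and len(term.atoms) != arity:
                    raise InputError(
                        f"block {self.resname!r}: {directive} interaction has "
                        f"{len(term.atoms)} atoms, expected {arity}"
                    )
                for name in term.atoms:
                    if name not in known:
                        raise InputError(
                            f"block {self.resname!r}: interaction references "
                            f"unknown atom {name!r}"
                        )

    def to_graph(self):
        """Atom-level graph of the block (nodes = atom names)."""
        g = nx.Graph()
        g.add_nodes_from(self.atom_names())
        for directive in EDGE_DIRECTIVES:
            for term in self.interactions.get(directive, ()):
                g.add_edge(*term.atoms)
        return g


@dataclass
class Link:
    """Inter-residue interaction pattern.

    The pattern is a small graph whose nodes are relative residue offsets
    (0 is the anchor).  Node attributes: ``resname`` (exact name or ``"*"``)
    plus arbitrary match constraints (e.g. ``chirality``).  Edge attributes
    constrain residue-graph edge attributes (e.g. ``linktype``).
    Interactions reference atoms as ``(offset, atom name)``.
    """

    pattern: nx.Graph
    interactions: dict = field(default_factory=dict)
    edges_to_add: list = field(default_factory=list)  # [((off, name), (off, name))]
    name: str = ""

    def offsets(self):
        return sorted(self.pattern.nodes)

    def validate(self):
        offs = self.offsets()
        if not offs:
            raise InputError(f"link {self.name!r}: empty pattern")
        if 0 not in offs:
            raise InputError(f"link {self.name!r}: pattern must contain offset 0")
        if offs != list(range(offs[0], offs[-1] + 1)):
            raise InputError(
                f"link {self.name!r}: offsets {offs} are not contiguous"
            )
        if not nx.is_connected(self.pattern):
            raise InputError(f"link {self.name!r}: pattern graph is disconnected")
        for directive, terms in self.interactions.items():
            arity = ARITY.get(directive)
            for term in terms:
                if arity is not None and len(term.atoms) != arity:
                    raise InputError(
                        f"link {self.name!r}: {directive} interaction has "
                        f"{len(term.atoms)} atoms, expected {arity}"
                    )
                for off, _ in term.atoms:
                    if off not in self.pattern:
                        raise InputError(
                            f"link {self.name!r}: interaction references "
                            f"offset {off} outside the pattern"
                        )


@dataclass
class ForceFieldLibrary:
    """Named blocks plus an ordered list of links.

    Link order is part of the contract: links are applied in file order and
    a later link overrides an earlier one on the same atom tuple.
    """

    name: str = "forcefield"
    version: str = ""
    blocks: dict = field(default_factory=dict)  # resname -> Block
    links: list = field(default_factory=list)

    def validate(self):
        for block in self.blocks.values():
            block.validate()
        for link in self.links:
            link.validate()
            # a link atom must exist in its block when the resname is exact
            for directive, terms in link.interactions.items():
                for term in terms:
                    for off, name in term.atoms:
                        resname = link.pattern.nodes[off].get("resname", WILDCARD)
                        if resname == WILDCARD:
                            continue
                        if resname not in self.blocks:
                            raise InputError(
                                f"link {link.name!r}: resname {resname!r} not "
                                "resolvable in the library"
                            )
                        if name not in self.blocks[resname].atom_names():
                            raise InputError(
                                f"link {link.name!r}: atom {name!r} absent "
                                f"from block {resname!r}"
                            )


@dataclass
class Atom:
    """One target-resolution particle of a molecule."""

    name: str
    resid: int  # 0-based, contiguous
    resname: str
    type: str
    charge: float = 0.0
    mass: float = 0.0


@dataclass
class MoleculeTopology:
    """Target-resolution molecule: atoms, interactions, bonded graph."""

    name: str
    atoms: list = field(default_factory=list)  # of Atom
    interactions: dict = field(default_factory=dict)  # directive -> [Interaction]
    graph: nx.Graph = field(default_factory=nx.Graph)
    nrexcl: int = 1

    # -- residue-level helpers ------------------------------------------
    def n_residues(self):
        return 1 + max((a.resid for a in self.atoms), default=-1)

    def residue_atoms(self):
        """Per-residue mapping ``resid -> {atom name: global index}``."""
        out = {}
        for idx, atom in enumerate(self.atoms):
            res = out.setdefault(atom.resid, {})
            if atom.name in res:
                res[atom.name] = None  # ambiguous
            else:
                res[atom.name] = idx
        return out

    def residue_of(self, index):
        return self.atoms[index].resid

    def add_interaction(self, directive, interaction, replace=True):
        """Append ``interaction``; an existing term on the same (canonical)
        atom tuple is replaced when ``replace`` (later links win)."""
        terms = self.interactions.setdefault(directive, [])
        if replace:
            key = interaction.canonical_atoms()
            for i, term in enumerate(terms):
                if term.canonical_atoms() == key:
                    terms[i] = interaction
                    return
        terms.append(interaction)

    def validate(self):
        n = len(self.atoms)
        for directive, terms in self.interactions.items():
            for term in terms:
                for idx in term.atoms:
                    if not 0 <= idx < n:
                        raise InputError(
                            f"molecule {self.name!r}: {directive} references "
                            f"atom index {idx} out of range"
                        )
        resids = sorted({a.resid for a in self.atoms})
        if resids and resids != list(range(len(resids))):
            raise InputError(
                f"molecule {self.name!r}: residue ids not contiguous: {resids}"
            )

    def __eq__(self, other):
        if not isinstance(other, MoleculeTopology):
            return NotImplemented
        mine = {d: v for d, v in self.interactions.items() if v}
        theirs = {d: v for d, v in other.interactions.items() if v}
        return (
            self.name == other.name
            and self.atoms == other.atoms
            and mine == theirs
            and set(self.graph.edges) == set(other.graph.edges)
        )


# ---------------------------------------------------------------------------
# Step 1: disconnected graph of residues at the target resolution
# ---------------------------------------------------------------------------

def build_disconnected(graph, library, name="MOL"):
    """Instantiate the matching block for every residue-graph node.

    Residues are laid out in sorted node order; resid ``i`` corresponds to
    the i-th sorted node.  The result contains all intra-residue
    interactions and no inter-residue edges.
    """
    mol = MoleculeTopology(name=name)
    nodes = sorted(graph.nodes)
    offset = 0
    for resid, node in enumerate(nodes):
        resname = graph.nodes[node].get("resname")
        block = library.blocks.get(resname)
        if block is None:
            raise InputError(
                f"no block for resname {resname!r} (residue-graph node {node!r})"
            )
        local = {}
        for a in block.atoms:
            local[a["name"]] = offset
            mol.atoms.append(
                Atom(
                    name=a["name"],
                    resid=resid,
                    resname=resname,
                    type=a["type"],
                    charge=a["charge"],
                    mass=a["mass"],
                )
            )
            mol.graph.add_node(offset)
            offset += 1
        for directive, terms in block.interactions.items():
            for term in terms:
                atoms = tuple(local[nm] for nm in term.atoms)
                mol.add_interaction(
                    directive,
                    Interaction(atoms, term.func, term.params,
                                meta={"source": f"block:{resname}"}),
                    replace=False,
                )
                if directive in EDGE_DIRECTIVES:
                    mol.graph.add_edge(*atoms)
    return mol


# ---------------------------------------------------------------------------
# Step 2: residue-level subgraph isomorphism
# ---------------------------------------------------------------------------

def _node_match(graph_attrs, pattern_attrs):
    for key, want in pattern_attrs.items():
        if key == "resname":
            if want != WILDCARD and graph_attrs.get("resname") != want:
                return False
        elif graph_attrs.get(key) != want:
            return False
    return True


def _edge_match(graph_attrs, pattern_attrs):
    return all(graph_attrs.get(k) == v for k, v in pattern_attrs.items())


def match_link(graph, link):
    """All induced embeddings of ``link.pattern`` into ``graph``.

    Returns a sorted list of dicts ``offset -> graph node``.  Matches that
    cover the same set of graph nodes (pattern automorphisms, e.g. the two
    orientations of a symmetric bond link) are reported once, keeping the
    orientation whose mapped node tuple (in offset order) is smallest.
    """
    matcher = nx_iso.GraphMatcher(
        graph, link.pattern, node_match=_node_match, edge_match=_edge_match
    )
    offs = link.offsets()
    best = {}
    for mapping in matcher.subgraph_isomorphisms_iter():
        # networkx yields graph-node -> pattern-node; invert
        inv = {poff: gnode for gnode, poff in mapping.items()}
        key = frozenset(inv.values())
        tup = tuple(inv[o] for o in offs)
        if key not in best or tup < best[key]:
            best[key] = tup
    return [dict(zip(offs, tup)) for tup in sorted(best.values())]


# ---------------------------------------------------------------------------
# Step 3: resolving matches to global atom indices
# ---------------------------------------------------------------------------

def _resolve(mol, residue_index, match, off, name, link):
    resid = match[off]
    atoms = residue_index.get(resid)
    if atoms is None or name not in atoms:
        raise InputError(
            f"link {link.name!r}: atom {name!r} not found in residue {resid}"
        )
    idx = atoms[name]
    if idx is None:
        raise InputError(
            f"link {link.name!r}: atom name {name!r} ambiguous in residue {resid}"
        )
    return idx


def apply_link(mol, link, match, node_to_resid=None, provenance=None):
    """Append one matched link's interactions and edges to ``mol``.

    ``match`` maps pattern offsets to residue-graph nodes; these are
    translated to resids through ``node_to_resid`` (identity when the
    residue-graph nodes already are 0-based resids).  Interactions landing
    on an atom tuple already covered by an earlier link are replaced (the
    later link wins).
    """
    if node_to_resid is not None:
        match = {off: node_to_resid[n] for off, n in match.items()}
    residue_index = mol.residue_atoms()
    meta = {"source": provenance or (f"link:{link.name}" if link.name else "link")}
    for directive, terms in link.interactions.items():
        for term in terms:
            atoms = tuple(
                _resolve(mol, residue_index, match, off, nm, link)
                for off, nm in term.atoms
            )
            mol.add_interaction(
                directive, Interaction(atoms, term.func, term.params, meta=dict(meta))
            )
            if directive in EDGE_DIRECTIVES:
                mol.graph.add_edge(*atoms)
    for (off_a, name_a), (off_b, name_b) in link.edges_to_add:
        a = _resolve(mol, residue_index, match, off_a, name_a, link)
        b = _resolve(mol, residue_index, match, off_b, name_b, link)
        mol.graph.add_edge(a, b)
    return mol


# ---------------------------------------------------------------------------
# the full pipeline
# ---------------------------------------------------------------------------

def gen_params(graph, library, name="MOL"):
    """Residue graph + library -> complete molecule topology.

    Links are applied in library (file) order; each physical site is
    visited once.  Emits a warning listing residue-graph edges across which
    no link introduced an interaction or edge.
    """
    library.validate()
    mol = build_disconnected(graph, library, name=name)
    nodes = sorted(graph.nodes)
    node_to_resid = {n: i for i, n in enumerate(nodes)}
    for link in library.links:
        for match in match_link(graph, link):
            apply_link(mol, link, match, node_to_resid=node_to_resid)
    # completeness: every residue-graph edge should be spanned
    resid_edges = {
        frozenset((mol.residue_of(a), mol.residue_of(b)))
        for a, b in mol.graph.edges
        if mol.residue_of(a) != mol.residue_of(b)
    }
    unlinked = [
        (u, v)
        for u, v in graph.edges
        if frozenset((node_to_resid[u], node_to_resid[v])) not in resid_edges
    ]
    if unlinked:
        warnings.warn(
            f"molecule {name!r}: no link applied across residue-graph edges "
            f"{sorted(unlinked)}",
            stacklevel=2,
        )
    mol.validate()
    return mol
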
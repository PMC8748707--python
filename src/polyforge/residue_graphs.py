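"""Residue graph construction.

A residue graph has one node per residue (attribute ``resname`` mandatory,
arbitrary extra attributes such as chirality or anomer tags allowed) and one
edge per inter-residue connection.  Sources: a compact sequence string
(``"PS:63|PEO:163"``), node-link JSON, an existing molecule topology, or a
random branched-polymer generator.
"""

from __future__ import annotations

import json

import networkx as nx
import numpy as np

from .errors import InputError


def parse_sequence(spec):
    """Linear polymer from a block-sequence string.

    ``"B:5"`` is a 5-residue homopolymer; blocks are concatenated with
    ``|``, e.g. ``"PS:63|PEO:163"`` gives 63 PS residues followed by 163
    PEO residues along one chain.
    """
    graph = nx.Graph()
    idx = 0
    for part in spec.split("|"):
        part = part.strip()
        if not part:
            raise InputError(f"empty block in sequence spec {spec!r}")
        resname, _, count = part.partition(":")
        resname = resname.strip()
        if not resname:
            raise InputError(f"empty resname in sequence spec {spec!r}")
        try:
            n = int(count)
        except ValueError:
            raise InputError(f"bad residue count in {part!r}") from None
        if n <= 0:
            raise InputError(f"residue count must be positive in {part!r}")
        for _ in range(n):
            graph.add_node(idx, resname=resname)
            if idx > 0:
                graph.add_edge(idx - 1, idx)
            idx += 1
    return graph


def graph_from_topology(mol):
    """Residue graph extracted from a molecule's bonded graph.

    One node per residue; an edge whenever any bond or constraint joins
    atoms of two distinct residues (parallel cross-residue bonds collapse
    to a single edge).  Isolated residues are kept.
    """
    graph = nx.Graph()
    for atom in mol.atoms:
        graph.add_node(atom.resid, resname=atom.resname)
    for a, b in mol.graph.edges:
        ra, rb = mol.residue_of(a), mol.residue_of(b)
        if ra != rb:
            graph.add_edge(ra, rb)
    return graph


def make_circular(graph):
    """Close a linear chain into a cycle (first and last resid joined)."""
    nodes = sorted(graph.nodes)
    if len(nodes) > 2:
        graph.add_edge(nodes[0], nodes[-1])
    return graph


def random_branched_graph(n_backbone, branch_prob, max_branch_len,
                          resname="GLC", seed=None):
    """Dextran-like random branched polymer.

    A backbone path of ``n_backbone`` residues; each backbone node
    independently sprouts one branch with probability ``branch_prob``,
    of length uniform in ``1..max_branch_len``.  Backbone edges carry
    ``linktype="main"``, branch edges ``linktype="branch"`` so that links
    can distinguish the two linkage chemistries (alpha-1,6 vs alpha-1,3
    style connections between otherwise identical residues).
    """
    if not 0.0 <= branch_prob <= 1.0:
        raise InputError("branch_prob must be in [0, 1]")
    if max_branch_len < 1:
        raise InputError("max_branch_len must be >= 1")
    if n_backbone < 1:
        raise InputError("n_backbone must be >= 1")
    rng = np.random.default_rng(seed)
    graph = nx.Graph()
    for i in range(n_backbone):
        graph.add_node(i, resname=resname)
        if i > 0:
            graph.add_edge(i - 1, i, linktype="main")
    nxt = n_backbone
    for i in range(n_backbone):
        if rng.random() < branch_prob:
            length = int(rng.integers(1, max_branch_len + 1))
            prev = i
            for k in range(length):
                graph.add_node(nxt, resname=resname)
                graph.add_edge(prev, nxt,
                               linktype="branch" if k == 0 else "main")
                prev = nxt
                nxt += 1
    return graph


# ---------------------------------------------------------------------------
# node-link JSON
# ---------------------------------------------------------------------------

def read_json_graph(path):
    """Residue graph from node-link JSON (``resname`` mandatory per node)."""
    with open(path) as handle:
        data = json.load(handle)
    try:
        graph = nx.node_link_graph(data, edges="edges")
    except Exception as exc:  # malformed structure
        raise InputError(f"{path}: not valid node-link JSON ({exc})") from exc
    validate_residue_graph(graph, origin=str(path))
    return graph


def write_json_graph(graph, path):
    data = nx.node_link_data(graph, edges="edges")
    with open(path, "w") as handle:
        json.dump(data, handle, indent=1, sort_keys=True)


def validate_residue_graph(graph, origin="residue graph"):
    for node, attrs in graph.nodes(data=True):
        if not attrs.get("resname"):
            raise InputError(f"{origin}: node {node!r} lacks a resname")
    if any(u == v for u, v in graph.edges):
        raise InputError(f"{origin}: self-loop present")
    return graph
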
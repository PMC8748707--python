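"""Template-based backmapping from super-CG beads to target resolution.

Every residue template is moved so its center of geometry sits on the
bead, rotated so that atoms bonded to neighboring residues point towards
those neighbors, and scaled towards the bead by a fudge factor (default
0.45) to leave room for the subsequent energy minimization in the user's
MD engine.  Residues are processed in breadth-first order, so connector
targets of already-backmapped neighbors use their target-resolution atom
positions; otherwise the neighbor's bead position is used.

The optimal rotation is the closed-form orthogonal-Procrustes solution on
the connector correspondence set (scipy ``Rotation.align_vectors``); with
zero connectors the identity is returned, and rank-deficient cases (a
single connector) resolve to the minimal-angle rotation, which fixes the
free roll axis deterministically.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
from scipy.spatial.transform import Rotation

from .errors import InputError
from .residue_graphs import graph_from_topology
from .walk_engine import minimum_image

DEFAULT_FUDGE = 0.45


def connector_map(mol):
    """Per-residue inter-residue bond attachments.

    Returns ``{resid: [(own atom index, neighbor resid, neighbor atom
    index), ...]}`` derived from the molecule's bonded graph; symmetric
    across each residue pair."""
    out = {resid: [] for resid in range(mol.n_residues())}
    for a, b in mol.graph.edges:
        ra, rb = mol.residue_of(a), mol.residue_of(b)
        if ra == rb:
            continue
        out[ra].append((a, rb, b))
        out[rb].append((b, ra, a))
    return out


def orient_template(offsets, targets):
    """Proper rotation R minimizing sum ||R a_i - b_i||^2 over connector
    offsets a_i and target directions b_i; identity for no connectors."""
    offsets = np.atleast_2d(np.asarray(offsets, dtype=float))
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if offsets.size == 0:
        return Rotation.identity()
    keep = (np.linalg.norm(offsets, axis=1) > 1e-12) \
        & (np.linalg.norm(targets, axis=1) > 1e-12)
    if not np.any(keep):
        return Rotation.identity()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        rotation, _rssd = Rotation.align_vectors(targets[keep], offsets[keep])
    return rotation


def place_residue(template, rotation, cg_position, fudge=DEFAULT_FUDGE):
    """Atom positions: bead + fudge * (R . template offset).

    The template is centered at its center of geometry, so the output
    center of geometry equals the bead position exactly and every
    intra-residue distance is the template distance times ``fudge``."""
    names = list(template.positions)
    offsets = template.array(names)
    offsets = offsets - offsets.mean(axis=0)
    placed = np.asarray(cg_position, dtype=float) \
        + fudge * rotation.apply(offsets)
    return dict(zip(names, placed))


def backmap_molecule(mol, templates, bead_positions, box, fudge=DEFAULT_FUDGE):
    """Target-resolution coordinates (atom-indexed array) of one molecule."""
    res_graph = graph_from_topology(mol)
    connectors = connector_map(mol)
    residue_atoms = mol.residue_atoms()
    coords = np.full((len(mol.atoms), 3), np.nan)
    root = min(res_graph.nodes)
    order = [root] + [v for _, v in nx.bfs_edges(res_graph, root)]
    done = set()
    for resid in order:
        resname = mol.atoms[next(iter(residue_atoms[resid].values()))].resname
        template = templates.get(resname)
        if template is None:
            raise InputError(f"no template for resname {resname!r}")
        bead = np.asarray(bead_positions[resid], dtype=float)
        offsets, targets = [], []
        centered = {
            name: pos - template.array().mean(axis=0)
            for name, pos in template.positions.items()
        }
        for own, nbr_res, nbr_atom in connectors[resid]:
            own_name = mol.atoms[own].name
            if own_name not in centered:
                raise InputError(
                    f"template {resname!r} lacks connector atom {own_name!r}"
                )
            if nbr_res in done:
                target_point = coords[nbr_atom]
            else:
                target_point = np.asarray(bead_positions[nbr_res], dtype=float)
            offsets.append(centered[own_name])
            targets.append(minimum_image(target_point, bead, box))
        rotation = orient_template(offsets, targets) if offsets \
            else Rotation.identity()
        placed = place_residue(template, rotation, bead, fudge=fudge)
        for name, idx in residue_atoms[resid].items():
            if idx is None:
                raise InputError(
                    f"residue {resid}: ambiguous atom name {name!r}"
                )
            coords[idx] = placed[name]
        done.add(resid)
    return coords


def backmap_system(system, top_model, templates, fudge=DEFAULT_FUDGE):
    """Backmap every molecule of a built system.

    ``system`` is the :class:`~polyforge.walk_engine.SystemCoordinates`
    produced by ``build_system``.  Returns ``(positions, meta)`` where
    ``meta`` carries per-atom resids/resnames/names ready for the
    coordinate writers."""
    all_pos = []
    resids, resnames, names = [], [], []
    mol_index = {name: top_model.molecules[name] for name, _ in
                 top_model.composition}
    resid_offset = 0
    for molname, beads in system.molecules:
        mol = mol_index[molname]
        coords = backmap_molecule(mol, templates, beads, system.box,
                                  fudge=fudge)
        all_pos.append(coords)
        for atom in mol.atoms:
            resids.append(resid_offset + atom.resid + 1)
            resnames.append(atom.resname)
            names.append(atom.name)
        resid_offset += mol.n_residues()
    positions = np.vstack(all_pos) if all_pos else np.empty((0, 3))
    meta = {"resids": resids, "resnames": resnames, "names": names}
    return positions, meta


def worst_clash(positions, box, same_residue=None, threshold=0.05):
    """Smallest nonbonded inter-residue atom distance below ``threshold``;
    returns (count below, minimum distance).  A post-placement sanity scan,
    not a physical check (minimization is the MD engine's job)."""
    from scipy.spatial import cKDTree

    pos = np.mod(np.asarray(positions, dtype=float), box)
    tree = cKDTree(np.clip(pos, 0, np.nextafter(box, 0)), boxsize=box)
    pairs = tree.query_pairs(threshold, output_type="ndarray")
    if same_residue is not None and len(pairs):
        res = np.asarray(same_residue)
        pairs = pairs[res[pairs[:, 0]] != res[pairs[:, 1]]]
    if len(pairs) == 0:
        return 0, np.inf
    d = np.linalg.norm(
        minimum_image(pos[pairs[:, 0]], pos[pairs[:, 1]], box), axis=1
    )
    return int(len(pairs)), float(d.min())
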
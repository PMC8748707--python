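"""File I/O: force-field libraries, GROMACS .itp/.top/.gro, PDB, build files.

Units follow the GROMACS convention: nm, kJ/mol, degrees for angles in
files.  Atom indices are 1-based in all GROMACS-dialect files and 0-based
internally; conversion happens only here.

Library dialect
---------------
Blocks use itp syntax with *atom names* in interaction lines::

    [ moleculetype ]
    VNL 1
    [ atoms ]
    1 C1 1 VNL C1 1 0.0 14.0
    [ bonds ]
    C1 C2 1 0.150 8000

A ``[ link ]`` header opens a link; its interaction atoms are written
``<offset>:<resname>:<atomname>`` where the offset is the relative residue
index (``*`` matches any resname)::

    [ link ]
    [ bonds ]
    0:VNL:C2 1:VNL:C1 1 0.150 8000

Optional link subsections: ``[ edges ]`` (extra target-resolution edges),
``[ pattern_edges ]`` (residue-level adjacency for branched patterns;
default is the chain of consecutive offsets), ``[ node_attrs ]``
(``offset key value`` match constraints such as chirality tags) and
``[ edge_attrs ]`` (``offset offset key value``, e.g. ``linktype branch``).
"""

from __future__ import annotations

import os
import re
import warnings

import networkx as nx
import numpy as np

from .errors import InputError, ParseError
from .topology_gen import (
    ARITY,
    Atom,
    Block,
    ForceFieldLibrary,
    Interaction,
    Link,
    MoleculeTopology,
)
from .walk_engine import (
    AxisSlab,
    BuildEntry,
    BuildSpec,
    DistanceRestraint,
    GeomConstraint,
    PersistenceSpec,
)

_SECTION_RE = re.compile(r"^\[\s*([A-Za-z_][A-Za-z_0-9]*)\s*\]$")

_BLOCK_DIRECTIVES = {"atoms", "bonds", "constraints", "angles", "dihedrals",
                     "impropers", "pairs", "exclusions"}
_LINK_DIRECTIVES = {"bonds", "constraints", "angles", "dihedrals", "impropers",
                    "edges", "pattern_edges", "node_attrs", "edge_attrs"}
_IMPROPER_DIHEDRAL_FUNCS = {2, 4}


def _lines(text, path):
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split(";", 1)[0].strip()
        if line:
            yield lineno, line


def _section(line):
    m = _SECTION_RE.match(line)
    return m.group(1).lower() if m else None


def _floats(tokens, path, lineno):
    try:
        return tuple(float(t) for t in tokens)
    except ValueError:
        raise ParseError(f"expected numbers, got {tokens}", path, lineno) from None


def _classify(directive, func):
    """Dihedral function types 2 and 4 are impropers."""
    if directive == "dihedrals" and func in _IMPROPER_DIHEDRAL_FUNCS:
        return "impropers"
    return directive


# ---------------------------------------------------------------------------
# force-field library
# ---------------------------------------------------------------------------

def parse_library(path):
    """Parse one library file, or all ``*.ff`` files of a directory."""
    if os.path.isdir(path):
        files = sorted(
            os.path.join(path, f) for f in os.listdir(path) if f.endswith(".ff")
        )
        if not files:
            raise InputError(f"no .ff files in {path}")
        lib = ForceFieldLibrary(name=os.path.basename(os.path.normpath(path)))
        for f in files:
            _parse_library_text(open(f).read(), f, lib)
        lib.validate()
        return lib
    if not os.path.exists(path):
        raise InputError(f"library path {path} does not exist")
    lib = ForceFieldLibrary(
        name=os.path.splitext(os.path.basename(path))[0]
    )
    _parse_library_text(open(path).read(), path, lib)
    lib.validate()
    return lib


def parse_library_text(text, name="forcefield"):
    lib = ForceFieldLibrary(name=name)
    _parse_library_text(text, f"<{name}>", lib)
    lib.validate()
    return lib


class _LinkBuilder:
    def __init__(self):
        self.interactions = {}
        self.edges = []
        self.pattern_edges = []
        self.node_attrs = {}
        self.edge_attrs = []
        self.resnames = {}

    def atom_ref(self, token, path, lineno):
        parts = token.split(":")
        if len(parts) != 3:
            raise ParseError(
                f"link atom must be offset:resname:atomname, got {token!r}",
                path, lineno,
            )
        try:
            off = int(parts[0])
        except ValueError:
            raise ParseError(f"bad offset in {token!r}", path, lineno) from None
        resname = parts[1]
        prev = self.resnames.setdefault(off, resname)
        if prev != resname:
            raise ParseError(
                f"offset {off} declared with both resname {prev!r} and "
                f"{resname!r}", path, lineno,
            )
        return off, parts[2]

    def build(self, name):
        pattern = nx.Graph()
        offsets = set(self.resnames) | set(self.node_attrs)
        for a, b in self.pattern_edges:
            offsets.update((a, b))
        for off in offsets:
            pattern.add_node(off, resname=self.resnames.get(off, "*"),
                             **self.node_attrs.get(off, {}))
        if self.pattern_edges:
            pattern.add_edges_from(self.pattern_edges)
        else:
            offs = sorted(offsets)
            pattern.add_edges_from(zip(offs, offs[1:]))
        for a, b, key, value in self.edge_attrs:
            if not pattern.has_edge(a, b):
                pattern.add_edge(a, b)
            pattern.edges[a, b][key] = value
        link = Link(pattern=pattern, interactions=self.interactions,
                    edges_to_add=self.edges, name=name)
        link.validate()
        return link


def _parse_library_text(text, path, lib):
    context = None  # None | "forcefield" | "block" | "link"
    directive = None
    block = None
    pending_block_header = False
    link_builder = None
    link_count = sum(1 for _ in lib.links)

    def finish_link():
        nonlocal link_builder, link_count
        if link_builder is not None:
            lib.links.append(link_builder.build(f"{lib.name}/link{link_count}"))
            link_count += 1
            link_builder = None

    for lineno, line in _lines(text, path):
        sec = _section(line)
        if sec is not None:
            if sec == "moleculetype":
                finish_link()
                context, pending_block_header, directive = "block", True, None
            elif sec == "link":
                finish_link()
                context, directive = "link", None
                link_builder = _LinkBuilder()
            elif sec == "forcefield":
                finish_link()
                context, directive = "forcefield", None
            elif context == "block" and sec in _BLOCK_DIRECTIVES:
                directive = sec
            elif context == "link" and sec in _LINK_DIRECTIVES:
                directive = sec
            else:
                raise ParseError(f"unexpected section [ {sec} ]", path, lineno)
            continue

        tokens = line.split()
        if context == "forcefield":
            if len(tokens) >= 2 and tokens[0] in ("name", "version"):
                setattr(lib, tokens[0], tokens[1])
            else:
                raise ParseError(f"bad forcefield line {line!r}", path, lineno)
        elif context == "block":
            if pending_block_header:
                if len(tokens) != 2:
                    raise ParseError(
                        "moleculetype header must be 'name nrexcl'", path, lineno
                    )
                resname = tokens[0]
                if resname in lib.blocks:
                    raise ParseError(
                        f"duplicate block {resname!r}", path, lineno
                    )
                block = Block(resname=resname, atoms=[])
                lib.blocks[resname] = block
                pending_block_header = False
                continue
            if directive == "atoms":
                if len(tokens) < 8:
                    raise ParseError(
                        "atom line needs: nr type resnr resname name cgnr "
                        "charge mass", path, lineno,
                    )
                charge, mass = _floats(tokens[6:8], path, lineno)
                block.atoms.append(
                    {"name": tokens[4], "type": tokens[1],
                     "charge": charge, "mass": mass}
                )
            elif directive in _BLOCK_DIRECTIVES:
                arity = ARITY[directive]
                if len(tokens) < arity + 1:
                    raise ParseError(
                        f"{directive} line too short", path, lineno
                    )
                names = tuple(tokens[:arity])
                func = int(tokens[arity])
                params = _floats(tokens[arity + 1:], path, lineno)
                dest = _classify(directive, func)
                block.interactions.setdefault(dest, []).append(
                    Interaction(names, func, params)
                )
            else:
                raise ParseError(f"stray line {line!r}", path, lineno)
        elif context == "link":
            lb = link_builder
            if directive in ("bonds", "constraints", "angles", "dihedrals",
                             "impropers"):
                arity = ARITY[directive]
                if len(tokens) < arity + 1:
                    raise ParseError(f"{directive} line too short", path, lineno)
                atoms = tuple(
                    lb.atom_ref(t, path, lineno) for t in tokens[:arity]
                )
                func = int(tokens[arity])
                params = _floats(tokens[arity + 1:], path, lineno)
                dest = _classify(directive, func)
                lb.interactions.setdefault(dest, []).append(
                    Interaction(atoms, func, params)
                )
            elif directive == "edges":
                if len(tokens) != 2:
                    raise ParseError("edge line needs two atoms", path, lineno)
                lb.edges.append(tuple(
                    lb.atom_ref(t, path, lineno) for t in tokens
                ))
            elif directive == "pattern_edges":
                if len(tokens) != 2:
                    raise ParseError("pattern edge needs two offsets",
                                     path, lineno)
                lb.pattern_edges.append((int(tokens[0]), int(tokens[1])))
            elif directive == "node_attrs":
                if len(tokens) != 3:
                    raise ParseError("node_attrs line: offset key value",
                                     path, lineno)
                lb.node_attrs.setdefault(int(tokens[0]), {})[tokens[1]] = tokens[2]
            elif directive == "edge_attrs":
                if len(tokens) != 4:
                    raise ParseError("edge_attrs line: off off key value",
                                     path, lineno)
                lb.edge_attrs.append(
                    (int(tokens[0]), int(tokens[1]), tokens[2], tokens[3])
                )
            else:
                raise ParseError(f"stray line {line!r} in link", path, lineno)
        else:
            raise ParseError(f"content outside any section: {line!r}",
                             path, lineno)
    finish_link()
    return lib


def write_library(lib):
    """Library back to its file dialect (round-trips through the parser)."""
    out = ["[ forcefield ]", f"name {lib.name}"]
    if lib.version:
        out.append(f"version {lib.version}")
    for block in lib.blocks.values():
        out += ["", "[ moleculetype ]", f"{block.resname} 1", "", "[ atoms ]"]
        for i, a in enumerate(block.atoms, start=1):
            out.append(
                f"{i} {a['type']} 1 {block.resname} {a['name']} {i} "
                f"{_num(a['charge'])} {_num(a['mass'])}"
            )
        for directive, terms in block.interactions.items():
            fdir = "dihedrals" if directive == "impropers" else directive
            out += ["", f"[ {fdir} ]"]
            for t in terms:
                out.append(" ".join(list(t.atoms) + [str(t.func)]
                                    + [_num(p) for p in t.params]))
    for link in lib.links:
        out += ["", "[ link ]"]
        for off, attrs in sorted(link.pattern.nodes(data=True)):
            for key, val in attrs.items():
                if key != "resname":
                    out += ["[ node_attrs ]", f"{off} {key} {val}"]
        offs = sorted(link.pattern.nodes)
        default_edges = set(map(frozenset, zip(offs, offs[1:])))
        actual = {frozenset(e) for e in link.pattern.edges}
        if actual != default_edges:
            out.append("[ pattern_edges ]")
            for a, b in sorted(map(sorted, actual)):
                out.append(f"{a} {b}")
        for a, b, attrs in link.pattern.edges(data=True):
            for key, val in attrs.items():
                out += ["[ edge_attrs ]", f"{a} {b} {key} {val}"]

        def ref(atom):
            off, name = atom
            return f"{off}:{link.pattern.nodes[off].get('resname', '*')}:{name}"

        for directive, terms in link.interactions.items():
            fdir = "dihedrals" if directive == "impropers" else directive
            out += [f"[ {fdir} ]"]
            for t in terms:
                out.append(" ".join([ref(a) for a in t.atoms] + [str(t.func)]
                                    + [_num(p) for p in t.params]))
        if link.edges_to_add:
            out.append("[ edges ]")
            for a, b in link.edges_to_add:
                out.append(f"{ref(a)} {ref(b)}")
    return "\n".join(out) + "\n"


def _num(x):
    return f"{x:.10g}"


# ---------------------------------------------------------------------------
# GROMACS topology (.top / .itp)
# ---------------------------------------------------------------------------

_IGNORED_DIRECTIVES = {"defaults", "atomtypes", "bondtypes", "angletypes",
                       "dihedraltypes", "nonbond_params", "pairtypes",
                       "settles", "position_restraints"}


class TopologyFileModel:
    """Molecule definitions plus the system composition of a .top file."""

    def __init__(self, molecules=None, composition=None, includes=None,
                 title=""):
        self.molecules = molecules or {}
        self.composition = composition or []   # [(name, count)]
        self.includes = includes or []
        self.title = title

    def validate(self):
        for name, count in self.composition:
            if name not in self.molecules:
                raise InputError(
                    f"[ molecules ] names undefined moleculetype {name!r}"
                )
            if count < 1:
                raise InputError(f"molecule count for {name!r} must be >= 1")

    def total_atoms(self):
        return sum(len(self.molecules[n].atoms) * c
                   for n, c in self.composition)


def parse_topology(path):
    """Parse a GROMACS .top (with #include resolution) into a model."""
    model = TopologyFileModel()
    seen_molecules_directive = _parse_gmx_file(path, model)
    if not seen_molecules_directive:
        raise InputError(f"{path}: missing [ molecules ] section")
    model.validate()
    return model


def parse_itp(path):
    """Molecule definitions only (no [ system ]/[ molecules ] required)."""
    model = TopologyFileModel()
    _parse_gmx_file(path, model)
    return model.molecules


def parse_itp_text(text, origin="<itp>"):
    model = TopologyFileModel()
    _parse_gmx_text(text, origin, None, model)
    return model.molecules


def _parse_gmx_file(path, model):
    if not os.path.exists(path):
        raise InputError(f"topology path {path} does not exist")
    model.includes.append(str(path))
    text = open(path).read()
    return _parse_gmx_text(text, str(path), os.path.dirname(path), model)


def _parse_gmx_text(text, path, basedir, model):
    directive = None
    mol = None
    pending_header = False
    seen_molecules = False

    def finish_mol():
        nonlocal mol
        if mol is not None:
            _index_interactions(mol, path)
            mol = None

    for lineno, line in _lines(text, path):
        if line.startswith("#include"):
            m = re.match(r'#include\s+"([^"]+)"', line)
            if not m or basedir is None:
                raise ParseError("malformed #include", path, lineno)
            finish_mol()
            sub = os.path.join(basedir, m.group(1))
            seen_molecules |= _parse_gmx_file(sub, model)
            continue
        if line.startswith("#"):
            warnings.warn(f"{path}:{lineno}: preprocessor line skipped: "
                          f"{line!r}")
            continue
        sec = _section(line)
        if sec is not None:
            if sec == "moleculetype":
                finish_mol()
                directive, pending_header = "moleculetype", True
            elif sec in ("system", "molecules"):
                finish_mol()
                directive = sec
                seen_molecules |= sec == "molecules"
            elif sec in _BLOCK_DIRECTIVES:
                directive = sec
            elif sec in _IGNORED_DIRECTIVES:
                directive = "_skip"
            else:
                warnings.warn(f"{path}:{lineno}: unknown directive "
                              f"[ {sec} ] skipped")
                directive = "_skip"
            continue

        tokens = line.split()
        if directive == "_skip":
            continue
        if directive == "moleculetype":
            if not pending_header:
                raise ParseError("stray line after moleculetype header",
                                 path, lineno)
            if len(tokens) != 2:
                raise ParseError("moleculetype header must be 'name nrexcl'",
                                 path, lineno)
            name = tokens[0]
            if name in model.molecules:
                raise ParseError(f"duplicate moleculetype {name!r}",
                                 path, lineno)
            mol = MoleculeTopology(name=name, nrexcl=int(tokens[1]))
            mol._raw = {}
            model.molecules[name] = mol
            pending_header = False
        elif directive == "atoms":
            if mol is None:
                raise ParseError("[ atoms ] outside moleculetype", path, lineno)
            if len(tokens) < 6:
                raise ParseError("atom line too short", path, lineno)
            charge = float(tokens[6]) if len(tokens) > 6 else 0.0
            mass = float(tokens[7]) if len(tokens) > 7 else 0.0
            mol.atoms.append(Atom(name=tokens[4], resid=int(tokens[2]),
                                  resname=tokens[3], type=tokens[1],
                                  charge=charge, mass=mass))
        elif directive in _BLOCK_DIRECTIVES:
            if mol is None:
                raise ParseError(f"[ {directive} ] outside moleculetype",
                                 path, lineno)
            arity = ARITY[directive]
            if len(tokens) < arity + 1:
                raise ParseError(f"{directive} line too short", path, lineno)
            try:
                atoms = tuple(int(t) for t in tokens[:arity])
            except ValueError:
                raise ParseError("atom indices must be integers",
                                 path, lineno) from None
            func = int(tokens[arity])
            params = _floats(tokens[arity + 1:], path, lineno)
            if not all(np.isfinite(params)):
                raise ParseError("non-finite parameter", path, lineno)
            dest = _classify(directive, func)
            mol._raw.setdefault(dest, []).append(
                (atoms, func, params, lineno)
            )
        elif directive == "system":
            model.title = (model.title + " " + line).strip()
        elif directive == "molecules":
            if len(tokens) != 2:
                raise ParseError("molecules line must be 'name count'",
                                 path, lineno)
            model.composition.append((tokens[0], int(tokens[1])))
        else:
            raise ParseError(f"content outside any section: {line!r}",
                             path, lineno)
    finish_mol()
    return seen_molecules


def _index_interactions(mol, path):
    """Convert 1-based raw interaction records, renumber resids to 0-based
    contiguous, and build the bonded graph."""
    n = len(mol.atoms)
    resid_order = []
    for atom in mol.atoms:
        if atom.resid not in resid_order:
            resid_order.append(atom.resid)
    remap = {r: i for i, r in enumerate(resid_order)}
    for atom in mol.atoms:
        atom.resid = remap[atom.resid]
    mol.graph.add_nodes_from(range(n))
    raw = getattr(mol, "_raw", {})
    for directive, records in raw.items():
        for atoms, func, params, lineno in records:
            idx = tuple(a - 1 for a in atoms)
            for a in idx:
                if not 0 <= a < n:
                    raise ParseError(
                        f"molecule {mol.name!r}: atom index {a + 1} out of "
                        f"range in [ {directive} ]", path, lineno,
                    )
            mol.add_interaction(directive, Interaction(idx, func, params),
                                replace=False)
            if directive in ("bonds", "constraints"):
                mol.graph.add_edge(*idx)
    if hasattr(mol, "_raw"):
        del mol._raw


_ITP_ORDER = ("bonds", "pairs", "constraints", "exclusions", "angles",
              "dihedrals", "impropers")


def write_itp(mol):
    """Molecule topology to .itp text (1-based indices, impropers under
    [ dihedrals ]); the text re-parses to an equal topology."""
    if not mol.atoms:
        raise InputError(f"molecule {mol.name!r} has no atoms")
    out = ["[ moleculetype ]", f"{mol.name} {mol.nrexcl}", "", "[ atoms ]"]
    for i, a in enumerate(mol.atoms, start=1):
        if not a.type:
            raise InputError(
                f"molecule {mol.name!r}: atom {i} ({a.name}) has no type"
            )
        out.append(f"{i:6d} {a.type:>6s} {a.resid + 1:5d} {a.resname:>6s} "
                   f"{a.name:>6s} {i:5d} {_num(a.charge):>10s} "
                   f"{_num(a.mass):>10s}")
    for directive in _ITP_ORDER:
        terms = mol.interactions.get(directive, ())
        if not terms:
            continue
        header = "dihedrals" if directive == "impropers" else directive
        out += ["", f"[ {header} ]"]
        for t in terms:
            out.append(" ".join([f"{a + 1:5d}" for a in t.atoms]
                                + [f"{t.func:3d}"]
                                + [_num(p) for p in t.params]))
    for directive, terms in mol.interactions.items():
        if directive not in _ITP_ORDER and terms:
            warnings.warn(f"molecule {mol.name!r}: directive {directive!r} "
                          "not written to itp")
    return "\n".join(out) + "\n"


def write_top(model, path=None):
    """Self-contained .top text with all moleculetypes inline."""
    parts = [write_itp(model.molecules[name])
             for name in model.molecules]
    parts.append("[ system ]\n" + (model.title or "polyforge system") + "\n")
    parts.append("[ molecules ]\n"
                 + "".join(f"{n} {c}\n" for n, c in model.composition))
    text = "\n".join(parts)
    if path is not None:
        with open(path, "w") as handle:
            handle.write(text)
    return text


# ---------------------------------------------------------------------------
# coordinates: .gro and PDB
# ---------------------------------------------------------------------------

def write_gro(positions, box, resids=None, resnames=None, atomnames=None,
              title="polyforge", path=None):
    """Fixed-width .gro text (nm, 3 decimals, no velocities)."""
    positions = np.asarray(positions, dtype=float)
    box = np.asarray(box, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 3:
        raise InputError("positions must be (N, 3)")
    if not np.all(np.isfinite(positions)):
        raise InputError("non-finite coordinate in .gro output")
    if not (np.all(np.isfinite(box)) and np.all(box > 0)):
        raise InputError("box must be positive and finite")
    if np.any(positions >= 9999.9995) or np.any(positions <= -999.9995):
        raise InputError("coordinate exceeds .gro field width")
    n = len(positions)
    resids = resids if resids is not None else [1] * n
    resnames = resnames if resnames is not None else ["MOL"] * n
    atomnames = atomnames if atomnames is not None else ["X"] * n
    out = [title, f"{n:5d}"]
    for i in range(n):
        x, y, z = positions[i]
        out.append(f"{(resids[i] % 100000):5d}{resnames[i][:5]:<5s}"
                   f"{atomnames[i][:5]:>5s}{((i + 1) % 100000):5d}"
                   f"{x:8.3f}{y:8.3f}{z:8.3f}")
    out.append(f"{box[0]:10.5f}{box[1]:10.5f}{box[2]:10.5f}")
    text = "\n".join(out) + "\n"
    if path is not None:
        with open(path, "w") as handle:
            handle.write(text)
    return text


def read_gro(path_or_text):
    """Read a .gro file (or its text); returns (positions, box, meta)."""
    if "\n" in str(path_or_text):
        text = path_or_text
        origin = "<gro>"
    else:
        text = open(path_or_text).read()
        origin = str(path_or_text)
    lines = text.splitlines()
    if len(lines) < 3:
        raise ParseError("truncated .gro file", origin)
    try:
        n = int(lines[1])
    except ValueError:
        raise ParseError("bad atom count line", origin, 2) from None
    if len(lines) < n + 3:
        raise ParseError(f"expected {n} atom lines", origin)
    positions = np.empty((n, 3))
    resids, resnames, names = [], [], []
    for i in range(n):
        line = lines[2 + i]
        try:
            resids.append(int(line[0:5]))
            resnames.append(line[5:10].strip())
            names.append(line[10:15].strip())
            positions[i] = [float(line[20:28]), float(line[28:36]),
                            float(line[36:44])]
        except ValueError:
            raise ParseError("malformed atom record", origin, 3 + i) from None
    box = np.array([float(t) for t in lines[2 + n].split()[:3]])
    if not np.all(np.isfinite(positions)):
        raise ParseError("non-finite coordinate", origin)
    meta = {"resids": resids, "resnames": resnames, "names": names}
    return positions, box, meta


def write_pdb(positions, box=None, resids=None, resnames=None,
              atomnames=None, path=None):
    """Minimal PDB text (ATOM records; nm converted to Angstrom)."""
    positions = np.asarray(positions, dtype=float) * 10.0  # nm -> A
    if not np.all(np.isfinite(positions)):
        raise InputError("non-finite coordinate in PDB output")
    if np.any(np.abs(positions) >= 9999.999):
        raise InputError("coordinate exceeds PDB field width")
    n = len(positions)
    resids = resids if resids is not None else [1] * n
    resnames = resnames if resnames is not None else ["MOL"] * n
    atomnames = atomnames if atomnames is not None else ["X"] * n
    out = []
    if box is not None:
        b = np.asarray(box, dtype=float) * 10.0
        out.append(f"CRYST1{b[0]:9.3f}{b[1]:9.3f}{b[2]:9.3f}"
                   f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1")
    for i in range(n):
        x, y, z = positions[i]
        out.append(f"ATOM  {(i + 1) % 100000:5d} {atomnames[i][:4]:<4s}"
                   f"{resnames[i][:4]:>4s} {(resids[i] % 10000):4d}    "
                   f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}")
    out.append("END")
    text = "\n".join(out) + "\n"
    if path is not None:
        with open(path, "w") as handle:
            handle.write(text)
    return text


def read_pdb(path):
    """ATOM/HETATM records only; returns (positions nm, meta)."""
    positions, resids, resnames, names = [], [], [], []
    for line in open(path):
        if line.startswith(("ATOM", "HETATM")):
            names.append(line[12:16].strip())
            resnames.append(line[17:21].strip())
            resids.append(int(line[22:26]))
            positions.append([float(line[30:38]), float(line[38:46]),
                              float(line[46:54])])
    return np.asarray(positions) / 10.0, {
        "resids": resids, "resnames": resnames, "names": names,
    }


# ---------------------------------------------------------------------------
# build file
# ---------------------------------------------------------------------------

def parse_build_file(path, known_molecules=None):
    """Parse the build-file dialect into a :class:`BuildSpec`.

    ``[ system ]`` holds global keys (box, grid, fmax, backtrack,
    max_attempts, max_restarts); every ``[ molecule ]`` section attaches
    constraints to a molecule name and optional instance index range::

        [ molecule ]
        name DNA
        step_length 0.63
        restraint 0 99 0.5 0.1        ; node node target tol
        persistence 3.2 0 99          ; l_p first-node last-node
        sphere inside 5 5 5 4.0       ; cx cy cz r
        rectangle outside 0 2 0 2 0 2 ; x0 x1 y0 y1 z0 z1
        cylinder inside 5 5 2.0 0 10  ; cx cy r z0 z1
        axis x 0 12                   ; slab along one axis
        start 5 5 5
    """
    text = open(path).read() if os.path.exists(str(path)) else None
    if text is None:
        raise InputError(f"build file {path} does not exist")
    spec = BuildSpec()
    entry = None
    section = None
    for lineno, line in _lines(text, path):
        sec = _section(line)
        if sec is not None:
            if sec == "system":
                section, entry = "system", None
            elif sec == "molecule":
                section = "molecule"
                entry = BuildEntry(molname=None)
                spec.entries.append(entry)
            else:
                raise ParseError(f"unknown section [ {sec} ]", path, lineno)
            continue
        tokens = line.split()
        key = tokens[0].lower()
        args = tokens[1:]
        try:
            if section == "system":
                _system_key(spec, key, args)
            elif section == "molecule":
                _molecule_key(entry, key, args)
            else:
                raise InputError(f"line outside any section: {line!r}")
        except InputError:
            raise
        except Exception as exc:
            raise ParseError(f"bad {key} line ({exc})", path, lineno) from exc
    for entry in spec.entries:
        if entry.molname is None:
            raise InputError(f"{path}: [ molecule ] section without a name")
        if known_molecules is not None and entry.molname not in known_molecules:
            raise InputError(
                f"{path}: build constraints on unknown molecule "
                f"{entry.molname!r}"
            )
    spec.validate()
    return spec


def _system_key(spec, key, args):
    if key == "box":
        spec.box = np.array([float(a) for a in args])
        if len(spec.box) != 3 or np.any(spec.box <= 0):
            raise InputError("box needs three positive lengths")
    elif key == "grid":
        spec.grid_spacing = float(args[0])
    elif key == "fmax":
        spec.fmax = float(args[0])
    elif key == "backtrack":
        spec.backtrack = int(args[0])
    elif key == "max_attempts":
        spec.max_attempts = int(args[0])
    elif key == "max_restarts":
        spec.max_restarts = int(args[0])
    elif key == "step_factor":
        spec.step_factor = float(args[0])
    else:
        raise InputError(f"unknown system key {key!r}")


def _molecule_key(entry, key, args):
    if key == "name":
        entry.molname = args[0]
    elif key == "indices":
        entry.first, entry.last = int(args[0]), int(args[1])
    elif key == "step_length":
        entry.step_length = float(args[0])
        if entry.step_length <= 0:
            raise InputError("step_length must be positive")
    elif key == "start":
        entry.start = np.array([float(a) for a in args[:3]])
    elif key == "restraint":
        target, tol = float(args[2]), float(args[3])
        if target < 0 or tol < 0:
            raise InputError("restraint target and tolerance must be >= 0")
        entry.restraints.append(
            DistanceRestraint(int(args[0]), int(args[1]), target, tol)
        )
    elif key == "persistence":
        lp = float(args[0])
        if lp <= 0:
            raise InputError("persistence length must be positive")
        entry.persistence.append(
            PersistenceSpec(lp, int(args[1]), int(args[2]))
        )
    elif key in ("sphere", "cylinder", "rectangle"):
        inside = args[0].lower()
        if inside not in ("inside", "outside"):
            raise InputError("constraint must be 'inside' or 'outside'")
        params = tuple(float(a) for a in args[1:])
        want = {"sphere": 4, "cylinder": 5, "rectangle": 6}[key]
        if len(params) != want:
            raise InputError(f"{key} needs {want} numbers")
        if key == "sphere" and params[3] <= 0:
            raise InputError("sphere radius must be positive")
        if key == "cylinder" and params[2] <= 0:
            raise InputError("cylinder radius must be positive")
        entry.geometry.append(
            GeomConstraint(key, inside == "inside", params)
        )
    elif key == "axis":
        axis = {"x": 0, "y": 1, "z": 2}[args[0].lower()]
        entry.dimension.append(AxisSlab(axis, float(args[1]), float(args[2])))
    else:
        raise InputError(f"unknown molecule key {key!r}")
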
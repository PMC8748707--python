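"""Bundled toy force fields and reproducible system recipes.

Three miniature libraries make the whole pipeline testable without any
external parameter files:

* ``bead_spring`` — one-bead residue ``B`` with harmonic bond and angle
  links; the generic coarse-grained homopolymer.
* ``vinyl3`` — three-atom vinyl-like residue (backbone pair C1-C2 plus a
  side atom S1) with an inter-residue bond/angle and a signed improper
  across the junction for chirality handling.
* ``nucleotide1`` — one-bead thymine-nucleotide surrogate for ssDNA
  builds: 0.63 nm step per base, bead radius 0.43 nm from the molecular
  volume of a nucleotide (~0.33 nm^3).

``FixtureSpec`` captures a complete build recipe (library, residue graph,
box, constraints, seed); the same spec always materializes to the same
system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .io_formats import TopologyFileModel, parse_library_text
from .residue_graphs import make_circular, parse_sequence
from .templates import build_supercg, make_templates
from .topology_gen import gen_params
from .walk_engine import (
    BuildEntry,
    BuildSpec,
    DistanceRestraint,
    PersistenceSpec,
    build_system,
)

_BEAD_SPRING = """\
[ forcefield ]
name bead_spring

[ moleculetype ]
B 1

[ atoms ]
1 BT 1 B B1 1 0.0 72.0

[ link ]
[ bonds ]
0:B:B1 1:B:B1 1 0.47 1250.0

[ link ]
[ angles ]
-1:B:B1 0:B:B1 1:B:B1 1 130.0 50.0
"""

_VINYL3 = """\
[ forcefield ]
name vinyl3

[ moleculetype ]
VNL 1

[ atoms ]
1 C 1 VNL C1 1 0.0 13.0
2 C 1 VNL C2 2 0.0 14.0
3 CH3 1 VNL S1 3 0.0 15.0

[ bonds ]
C1 C2 1 0.15 8000.0
C1 S1 1 0.15 8000.0

[ angles ]
C2 C1 S1 1 109.47 100.0

[ link ]
[ bonds ]
0:VNL:C2 1:VNL:C1 1 0.15 8000.0
[ angles ]
0:VNL:C1 0:VNL:C2 1:VNL:C1 1 120.0 80.0
[ impropers ]
0:VNL:C1 0:VNL:C2 0:VNL:S1 1:VNL:C1 2 35.0 100.0
"""

_NUCLEOTIDE1 = """\
[ forcefield ]
name nucleotide1

[ moleculetype ]
T 1

[ atoms ]
1 TN 1 T B1 1 0.0 304.2

[ link ]
[ bonds ]
0:T:B1 1:T:B1 1 0.63 5000.0
"""

_LIBRARIES = {
    "bead_spring": _BEAD_SPRING,
    "vinyl3": _VINYL3,
    "nucleotide1": _NUCLEOTIDE1,
}

#: atomic/bead radius r_a per toy library (nm); the nucleotide surrogate
#: carries the whole residue volume in r_a because its block is one atom.
TOY_ATOM_RADIUS = {
    "bead_spring": 0.21,
    "vinyl3": 0.21,
    "nucleotide1": 0.43,
}

#: per-base step of the ssDNA surrogate, nm
SSDNA_STEP = 0.63
SSDNA_LENGTHS = (8, 16, 50, 65, 100)


def toy_library(kind):
    """One of the bundled libraries, parsed from its own file dialect."""
    try:
        text = _LIBRARIES[kind]
    except KeyError:
        raise InputError(
            f"unknown toy library {kind!r}; choose from "
            f"{sorted(_LIBRARIES)}"
        ) from None
    return parse_library_text(text, name=kind)


def toy_library_text(kind):
    if kind not in _LIBRARIES:
        raise InputError(f"unknown toy library {kind!r}")
    return _LIBRARIES[kind]


@dataclass
class FixtureSpec:
    """A reproducible build recipe: same spec -> identical system."""

    name: str
    library: str
    sequence: str
    n_chains: int
    box: np.ndarray
    seed: int
    step_length: float = None
    persistence: float = None       # l_p over the whole chain, nm
    circular: bool = False
    restraints: list = field(default_factory=list)
    fmax: float = 5.0e4
    molname: str = "MOL"

    def chain_length(self):
        return sum(int(p.split(":")[1]) for p in self.sequence.split("|"))


def materialize(fixture):
    """Build everything a fixture needs: returns a dict with the library,
    molecule topology, templates, super-CG model, topology model and
    build spec."""
    library = toy_library(fixture.library)
    graph = parse_sequence(fixture.sequence)
    if fixture.circular:
        graph = make_circular(graph)
    mol = gen_params(graph, library, name=fixture.molname)
    templates = make_templates(
        library, r_a=TOY_ATOM_RADIUS[fixture.library]
    )
    supercg = build_supercg(mol, templates)
    model = TopologyFileModel(
        molecules={fixture.molname: mol},
        composition=[(fixture.molname, fixture.n_chains)],
        title=fixture.name,
    )
    n = fixture.chain_length()
    entry = BuildEntry(
        molname=fixture.molname,
        step_length=fixture.step_length,
        restraints=list(fixture.restraints),
        persistence=(
            [PersistenceSpec(fixture.persistence, 0, n - 1)]
            if fixture.persistence else []
        ),
    )
    spec = BuildSpec(box=np.asarray(fixture.box, dtype=float),
                     fmax=fixture.fmax, entries=[entry])
    spec.validate()
    return {
        "library": library,
        "graph": graph,
        "molecule": mol,
        "templates": templates,
        "supercg": supercg,
        "top_model": model,
        "spec": spec,
    }


def build_fixture(fixture):
    """Materialize and run the random walk; returns (system, context)."""
    ctx = materialize(fixture)
    rng = np.random.default_rng(fixture.seed)
    system = build_system(ctx["top_model"], {fixture.molname: ctx["supercg"]},
                          ctx["spec"], rng)
    return system, ctx


# ---------------------------------------------------------------------------
# recipes
# ---------------------------------------------------------------------------

def melt_spec(n_chains, chain_length, volume_fraction=0.4, seed=0,
              library="bead_spring"):
    """Cubic melt box sized so the super-CG beads fill the requested
    volume fraction (must stay below random close packing, 0.64)."""
    if n_chains < 1:
        raise InputError("n_chains must be >= 1")
    if chain_length < 1:
        raise InputError("chain_length must be >= 1")
    if not 0.0 < volume_fraction < 0.64:
        raise InputError(
            "volume fraction must be in (0, 0.64) for a buildable melt"
        )
    lib = toy_library(library)
    templates = make_templates(lib, r_a=TOY_ATOM_RADIUS[library])
    resname = next(iter(lib.blocks))
    rho = templates[resname].rho
    bead_volume = 4.0 / 3.0 * np.pi * rho ** 3
    total = n_chains * chain_length * bead_volume
    edge = float((total / volume_fraction) ** (1.0 / 3.0))
    return FixtureSpec(
        name=f"melt_{library}_{n_chains}x{chain_length}",
        library=library,
        sequence=f"{resname}:{chain_length}",
        n_chains=n_chains,
        box=np.array([edge, edge, edge]),
        seed=seed,
    )


def cyclization_spec(n_beads=20, target=0.5, tol=0.1, seed=0):
    """Single chain whose ends are restrained into contact (macrocycle)."""
    contour = 1.5 * 0.47 * n_beads
    edge = max(5.0, contour)
    return FixtureSpec(
        name=f"cyclization_{n_beads}",
        library="bead_spring",
        sequence=f"B:{n_beads}",
        n_chains=1,
        box=np.array([edge, edge, edge]),
        seed=seed,
        step_length=0.47,
        restraints=[DistanceRestraint(0, n_beads - 1, target, tol)],
    )


def _dilute_box(n_bases):
    contour = SSDNA_STEP * max(1, n_bases - 1)
    edge = max(5.0, 1.2 * contour)
    return np.array([edge, edge, edge])


def ssdna_experiment_spec(l_p, lengths=SSDNA_LENGTHS, replicas=100, seed=0):
    """Build recipes for the ssDNA scaling experiment: one-bead poly-T
    chains at several lengths, ``replicas`` independent dilute builds per
    length, WLC persistence restraint over the whole chain."""
    if l_p <= 0:
        raise InputError("persistence length must be positive")
    seeds = np.random.SeedSequence(seed).generate_state(
        len(lengths) * replicas
    ) % (2 ** 31)
    specs = []
    k = 0
    for n in lengths:
        for _rep in range(replicas):
            specs.append(FixtureSpec(
                name=f"ssdna_lp{l_p}_n{n}_r{_rep}",
                library="nucleotide1",
                sequence=f"T:{n}",
                n_chains=1,
                box=_dilute_box(n),
                seed=int(seeds[k]),
                step_length=SSDNA_STEP,
                persistence=l_p,
                molname="DNA",
            ))
            k += 1
    return specs


def run_scaling_experiment(specs):
    """Build every fixture, measure per-chain R_G, and fit R_G = A N^v.

    Returns a dict with per-length mean radii of gyration, the fit, and
    the count of failed builds (rare dense-target replicas that exhaust
    their restarts are skipped)."""
    from .chain_models import chain_statistics, fit_power_law
    from .errors import BuildError

    by_length = {}
    failures = 0
    for fixture in specs:
        try:
            system, ctx = build_fixture(fixture)
        except BuildError:
            failures += 1
            continue
        graph = ctx["supercg"].graph
        _ee, rg = chain_statistics(graph, system.molecules[0][1], system.box)
        by_length.setdefault(fixture.chain_length(), []).append(rg)
    lengths = sorted(by_length)
    mean_rg = np.array([np.mean(by_length[n]) for n in lengths])
    fit = fit_power_law(np.array(lengths, dtype=float), mean_rg)
    return {
        "lengths": np.array(lengths),
        "mean_rg": mean_rg,
        "fit": fit,
        "failures": failures,
        "per_length": by_length,
    }


def ideal_chain_specs(lengths=(16, 32, 64, 128, 256, 512), replicas=60,
                      seed=0):
    """Control builds with stiffness and self-exclusion disabled: a pure
    random walk, which must reproduce the v = 1/2 scaling exponent."""
    seeds = np.random.SeedSequence(seed).generate_state(
        len(lengths) * replicas
    ) % (2 ** 31)
    specs = []
    k = 0
    for n in lengths:
        contour = 0.47 * (n - 1)
        edge = max(5.0, 1.2 * contour)
        for _rep in range(replicas):
            specs.append(FixtureSpec(
                name=f"ideal_n{n}_r{_rep}",
                library="bead_spring",
                sequence=f"B:{n}",
                n_chains=1,
                box=np.array([edge, edge, edge]),
                seed=int(seeds[k]),
                step_length=0.47,
                fmax=None,
            ))
            k += 1
    return specs
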
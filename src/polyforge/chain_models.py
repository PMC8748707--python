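"""Chain-statistics models and measurements used to validate builds.

Two ideal-chain theories predict the mean-square end-to-end distance of a
melt chain:

* hindered rotation model (HRM):
  ``<R^2> = n l^2 [(1 - cos t)/(1 + cos t)] [(1 + <cos p>)/(1 - <cos p>)]``
  with ``t`` the backbone valence angle and ``<cos p>`` the mean torsion
  cosine.  With the tetrahedral valence angle (cos t = -1/3) the angular
  factor is 2; with ``t = 90 deg`` and free torsions the ideal-chain
  ``n l^2`` is recovered.
* worm-like chain (WCM): ``<R^2> = 2 l_p L - 2 l_p^2 (1 - exp(-L/l_p))``.

The module also measures per-chain end-to-end distance and radius of
gyration from built coordinates (bond-walk unwrapping under periodic
boundaries) and fits the scaling law ``R_G = A N^v`` on log-log data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .errors import InputError
from .templates import radius_of_gyration
from .walk_engine import minimum_image, wlc_mean_square_ee  # noqa: F401

__all__ = [
    "ScalingFit", "hrm_mean_square_ee", "wlc_mean_square_ee",
    "fit_power_law", "unwrap_chain", "chain_statistics", "measure_chains",
]


def hrm_mean_square_ee(n, l, theta, mean_cos_phi):
    """Hindered-rotation-model mean-square end-to-end distance (nm^2).

    ``theta`` is the backbone valence angle in radians (tetrahedral
    109.47 deg gives an angular stiffness factor of 2); ``mean_cos_phi``
    the mean cosine of the torsion angle (0 = free rotation)."""
    if n < 1:
        raise InputError("n must be >= 1")
    if not -1.0 < mean_cos_phi < 1.0:
        raise InputError("<cos phi> must lie strictly inside (-1, 1)")
    cos_t = np.cos(theta)
    angular = (1.0 - cos_t) / (1.0 + cos_t)
    torsional = (1.0 + mean_cos_phi) / (1.0 - mean_cos_phi)
    return n * l * l * angular * torsional


@dataclass
class ScalingFit:
    """Result of fitting R_G = A N^v by least squares on log-log data."""

    prefactor: float          # A, nm
    exponent: float           # v
    prefactor_stderr: float
    exponent_stderr: float
    n_values: np.ndarray
    rg_values: np.ndarray

    def predict(self, n):
        return self.prefactor * np.power(n, self.exponent)


def fit_power_law(n_values, rg_values):
    """Least-squares fit of ``R_G = A N^v`` on log-transformed data."""
    n_values = np.asarray(n_values, dtype=float)
    rg_values = np.asarray(rg_values, dtype=float)
    if len(np.unique(n_values)) < 2:
        raise InputError("need at least two distinct N values")
    if np.any(rg_values <= 0) or np.any(n_values <= 0):
        raise InputError("N and R_G must be positive")
    result = stats.linregress(np.log(n_values), np.log(rg_values))
    prefactor = float(np.exp(result.intercept))
    return ScalingFit(
        prefactor=prefactor,
        exponent=float(result.slope),
        prefactor_stderr=float(prefactor * result.intercept_stderr),
        exponent_stderr=float(result.stderr),
        n_values=n_values,
        rg_values=rg_values,
    )


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

def unwrap_chain(graph, positions, box):
    """Unwrap a molecule built contiguously across periodic boundaries by
    walking its bonds: each bead is placed at the minimum image relative
    to its already-unwrapped neighbor."""
    root = min(graph.nodes)
    unwrapped = {root: np.asarray(positions[root], dtype=float)}
    for u, v in nx.bfs_edges(graph, root):
        unwrapped[v] = unwrapped[u] + minimum_image(positions[v],
                                                    positions[u], box)
    return unwrapped


def _backbone_endpoints(graph):
    """Leaves of the longest path (tree diameter by double BFS); ties and
    non-tree graphs fall back to lowest node ids."""
    nodes = sorted(graph.nodes)
    if len(nodes) == 1:
        return nodes[0], nodes[0]
    if nx.is_tree(graph):
        far = lambda src: max(
            nx.single_source_shortest_path_length(graph, src).items(),
            key=lambda kv: (kv[1], -_rank(nodes, kv[0])),
        )[0]
        a = far(nodes[0])
        b = far(a)
        return min(a, b), max(a, b)
    warnings.warn("cyclic molecule: endpoints chosen by lowest node id")
    return nodes[0], nodes[-1]


def _rank(nodes, node):
    return nodes.index(node)


def chain_statistics(graph, positions, box):
    """(end-to-end distance, radius of gyration) of one chain, measured on
    the unwrapped coordinates."""
    unwrapped = unwrap_chain(graph, positions, box)
    a, b = _backbone_endpoints(graph)
    ee = float(np.linalg.norm(unwrapped[a] - unwrapped[b]))
    rg = radius_of_gyration([unwrapped[n] for n in sorted(unwrapped)])
    return ee, rg


def measure_chains(system, supercg):
    """Per-chain statistics of a built system.

    Returns a list of dicts (molecule, end_to_end, rg), one per molecule
    instance, in build order."""
    rows = []
    for molname, beads in system.molecules:
        graph = getattr(supercg[molname], "graph", supercg[molname])
        ee, rg = chain_statistics(graph, beads, system.box)
        rows.append({"molecule": molname, "end_to_end": ee, "rg": rg})
    return rows


def write_chain_csv(rows, path):
    """Tidy CSV of per-chain statistics."""
    with open(path, "w") as handle:
        handle.write("molecule,end_to_end,rg\n")
        for row in rows:
            handle.write(f"{row['molecule']},{row['end_to_end']:.6f},"
                         f"{row['rg']:.6f}\n")
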
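"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: the matcher
enumerates all injective maps directly, and the periodic-distance oracle
enumerates all 27 periodic images.
"""

import itertools

import numpy as np


def _node_ok(graph_attrs, pattern_attrs):
    for key, want in pattern_attrs.items():
        if key == "resname":
            if want != "*" and graph_attrs.get("resname") != want:
                return False
        elif graph_attrs.get(key) != want:
            return False
    return True


def _edge_ok(graph_attrs, pattern_attrs):
    return all(graph_attrs.get(k) == v for k, v in pattern_attrs.items())


def brute_force_matches(graph, link):
    """All induced embeddings of the link pattern by exhaustive injective
    enumeration, deduplicated per covered node set (smallest mapped tuple
    in offset order wins)."""
    offs = sorted(link.pattern.nodes)
    best = {}
    for perm in itertools.permutations(graph.nodes, len(offs)):
        mapping = dict(zip(offs, perm))
        if not all(_node_ok(graph.nodes[mapping[o]], link.pattern.nodes[o])
                   for o in offs):
            continue
        ok = True
        for a, b in itertools.combinations(offs, 2):
            has_p = link.pattern.has_edge(a, b)
            has_g = graph.has_edge(mapping[a], mapping[b])
            if has_p != has_g:
                ok = False
                break
            if has_p and not _edge_ok(graph.edges[mapping[a], mapping[b]],
                                      link.pattern.edges[a, b]):
                ok = False
                break
        if not ok:
            continue
        key = frozenset(mapping.values())
        tup = tuple(mapping[o] for o in offs)
        if key not in best or tup < best[key]:
            best[key] = tup
    return [dict(zip(offs, tup)) for tup in sorted(best.values())]


def min_image_27(p, q, box):
    """Minimum-image displacement by enumerating all 27 periodic images."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    box = np.asarray(box, dtype=float)
    best = None
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            for sz in (-1, 0, 1):
                shift = np.array([sx, sy, sz]) * box
                d = p - (q + shift)
                if best is None or np.dot(d, d) < np.dot(best, best):
                    best = d
    return best
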
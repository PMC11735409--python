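"""Literal step-by-step re-implementation of the ordered pruning contract.

Kept deliberately naive — everything is recomputed from scratch at every
iteration — so it serves as an independent oracle for the production
pruning code. The deterministic contract shared by both implementations:

* rule 1 (once): delete every edge with Jaccard distance > jaccard_purge;
* components are processed first-come-first-served, initially ordered by
  their smallest node key; split products are ordered by smallest node key,
  undersized ones accepted, oversized ones appended to the queue;
* within an oversized component, repeatedly: (2) if two members share a
  plane, delete the highest-distance edge incident to any such member;
  (3) else delete the highest-distance edge if it exceeds the guard;
  (4) else if the component exceeds t_max, delete the edge at a uniform
  random index into the list of edges sorted by their (plane, label)
  endpoint pairs; (5) else accept;
* ties on distance break toward the lexicographically smallest sorted
  endpoint pair.
"""

from typing import List

import networkx as nx
import numpy as np


def _ekey(e):
    u, v = e
    return (u, v) if u <= v else (v, u)


def _worst(sub: nx.Graph, edges) -> tuple:
    ranked = sorted(edges, key=lambda e: (-sub.edges[e]["jaccard_distance"], _ekey(e)))
    return ranked[0] if ranked else None


def oracle_prune(component: nx.Graph, params, rng: np.random.Generator) -> List[frozenset]:
    g = component.copy()
    if g.number_of_nodes() <= params.t_typical:
        return [frozenset(g.nodes)]
    for e in list(g.edges):
        if g.edges[e]["jaccard_distance"] > params.jaccard_purge:
            g.remove_edge(*e)

    queue = sorted((frozenset(c) for c in nx.connected_components(g)), key=min)
    done: List[frozenset] = []
    while queue:
        nodes = queue.pop(0)
        if len(nodes) <= params.t_typical:
            done.append(nodes)
            continue
        sub = g.subgraph(nodes).copy()
        while True:
            planes = {}
            for n in sub.nodes:
                planes.setdefault(n[0], []).append(n)
            conflicted = [n for same in planes.values() if len(same) > 1 for n in same]
            if conflicted:
                candidates = {_ekey(e) for n in conflicted for e in sub.edges(n)}
                sub.remove_edge(*_worst(sub, candidates))
            else:
                worst = _worst(sub, [_ekey(e) for e in sub.edges])
                if worst is not None and sub.edges[worst]["jaccard_distance"] > params.low_distance_guard:
                    sub.remove_edge(*worst)
                elif sub.number_of_nodes() > params.t_max:
                    edges = sorted((_ekey(e) for e in sub.edges))
                    if not edges:
                        done.append(frozenset(sub.nodes))
                        break
                    sub.remove_edge(*edges[int(rng.integers(len(edges)))])
                else:
                    done.append(frozenset(sub.nodes))
                    break
            parts = sorted(nx.connected_components(sub), key=min)
            if len(parts) > 1:
                for p in parts:
                    if len(p) <= params.t_typical:
                        done.append(frozenset(p))
                    else:
                        queue.append(frozenset(p))
                break
    return done


def random_component(rng: np.random.Generator, max_nodes: int = 10) -> nx.Graph:
    """Random connected link-graph component with adjacent-plane edges and
    tie-prone Jaccard distances."""
    while True:
        n = int(rng.integers(2, max_nodes + 1))
        zs = sorted(int(rng.integers(0, 5)) for _ in range(n))
        labels = {}
        nodes = []
        for z in zs:
            labels[z] = labels.get(z, 0) + 1
            nodes.append((z, labels[z]))
        candidates = [
            (a, b) for i, a in enumerate(nodes) for b in nodes[i + 1 :] if abs(a[0] - b[0]) == 1
        ]
        if not candidates:
            continue
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for idx in rng.permutation(len(candidates)):
            a, b = candidates[idx]
            if rng.random() < 0.65:
                jd = float(rng.integers(0, 21)) / 20.0  # coarse grid => frequent ties
                g.add_edge(a, b, jaccard_distance=jd, overlap_fraction=1.0, intersection_px=1)
        if g.number_of_edges() and nx.is_connected(g):
            return g
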
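"""Brute-force oracle for ontology semantic-similarity arithmetic.

Independent of the package implementation: plain-dict adjacency, BFS
reachability, explicit loops for IC counting, Jaccard, MICA search and the
best-match profile score. Used to cross-check PhenotypeGraph on random DAGs.
"""

import math

import networkx as nx
import numpy as np

GLOBAL_ROOT = "PHENO:ROOT"


def merged_adjacency(hpo_edges, mpo_edges, bridges):
    """child->parents adjacency incl. bridge equivalences and global root."""
    adj = {}

    def add(a, b):
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set())

    h_children = set()
    h_nodes = set()
    for c, p in hpo_edges:
        add(c, p)
        h_nodes.update((c, p))
        h_children.add(c)
    m_children = set()
    m_nodes = set()
    for c, p in mpo_edges:
        add(c, p)
        m_nodes.update((c, p))
        m_children.add(c)
    for root in sorted((h_nodes - h_children) | (m_nodes - m_children)):
        add(root, GLOBAL_ROOT)
    for a, b in bridges:
        add(a, b)
        add(b, a)
    return adj


def bfs_ancestors(adj, term):
    seen = {term}
    frontier = [term]
    while frontier:
        nxt = []
        for t in frontier:
            for p in adj.get(t, ()):
                if p not in seen:
                    seen.add(p)
                    nxt.append(p)
        frontier = nxt
    return frozenset(seen)


def brute_ic(adj, model_terms):
    """Term -> IC by explicit subsumer counting over the model corpus."""
    n = len(model_terms)
    counts = {}
    for terms in model_terms.values():
        closure = set()
        for t in terms:
            closure |= bfs_ancestors(adj, t)
        for t in closure:
            counts[t] = counts.get(t, 0) + 1
    ic = {t: -math.log(c / n) for t, c in counts.items()}
    max_ic = max(ic.values(), default=0.0)
    out = dict(ic)
    for t in adj:
        if t not in out:
            out[t] = max_ic
    return out


def brute_similarity(adj, ic, t1, t2):
    a1 = bfs_ancestors(adj, t1)
    a2 = bfs_ancestors(adj, t2)
    common = a1 & a2
    if not common:
        return 0.0
    mica_ic = max(ic[t] for t in common)
    return math.sqrt(len(common) / len(a1 | a2) * mica_ic)


def brute_mica(adj, ic, t1, t2):
    common = bfs_ancestors(adj, t1) & bfs_ancestors(adj, t2)
    if not common:
        return None
    return max(sorted(common), key=lambda t: ic[t])


def brute_model_score(adj, ic, disease_terms, model_terms):
    d = sorted(disease_terms)
    m = sorted(model_terms)
    if not d or not m:
        return 0.0

    def stat(set_a, set_b):
        best = [max(brute_similarity(adj, ic, a, b) for b in set_b) for a in set_a]
        best += [max(brute_similarity(adj, ic, b, a) for a in set_a) for b in set_b]
        return (sum(best) / len(best) + max(best)) / 2.0

    norm = stat(d, d)
    if norm <= 0:
        return 0.0
    return min(1.0, stat(d, m) / norm)


def random_world(seed, max_terms=50):
    """Random two-species DAG + bridges + model corpus for oracle checks."""
    rng = np.random.default_rng(seed)
    n_h = int(rng.integers(5, max_terms // 2 + 1))
    n_m = int(rng.integers(5, max_terms // 2 + 1))

    def dag(prefix, n):
        g = nx.DiGraph()
        ids = [f"{prefix}{i}" for i in range(n)]
        g.add_node(ids[0])
        for i in range(1, n):
            n_parents = 1 + int(rng.random() < 0.3)
            parents = rng.choice(i, size=min(n_parents, i), replace=False)
            for p in parents:
                g.add_edge(ids[i], ids[int(p)])
        return g, ids

    hpo, h_ids = dag("H", n_h)
    mpo, m_ids = dag("M", n_m)
    n_bridges = int(rng.integers(0, min(n_h, n_m) // 2 + 1))
    h_pick = rng.choice(n_h - 1, size=min(n_bridges, n_h - 1), replace=False) + 1
    m_pick = rng.choice(n_m - 1, size=min(n_bridges, n_m - 1), replace=False) + 1
    bridges = [
        (h_ids[int(h)], m_ids[int(m)]) for h, m in zip(sorted(h_pick), sorted(m_pick))
    ]
    n_models = int(rng.integers(2, 9))
    model_terms = {}
    for i in range(n_models):
        k = int(rng.integers(1, 5))
        picks = rng.choice(n_m, size=min(k, n_m), replace=False)
        model_terms[f"MOD{i}"] = frozenset(m_ids[int(p)] for p in picks)
    return hpo, mpo, bridges, model_terms
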
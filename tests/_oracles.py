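"""Independent brute-force oracles used to validate the package's algorithms.

Everything here is deliberately naive: exhaustive enumeration and graph
walks, never sharing code paths with the implementation under test.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx


# ---------------------------------------------------------------------------
# Clustering: exhaustive adjacent-pair rule + chain union


def brute_force_clusters(genes: list[tuple[str, int, int]], window: int) -> list[list[str]]:
    """genes: (gene_id, start, end) on ONE sequence. Returns member-id lists.

    Tests every adjacent pair against the rule and unions linked pairs into
    chains via a graph, keeping components of size >= 2.
    """
    srt = sorted(genes, key=lambda g: (g[1], g[2], g[0]))
    G = nx.Graph()
    G.add_nodes_from(g[0] for g in srt)
    for (id1, s1, _), (id2, _, e2) in zip(srt, srt[1:]):
        if e2 - s1 < window:
            G.add_edge(id1, id2)
    comps = []
    for comp in nx.connected_components(G):
        if len(comp) >= 2:
            members = [g[0] for g in srt if g[0] in comp]
            comps.append(members)
    comps.sort(key=lambda c: c[0])
    return comps


# ---------------------------------------------------------------------------
# Alignment: exhaustive enumeration of all global alignments, affine gaps


def best_alignment_score(
    a: str, b: str, score_fn, gap_open: float, gap_extend: float
) -> float:
    """Maximum score over every global alignment of a and b.

    A gap run of length L costs gap_open + (L-1)*gap_extend; a gap opening
    immediately after a gap in the other sequence re-opens.
    """
    best = -math.inf

    def rec(i: int, j: int, prev: str, acc: float) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            if acc > best:
                best = acc
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", acc + score_fn(a[i], b[j]))
        if i < len(a):
            cost = gap_extend if prev == "X" else gap_open
            rec(i + 1, j, "X", acc - cost)
        if j < len(b):
            cost = gap_extend if prev == "Y" else gap_open
            rec(i, j + 1, "Y", acc - cost)

    rec(0, 0, "", 0.0)
    return best


def column_scan_similarity(aligned_a: str, aligned_b: str) -> tuple[int, float]:
    """(matched_length, similarity) by direct column counting; X never identical."""
    matched = sum(1 for x, y in zip(aligned_a, aligned_b) if x != "-" and y != "-")
    if matched == 0:
        return 0, 0.0
    ident = sum(
        1 for x, y in zip(aligned_a, aligned_b) if x != "-" and y != "-" and x == y and x != "X"
    )
    return matched, ident / matched


# ---------------------------------------------------------------------------
# Synteny: exhaustive monotone-chain enumeration + the same greedy loop


def _chain_score(chain, gap_penalty):
    s = sum(a.score for a in chain)
    for x, y in zip(chain, chain[1:]):
        s -= gap_penalty * ((abs(y.rank_a - x.rank_a) - 1) + (abs(y.rank_b - x.rank_b) - 1))
    return s


def exhaustive_best_chain(anchors, max_gap, gap_penalty):
    """Max-score monotone chain by full enumeration (ascending wins ties)."""
    best = None
    for direction, name in ((1, "same"), (-1, "inverted")):

        def extend(chain):
            nonlocal best
            score = _chain_score(chain, gap_penalty)
            if best is None or score > best[1]:
                best = (list(chain), score, name)
            last = chain[-1]
            for a2 in anchors:
                if any(a2 is c for c in chain):
                    continue
                da = a2.rank_a - last.rank_a
                db = direction * (a2.rank_b - last.rank_b)
                if da > 0 and db > 0 and da <= max_gap and abs(a2.rank_b - last.rank_b) <= max_gap:
                    extend(chain + [a2])

        for a in anchors:
            extend([a])
    return best


def exhaustive_blocks(anchors, min_block_size, max_gap, gap_penalty):
    """Same greedy extraction loop as the implementation, but with the
    exhaustive chain search doing the heavy lifting."""
    pool = list(anchors)
    blocks = []
    while pool:
        found = exhaustive_best_chain(pool, max_gap, gap_penalty)
        if found is None:
            break
        chain, _, orientation = found
        taken = {id(a) for a in chain}
        pool = [a for a in pool if id(a) not in taken]
        if len(chain) >= min_block_size:
            blocks.append((orientation, [(a.gene_a, a.gene_b) for a in chain]))
    return blocks


# ---------------------------------------------------------------------------
# Phylogeny: random additive trees and their path-length distances


def random_additive_tree(rng, n_taxa: int):
    """Random unrooted binary tree with edge lengths in [0.1, 1.0].

    Returns (distance matrix as dict-of-dict, labels, set of bipartitions).
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    G = nx.Graph()
    center = "i0"
    next_internal = 1
    for lab in labels[:3]:
        G.add_edge(center, lab, length=float(rng.uniform(0.1, 1.0)))
    for lab in labels[3:]:
        edges = list(G.edges)
        u, v = edges[rng.integers(0, len(edges))]
        mid = f"i{next_internal}"
        next_internal += 1
        w = G[u][v]["length"]
        G.remove_edge(u, v)
        split = float(rng.uniform(0.2, 0.8))
        G.add_edge(u, mid, length=w * split)
        G.add_edge(mid, v, length=w * (1.0 - split))
        G.add_edge(mid, lab, length=float(rng.uniform(0.1, 1.0)))
    dist = dict(nx.all_pairs_dijkstra_path_length(G, weight="length"))
    # mirror one triangle so float summation order cannot break symmetry
    D = {a: {} for a in labels}
    for i, a in enumerate(labels):
        D[a][a] = 0.0
        for b in labels[i + 1 :]:
            D[a][b] = D.setdefault(b, {})[a] = dist[a][b]
    ref = min(labels)
    bips = set()
    for u, v in list(G.edges):
        H = G.copy()
        H.remove_edge(u, v)
        side = frozenset(x for x in nx.node_connected_component(H, u) if x in set(labels))
        if len(side) < 2 or len(side) > n_taxa - 2:
            continue
        bips.add(side if ref not in side else frozenset(labels) - side)
    return D, labels, bips
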
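"""Collinear (synteny) block detection between two gene sets.

Anchors are high-scoring gene pairs carrying per-chromosome order ranks.
Blocks are maximal-scoring chains of anchors, strictly increasing in the
A-genome rank and strictly monotone (same or inverted direction) in the
B-genome rank, with a bounded rank gap between consecutive anchors. Blocks
are extracted greedily in descending chain-score order, each anchor
belonging to at most one block; chains shorter than the minimum block size
are dropped.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Sequence

from ._util import percent
from .models import Anchor, GeneModel, SimilarityRecord, SyntenyBlock, SyntenySummary

DEFAULT_MIN_BLOCK_SIZE = 5
DEFAULT_MAX_GAP = 25
DEFAULT_GAP_PENALTY = 1.0


def gene_ranks(genes: Sequence[GeneModel]) -> dict[str, tuple[str, int]]:
    """gene_id -> (seq_id, rank), ranks being 1-based start-order per sequence."""
    by_seq: dict[str, list[GeneModel]] = defaultdict(list)
    for g in genes:
        by_seq[g.seq_id].append(g)
    out: dict[str, tuple[str, int]] = {}
    for seq_id, gs in by_seq.items():
        gs.sort(key=lambda g: (g.start, g.end, g.gene_id))
        for rank, g in enumerate(gs, 1):
            out[g.gene_id] = (seq_id, rank)
    return out


def build_anchors(
    records: Sequence[SimilarityRecord],
    genes_a: Sequence[GeneModel],
    genes_b: Sequence[GeneModel],
    top_k: int = 5,
    score_floor: float | None = None,
) -> list[Anchor]:
    """Keep each A gene's ``top_k`` best-scoring partners in B as anchors.

    Ties at the k-th place are all kept. ``score_floor`` drops weak hits
    first (a stand-in for an alignment E-value cutoff).
    """
    ranks_a = gene_ranks(genes_a)
    ranks_b = gene_ranks(genes_b)
    by_a: dict[str, list[SimilarityRecord]] = defaultdict(list)
    for r in records:
        if score_floor is not None and r.score < score_floor:
            continue
        if r.gene_a in ranks_a and r.gene_b in ranks_b:
            by_a[r.gene_a].append(r)
    anchors: list[Anchor] = []
    for ga in sorted(by_a):
        hits = sorted(by_a[ga], key=lambda r: (-r.score, r.gene_b))
        if len(hits) > top_k:
            kth = hits[top_k - 1].score
            hits = [h for h in hits if h.score >= kth]
        for h in hits:
            seq_a, rank_a = ranks_a[h.gene_a]
            seq_b, rank_b = ranks_b[h.gene_b]
            anchors.append(Anchor(h.gene_a, h.gene_b, seq_a, seq_b, rank_a, rank_b, h.score))
    return anchors


def _anchor_key(a: Anchor) -> tuple:
    return (a.rank_a, a.rank_b, a.gene_a, a.gene_b)


def best_chain(
    anchors: Sequence[Anchor], max_gap: int, gap_penalty: float
) -> tuple[list[Anchor], float, str] | None:
    """Maximum-scoring monotone chain over the given anchors (exact DP).

    Both orientations are tried; the higher-scoring chain wins, the
    ascending orientation winning exact ties. Chain score is the sum of
    anchor scores minus ``gap_penalty`` per rank skipped on either side
    between consecutive anchors.
    """
    if not anchors:
        return None
    best = None
    for direction, name in ((1, "same"), (-1, "inverted")):
        srt = sorted(anchors, key=lambda a: (a.rank_a, direction * a.rank_b, a.gene_a, a.gene_b))
        n = len(srt)
        score = [a.score for a in srt]
        parent = [-1] * n
        for i in range(n):
            ai = srt[i]
            for j in range(i):
                aj = srt[j]
                da = ai.rank_a - aj.rank_a
                db = direction * (ai.rank_b - aj.rank_b)
                if da <= 0 or db <= 0 or da > max_gap or abs(ai.rank_b - aj.rank_b) > max_gap:
                    continue
                cand = score[j] + ai.score - gap_penalty * ((da - 1) + (db - 1))
                if cand > score[i]:
                    score[i] = cand
                    parent[i] = j
        end = max(range(n), key=lambda i: score[i])
        chain = []
        i = end
        while i != -1:
            chain.append(srt[i])
            i = parent[i]
        chain.reverse()
        if best is None or score[end] > best[1]:
            best = (chain, score[end], name)
    return best


def chain_blocks(
    anchors: Sequence[Anchor],
    min_block_size: int = DEFAULT_MIN_BLOCK_SIZE,
    max_gap: int = DEFAULT_MAX_GAP,
    gap_penalty: float = DEFAULT_GAP_PENALTY,
) -> list[SyntenyBlock]:
    """Extract non-overlapping blocks per (seq_a, seq_b) chromosome pair.

    Repeatedly removes the maximum-scoring chain from the remaining anchor
    pool; chains of at least ``min_block_size`` anchors become blocks,
    smaller ones are discarded with their anchors.
    """
    groups: dict[tuple[str, str], list[Anchor]] = defaultdict(list)
    for a in anchors:
        groups[(a.seq_a, a.seq_b)].append(a)
    blocks: list[SyntenyBlock] = []
    for (seq_a, seq_b) in sorted(groups):
        pool = list(groups[(seq_a, seq_b)])
        while pool:
            found = best_chain(pool, max_gap, gap_penalty)
            if found is None:
                break
            chain, _, orientation = found
            taken = {id(a) for a in chain}
            pool = [a for a in pool if id(a) not in taken]
            if len(chain) >= min_block_size:
                blocks.append(SyntenyBlock(seq_a, seq_b, chain, orientation))
    return blocks


def synteny_summary(
    blocks: Sequence[SyntenyBlock],
    genes_a_total: int,
    genes_b_total: int,
    dp: int = 1,
) -> SyntenySummary:
    """Block, pair and distinct-syntenic-gene counts with proportions."""
    n_pairs = sum(b.size for b in blocks)
    syn_a = {a.gene_a for b in blocks for a in b.pairs}
    syn_b = {a.gene_b for b in blocks for a in b.pairs}
    pa = percent(len(syn_a), genes_a_total, dp) if genes_a_total else 0.0
    pb = percent(len(syn_b), genes_b_total, dp) if genes_b_total else 0.0
    return SyntenySummary(len(blocks), n_pairs, len(syn_a), len(syn_b), pa, pb)


def syntenic_proportion(n_syntenic: int, total: int, dp: int = 0) -> float:
    """The syntenic-gene proportion arithmetic on bare counts."""
    return percent(n_syntenic, total, dp)


def write_collinearity(blocks: Sequence[SyntenyBlock], path) -> None:
    """MCScanX-like text output: block headers followed by gene pairs."""
    with open(path, "w") as fh:
        for i, b in enumerate(blocks, 1):
            fh.write(
                f"## block {i}\t{b.seq_a}\t{b.seq_b}\t{b.orientation}\tn_pairs={b.size}\n"
            )
            for a in b.pairs:
                fh.write(f"{a.gene_a}\t{a.gene_b}\t{a.score:.1f}\n")
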
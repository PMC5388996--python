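"""Bootstrap neighbor-joining phylogeny of TIR-containing NBS proteins.

Distances come from pairwise p-distances over a multiple alignment
(pairwise or complete gap deletion), optionally passed through the Kimura
protein correction d = -ln(1 - p - 0.2 p^2). Trees are built with the
Saitou-Nei neighbor-joining algorithm; node stability is assessed by
column-bootstrap replicates, supports being the percentage of replicate
trees containing each original bipartition.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .models import NBSRecord, NBSType

log = logging.getLogger(__name__)

#: Distance assigned to saturated pairs (p beyond the correction's domain).
SATURATION_CAP = 10.0

# p at which 1 - p - 0.2 p^2 reaches zero
_P_SATURATION = (math.sqrt(1.8) - 1.0) / 0.4


def select_tir_nbs(records: Sequence[NBSRecord]) -> list[NBSRecord]:
    """Records of the TIR clade: TN and TNL architectures."""
    return [r for r in records if r.nbs_type in (NBSType.TN, NBSType.TNL)]


def p_distance(aligned_a: str, aligned_b: str, deletion: str = "pairwise") -> float:
    """Proportion of differing residues over counted columns.

    With pairwise deletion only columns where both rows carry a residue
    are counted. (Complete deletion is a property of the whole alignment;
    for a single pair it coincides with pairwise deletion.)
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("rows must have equal length")
    if deletion not in {"pairwise", "complete"}:
        raise ValueError(f"unknown deletion mode: {deletion}")
    counted = 0
    diff = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == "-" or cb == "-":
            continue
        counted += 1
        if ca != cb:
            diff += 1
    if counted == 0:
        raise ValueError("no counted columns between rows")
    return diff / counted


def kimura_correct(p: float, cap: float = SATURATION_CAP) -> float:
    """Kimura's protein-distance correction d = -ln(1 - p - 0.2 p^2).

    Valid for p below ~0.854; saturated inputs are capped at ``cap`` with
    a log notice rather than returning infinity.
    """
    if p < 0.0 or p >= 1.0:
        raise ValueError(f"p-distance {p} outside [0, 1)")
    arg = 1.0 - p - 0.2 * p * p
    if arg <= 0.0:
        log.debug("p=%.4f beyond saturation bound %.4f; capped at %s", p, _P_SATURATION, cap)
        return cap
    return -math.log(arg)


def _encode_alignment(rows: Sequence[str]) -> np.ndarray:
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValueError("alignment rows must have equal length")
    A = np.empty((len(rows), ncol), dtype=np.int16)
    for i, r in enumerate(rows):
        A[i] = [(-1 if c == "-" else ord(c)) for c in r]
    return A


def distance_matrix(
    rows: Sequence[str],
    labels: Sequence[str],
    model: str = "kimura",
    deletion: str = "pairwise",
    allow_empty_pairs: bool = False,
) -> DistanceMatrix:
    """Pairwise distance matrix from an alignment.

    ``model`` is ``kimura`` (corrected) or ``p`` (raw p-distance). Pairs
    without counted columns raise, unless ``allow_empty_pairs`` assigns the
    saturation cap (used inside bootstrap resampling).
    """
    if model not in {"kimura", "p"}:
        raise ValueError(f"unknown distance model: {model}")
    A = _encode_alignment(rows)
    if deletion == "complete":
        keep = (A >= 0).all(axis=0)
        if not keep.any():
            raise ValueError("complete deletion removed every column")
        A = A[:, keep]
    n = len(rows)
    D = np.zeros((n, n))
    residue = A >= 0
    for i in range(n):
        for j in range(i + 1, n):
            valid = residue[i] & residue[j]
            m = int(valid.sum())
            if m == 0:
                if not allow_empty_pairs:
                    raise ValueError(f"no counted columns between {labels[i]} and {labels[j]}")
                d = SATURATION_CAP
            else:
                p = float(((A[i] != A[j]) & valid).sum()) / m
                d = kimura_correct(p) if model == "kimura" else p
            D[i, j] = D[j, i] = d
    return DistanceMatrix(D, ids=list(labels))


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted tree (trifurcating root).

    The pair minimizing the Q-criterion is joined each round, ties broken
    by lowest (i, j) in current matrix order (original label order, merged
    nodes appended). Negative branch lengths are clamped to zero.
    """
    labels = list(dm.ids)
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    D = dm.data.astype(float).copy()
    nodes = [TreeNode(name=lab) for lab in labels]
    while len(nodes) > 3:
        k = len(nodes)
        r = D.sum(axis=1)
        Q = (k - 2) * D - r[:, None] - r[None, :]
        iu = np.triu_indices(k, 1)
        flat = Q[iu]
        pos = int(np.argmin(flat))
        i, j = int(iu[0][pos]), int(iu[1][pos])
        d_ij = D[i, j]
        li = 0.5 * d_ij + (r[i] - r[j]) / (2.0 * (k - 2))
        lj = d_ij - li
        li, lj = _clamp(li), _clamp(lj)
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        new_row = 0.5 * (D[i] + D[j] - d_ij)
        keep = [x for x in range(k) if x not in (i, j)]
        D = np.vstack([D[keep][:, keep], new_row[keep][None, :]])
        D = np.hstack([D, np.append(new_row[keep], 0.0)[:, None]])
        nodes = [nodes[x] for x in keep] + [parent]
    # final trifurcation: three-point formulas are exact here
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    nodes[0].length = _clamp(0.5 * (d01 + d02 - d12))
    nodes[1].length = _clamp(0.5 * (d01 + d12 - d02))
    nodes[2].length = _clamp(0.5 * (d02 + d12 - d01))
    return TreeNode(children=nodes)


def _clamp(x: float) -> float:
    if x < 0.0:
        log.debug("negative branch length %.4g clamped to 0", x)
        return 0.0
    return float(x)


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of an (unrooted) tree, normalized.

    Each internal edge splits the leaves in two; the side not containing
    the lexicographically smallest leaf represents the bipartition.
    """
    tips = frozenset(t.name for t in tree.tips())
    ref = min(tips)
    out = set()
    for node in tree.non_tips():
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(tips) - 2:
            continue
        out.add(side if ref not in side else tips - side)
    return out


def bootstrap_nj(
    rows: Sequence[str],
    labels: Sequence[str],
    n_replicates: int = 1000,
    seed: int | None = None,
    model: str = "kimura",
) -> tuple[TreeNode, dict[frozenset, int]]:
    """NJ tree with column-bootstrap supports on internal nodes.

    Columns are resampled with replacement per replicate; support of an
    original bipartition is the percentage of replicate trees containing
    it, attached as the internal node name (integer percent).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if len(rows) < 4:
        raise ValueError("bootstrap needs at least 4 rows")
    tree = nj_tree(distance_matrix(rows, labels, model=model))
    orig = bipartitions(tree)
    counts = {b: 0 for b in orig}
    rng = np.random.default_rng(seed)
    ncol = len(rows[0])
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, ncol)
        rep_rows = ["".join(r[c] for c in cols) for r in rows]
        try:
            rep_dm = distance_matrix(rep_rows, labels, model=model, allow_empty_pairs=True)
        except ValueError:
            continue
        rep_bip = bipartitions(nj_tree(rep_dm))
        for b in orig:
            if b in rep_bip:
                counts[b] += 1
    supports = {b: round(100.0 * c / n_replicates) for b, c in counts.items()}
    tips = frozenset(labels)
    ref = min(tips)
    for node in tree.non_tips():
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(tips) - 2:
            continue
        key = side if ref not in side else tips - side
        node.name = str(supports[key])
    return tree, supports


def star_alignment(seqs: Sequence[str], params=None) -> list[str]:
    """Reference-star multiple alignment via pairwise global alignments.

    Every sequence is aligned to the longest one and the pairwise gaps are
    projected into common columns. This is a deliberately simple MSA used
    for synthetic data, not a progressive aligner.
    """
    from .similarity import global_align

    if len(seqs) < 2:
        return list(seqs)
    ref_idx = max(range(len(seqs)), key=lambda i: (len(seqs[i]), -i))
    ref = seqs[ref_idx]
    L = len(ref)
    # per sequence: residue (or gap) at each ref slot + insertions before each slot
    slot_res: list[list[str]] = []
    slot_ins: list[list[str]] = []
    for s in seqs:
        if s is ref:
            slot_res.append(list(ref))
            slot_ins.append([""] * (L + 1))
            continue
        ra, sa, _ = global_align(ref, s, params)
        res = []
        ins = [""] * (L + 1)
        k = 0  # next ref slot
        for cr, cs in zip(ra, sa):
            if cr == "-":
                ins[k] += cs
            else:
                res.append(cs)
                k += 1
        slot_res.append(res)
        slot_ins.append(ins)
    ins_max = [max(ins[k] and len(ins[k]) or 0 for ins in slot_ins) for k in range(L + 1)]
    out = []
    for res, ins in zip(slot_res, slot_ins):
        parts = []
        for k in range(L):
            parts.append(ins[k].ljust(ins_max[k], "-"))
            parts.append(res[k])
        parts.append(ins[L].ljust(ins_max[L], "-"))
        out.append("".join(parts))
    return out
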
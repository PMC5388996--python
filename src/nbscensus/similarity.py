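"""Pairwise global protein similarity and the multi-threshold census.

Distances are identity-based: over the *matched length* (alignment columns
with a residue in both rows), distance = 1 - identical/matched and
similarity = 1 - distance. All threshold comparisons are strict, mirroring
the "more than"/"greater than"/"less than" census definitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from ._nw import nw_affine
from ._util import percent
from .models import AA_ALPHABET_X, GeneModel, SimilarityRecord, ThresholdCensus

DEFAULT_THRESHOLDS = (90, 80, 70, 60, 50, 40, 30)
DEFAULT_MIN_MATCHED = 200


@dataclass(frozen=True)
class AlignParams:
    """Scoring configuration for global alignment.

    Defaults are the classic protein settings (BLOSUM62, gap open 10,
    gap extend 0.5). ``x_neutral`` forces the unknown residue X to score 0
    against everything.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    x_neutral: bool = True


@lru_cache(maxsize=4)
def _scoring(params: AlignParams) -> tuple[str, np.ndarray]:
    mat = substitution_matrices.load(params.matrix_name)
    alphabet = str(mat.alphabet)
    S = np.asarray(mat, dtype=np.float64)
    if params.x_neutral and "X" in alphabet:
        xi = alphabet.index("X")
        S[xi, :] = 0.0
        S[:, xi] = 0.0
    return alphabet, S


def _encode(seq: str, alphabet: str) -> np.ndarray:
    idx = np.empty(len(seq), dtype=np.int64)
    for i, c in enumerate(seq):
        if c not in AA_ALPHABET_X:
            raise ValueError(f"non-amino-acid character {c!r} in sequence")
        idx[i] = alphabet.index(c)
    return idx


def global_align(
    seq_a: str, seq_b: str, params: AlignParams | None = None
) -> tuple[str, str, float]:
    """Optimal global alignment of two proteins; returns aligned strings and score."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    params = params or AlignParams()
    alphabet, S = _scoring(params)
    a = _encode(seq_a, alphabet)
    b = _encode(seq_b, alphabet)
    score, ops = nw_affine(a, b, S, float(params.gap_open), float(params.gap_extend))
    ra, rb = [], []
    i = j = 0
    for op in ops:
        if op == 0:
            ra.append(seq_a[i])
            rb.append(seq_b[j])
            i += 1
            j += 1
        elif op == 1:
            ra.append(seq_a[i])
            rb.append("-")
            i += 1
        else:
            ra.append("-")
            rb.append(seq_b[j])
            j += 1
    return "".join(ra), "".join(rb), float(score)


def pairwise_similarity(
    aligned_a: str,
    aligned_b: str,
    gene_a: str = "a",
    gene_b: str = "b",
    score: float = 0.0,
    kimura: bool = False,
) -> SimilarityRecord:
    """Identity-based similarity over matched columns of an alignment.

    Columns where either row is a gap are excluded from the matched length;
    an X residue is never counted as identical. With ``kimura=True`` the
    raw p-distance is passed through the Kimura protein correction before
    similarity is derived.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned strings must have equal length")
    matched = 0
    ident = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == "-" or cb == "-":
            continue
        matched += 1
        if ca == cb and ca != "X":
            ident += 1
    if matched == 0:
        return SimilarityRecord(gene_a, gene_b, 0, 1.0, 0.0, score, usable=False)
    p = 1.0 - ident / matched
    if kimura:
        from .phylo import kimura_correct

        d = kimura_correct(p)
    else:
        d = p
    return SimilarityRecord(gene_a, gene_b, matched, d, 1.0 - d, score)


def align_pair(
    gene_a: GeneModel, gene_b: GeneModel, params: AlignParams | None = None, kimura: bool = False
) -> SimilarityRecord:
    aa, ab, score = global_align(gene_a.protein, gene_b.protein, params)
    return pairwise_similarity(aa, ab, gene_a.gene_id, gene_b.gene_id, score, kimura)


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def all_vs_all(
    genes_a: Sequence[GeneModel],
    genes_b: Sequence[GeneModel],
    params: AlignParams | None = None,
    prefilter: bool = False,
    kmer_k: int = 4,
    min_shared_kmers: int = 1,
    kimura: bool = False,
) -> list[SimilarityRecord]:
    """All-vs-all similarity records between two gene sets (unfiltered).

    The optional k-mer prefilter skips pairs sharing fewer than
    ``min_shared_kmers`` k-mers; its output is a heuristic subset of the
    exhaustive result.
    """
    params = params or AlignParams()
    kmers_b = [_kmer_set(g.protein, kmer_k) for g in genes_b] if prefilter else None
    out: list[SimilarityRecord] = []
    for ga in genes_a:
        kmers_a = _kmer_set(ga.protein, kmer_k) if prefilter else None
        for jb, gb in enumerate(genes_b):
            if prefilter and len(kmers_a & kmers_b[jb]) < min_shared_kmers:
                continue
            out.append(align_pair(ga, gb, params, kimura))
    return out


def filter_matched_length(
    records: Iterable[SimilarityRecord], min_len: int = DEFAULT_MIN_MATCHED
) -> list[SimilarityRecord]:
    """Keep records whose matched length is strictly greater than ``min_len``."""
    return [r for r in records if r.usable and r.matched_length > min_len]


def threshold_census(
    records: Sequence[SimilarityRecord],
    total_a: int,
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    species_pair: tuple[str, str] = ("A", "B"),
    dp: int = 0,
) -> ThresholdCensus:
    """Non-redundant count of A genes with a partner strictly above each level.

    Proportions are percentages of ``total_a``, half-up at ``dp`` decimals
    (integer percent by default, the usual printed precision).
    """
    if total_a == 0:
        raise ValueError("total_a must be positive")
    best: dict[str, float] = {}
    for r in records:
        if r.similarity > best.get(r.gene_a, -1.0):
            best[r.gene_a] = r.similarity
    n_nonred = {}
    proportion = {}
    for t in thresholds:
        n = sum(1 for s in best.values() if s > t / 100.0)
        n_nonred[t] = n
        proportion[t] = percent(n, total_a, dp)
    return ThresholdCensus(species_pair, list(thresholds), n_nonred, proportion, total_a)


def threshold_proportion(n: int, total: int, dp: int = 0) -> float:
    """The census proportion arithmetic on bare counts."""
    return percent(n, total, dp)


def low_similarity_genes(
    records: Sequence[SimilarityRecord],
    all_genes_a: Iterable[str | GeneModel],
    cutoff: int = 30,
) -> list[str]:
    """Genes of A whose best similarity to any B gene is strictly below cutoff%.

    Genes with no surviving record at all are included (their best
    similarity is vacuously below any cutoff).
    """
    ids = [g.gene_id if isinstance(g, GeneModel) else g for g in all_genes_a]
    best: dict[str, float] = {}
    for r in records:
        if r.similarity > best.get(r.gene_a, -1.0):
            best[r.gene_a] = r.similarity
    c = cutoff / 100.0
    return [g for g in ids if best.get(g, -math.inf) < c]


def records_to_rows(records: Sequence[SimilarityRecord]) -> list[dict]:
    return [
        {
            "gene_a": r.gene_a,
            "gene_b": r.gene_b,
            "matched_length": r.matched_length,
            "distance": round(r.distance, 6),
            "similarity": round(r.similarity, 6),
        }
        for r in records
    ]


def census_to_rows(census: ThresholdCensus) -> list[dict]:
    return [
        {
            "species_a": census.species_pair[0],
            "species_b": census.species_pair[1],
            "total_a": census.total_a,
            "threshold_pct": t,
            "n_nonredundant": census.n_nonredundant[t],
            "proportion_pct": census.proportion[t],
        }
        for t in census.thresholds
    ]
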
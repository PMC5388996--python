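"""Chromosomal distribution and physical clustering of NBS genes.

Two NBS genes adjacent on a chromosome (in start-position order) are linked
when the distance from the first gene's start to the second gene's end is
strictly less than the window (200 kb by default). Maximal chains of linked
adjacent genes with at least two members form clusters, so a cluster's
total span may well exceed the window.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

from ._util import percent, round_half_up
from .models import ClusterSummary, GeneCluster, NBSRecord, NBSType

DEFAULT_WINDOW_BP = 200_000


def chromosome_distribution(
    records: Iterable[NBSRecord],
) -> dict[str, tuple[int, set[NBSType]]]:
    """Per-sequence NBS gene count and the set of types present.

    Sequences without NBS genes are simply absent; the caller renders
    zeros. Scaffolds are reported like chromosomes — separating them is a
    presentation concern (see :func:`split_by_prefix`).
    """
    out: dict[str, tuple[int, set[NBSType]]] = {}
    for r in records:
        count, types = out.get(r.gene.seq_id, (0, set()))
        types.add(r.nbs_type)
        out[r.gene.seq_id] = (count + 1, types)
    return out


def split_by_prefix(
    distribution: dict[str, tuple[int, set[NBSType]]],
    scaffold_prefix: str = "scaffold",
) -> tuple[dict, dict]:
    """Split a distribution into (chromosomes, unplaced scaffolds) by name prefix."""
    chroms = {k: v for k, v in distribution.items() if not k.lower().startswith(scaffold_prefix.lower())}
    scaffolds = {k: v for k, v in distribution.items() if k.lower().startswith(scaffold_prefix.lower())}
    return chroms, scaffolds


def find_clusters(
    records: Sequence[NBSRecord], window_bp: int = DEFAULT_WINDOW_BP
) -> list[GeneCluster]:
    """Detect gene clusters with the chained adjacent-pair rule.

    Per sequence, genes sorted by (start, end, gene_id); adjacent genes i
    and i+1 are linked iff end(i+1) - start(i) < window_bp. Chains of
    length >= 2 become clusters; singletons never do.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    by_seq: dict[str, list[NBSRecord]] = defaultdict(list)
    for r in records:
        by_seq[r.gene.seq_id].append(r)
    clusters: list[GeneCluster] = []
    for seq_id in sorted(by_seq):
        genes = sorted(by_seq[seq_id], key=lambda r: (r.gene.start, r.gene.end, r.gene_id))
        chain: list[NBSRecord] = [genes[0]]
        for prev, cur in zip(genes, genes[1:]):
            if cur.gene.end - prev.gene.start < window_bp:
                chain.append(cur)
            else:
                if len(chain) >= 2:
                    clusters.append(_make_cluster(seq_id, chain))
                chain = [cur]
        if len(chain) >= 2:
            clusters.append(_make_cluster(seq_id, chain))
    return clusters


def _make_cluster(seq_id: str, chain: list[NBSRecord]) -> GeneCluster:
    return GeneCluster(
        seq_id=seq_id,
        member_ids=[r.gene_id for r in chain],
        span_start=min(r.gene.start for r in chain),
        span_end=max(r.gene.end for r in chain),
    )


def cluster_summary(
    records: Sequence[NBSRecord],
    clusters: Sequence[GeneCluster],
    species: str,
) -> ClusterSummary:
    """Table-style summary: cluster-gene proportion and mean cluster size."""
    n_genes = len(records)
    n_cluster_genes = sum(c.size for c in clusters)
    return summary_from_counts(n_genes, n_cluster_genes, len(clusters), species)


def summary_from_counts(
    n_genes: int, n_cluster_genes: int, n_clusters: int, species: str = ""
) -> ClusterSummary:
    """The summary arithmetic on bare counts (one decimal, half-up)."""
    proportion = percent(n_cluster_genes, n_genes, 1) if n_genes else 0.0
    if n_clusters == 0:
        return ClusterSummary(species, n_genes, n_cluster_genes, proportion, 0, 0.0, False)
    mean_members = round_half_up(n_cluster_genes / n_clusters, 1)
    return ClusterSummary(
        species, n_genes, n_cluster_genes, proportion, n_clusters, mean_members, True
    )


def clusters_to_rows(clusters: Sequence[GeneCluster]) -> list[dict]:
    return [
        {
            "cluster_id": f"c{i:04d}",
            "seq_id": c.seq_id,
            "size": c.size,
            "span_start": c.span_start,
            "span_end": c.span_end,
            "member_ids": ";".join(c.member_ids),
        }
        for i, c in enumerate(clusters, 1)
    ]
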
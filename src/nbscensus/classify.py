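"""Architecture coding and NBS typing.

A gene qualifies as NBS-encoding iff it carries at least one NB-ARC domain.
Its architecture is coded relative to the leftmost NB-ARC hit: a TIR, CC or
RPW8 domain starting before the NB-ARC contributes the prefix letter T, C
or R (precedence T > R > C when several classes qualify); an LRR starting
strictly after the NB-ARC end appends L. The resulting code is one of the
eight mutually exclusive types CN, CNL, N, NL, RN, RNL, TN, TNL.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Sequence

from ._util import percent
from .models import (
    NBS_TYPE_ORDER,
    DomainClass,
    DomainHit,
    GeneModel,
    NBSRecord,
    NBSType,
    TypeCensus,
)

log = logging.getLogger(__name__)

_PREFIX_PRECEDENCE = [
    (DomainClass.TIR, "T"),
    (DomainClass.RPW8, "R"),
    (DomainClass.CC, "C"),
]


def select_nbs_genes(
    hits: Sequence[DomainHit], genes: Sequence[GeneModel]
) -> list[tuple[GeneModel, list[DomainHit]]]:
    """Return genes carrying >= 1 NB-ARC hit, each paired with all its hits."""
    by_gene: dict[str, list[DomainHit]] = defaultdict(list)
    for h in hits:
        by_gene[h.gene_id].append(h)
    out = []
    for g in genes:
        ghits = by_gene.get(g.gene_id, [])
        if any(h.dclass is DomainClass.NBARC for h in ghits):
            out.append((g, sorted(ghits, key=lambda h: (h.p_start, h.p_end))))
    return out


def code_architecture(hits: Sequence[DomainHit]) -> str:
    """Code a gene's domain architecture over {T, C, R, N, L}.

    Order of the input hits is irrelevant. Raises if no NB-ARC hit is
    present. Consecutive same-class hits (e.g. several LRR repeats)
    collapse into a single letter.
    """
    nbarc = [h for h in hits if h.dclass is DomainClass.NBARC]
    if not nbarc:
        raise ValueError("no NB-ARC hit: gene is not NBS-encoding")
    ref = min(nbarc, key=lambda h: (h.p_start, h.p_end))
    prefix = ""
    qualifying = {
        h.dclass for h in hits if h.p_start < ref.p_start and h.dclass is not DomainClass.NBARC
    }
    for dclass, letter in _PREFIX_PRECEDENCE:
        if dclass in qualifying:
            prefix = letter
            if len(qualifying & {d for d, _ in _PREFIX_PRECEDENCE}) > 1:
                log.debug(
                    "multiple N-terminal classes %s; precedence chose %s",
                    sorted(d.value for d in qualifying),
                    letter,
                )
            break
    suffix = "L" if any(
        h.dclass is DomainClass.LRR and h.p_start > ref.p_end for h in hits
    ) else ""
    return f"{prefix}N{suffix}"


def classify(code: str) -> NBSType:
    """Map an architecture code onto the eight-value type enum."""
    try:
        return NBSType(code)
    except ValueError:
        raise ValueError(f"unknown architecture code: {code!r}") from None


def build_records(
    hits: Sequence[DomainHit], genes: Sequence[GeneModel]
) -> list[NBSRecord]:
    """Select, code and type all NBS genes in one pass."""
    out = []
    for gene, ghits in select_nbs_genes(hits, genes):
        code = code_architecture(ghits)
        out.append(NBSRecord(gene=gene, hits=ghits, code=code, nbs_type=classify(code)))
    return out


def type_census(records: Iterable[NBSRecord], species: str) -> TypeCensus:
    """Per-type counts and half-up two-decimal percentages for one species."""
    counts = {t: 0 for t in NBS_TYPE_ORDER}
    for r in records:
        counts[r.nbs_type] += 1
    total = sum(counts.values())
    if total == 0:
        return TypeCensus(species, counts, {t: 0.0 for t in NBS_TYPE_ORDER}, 0)
    percentages = {t: percent(c, total, 2) for t, c in counts.items()}
    return TypeCensus(species, counts, percentages, total)


def census_percentage(count: int, total: int) -> float:
    """The census percentage arithmetic on bare counts (two decimals, half-up)."""
    return percent(count, total, 2)


def census_to_rows(census: TypeCensus) -> list[dict]:
    """Rows for the TSV census table: species, type, count, percentage."""
    rows = [
        {
            "species": census.species,
            "type": t.value,
            "count": census.counts[t],
            "percentage": census.percentages[t],
        }
        for t in NBS_TYPE_ORDER
    ]
    rows.append(
        {
            "species": census.species,
            "type": "Total",
            "count": census.total,
            "percentage": 100.0 if census.total else 0.0,
        }
    )
    return rows
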
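"""Exon-count statistics per species and per NBS type."""

from __future__ import annotations

from collections import defaultdict
from typing import Sequence

from ._util import round_half_up
from .models import ExonSummary, NBSRecord, NBSType


def exon_summary(records: Sequence[NBSRecord], species: str) -> ExonSummary:
    """Arithmetic mean exon counts, overall and per type, half-up to 1 dp.

    Types with no genes are absent from the per-type maps.
    """
    by_type: dict[NBSType, list[int]] = defaultdict(list)
    for r in records:
        by_type[r.nbs_type].append(r.gene.exon_count)
    n_by_type = {t: len(v) for t, v in by_type.items()}
    mean_by_type = {t: round_half_up(sum(v) / len(v), 1) for t, v in by_type.items()}
    total = sum(n_by_type.values())
    mean_overall = (
        round_half_up(sum(r.gene.exon_count for r in records) / total, 1) if total else 0.0
    )
    return ExonSummary(species, mean_overall, mean_by_type, n_by_type)


def summary_to_rows(summary: ExonSummary) -> list[dict]:
    rows = [
        {
            "species": summary.species,
            "type": t.value,
            "n": summary.n_by_type[t],
            "mean_exons": summary.mean_by_type[t],
        }
        for t in sorted(summary.mean_by_type, key=lambda t: t.value)
    ]
    rows.append(
        {
            "species": summary.species,
            "type": "All",
            "n": sum(summary.n_by_type.values()),
            "mean_exons": summary.mean_overall,
        }
    )
    return rows
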
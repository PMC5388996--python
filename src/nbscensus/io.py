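"""Readers and writers for the formats the pipeline touches.

Protein FASTA, GFF3 gene models, tabular domain-hit files (a simple TSV
dialect and HMMER3 ``domtblout``) and newick trees. Downstream modules
depend only on the domain types produced here, never on raw files.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from skbio import TreeNode

from .models import DomainClass, DomainHit, GeneModel

log = logging.getLogger(__name__)

#: Accession -> domain class. Keys are lower-cased and version-stripped
#: before lookup, so "PF00931.22" and "pfam00931" both resolve to NB-ARC.
ACCESSION_MAP: dict[str, DomainClass] = {
    "pf00931": DomainClass.NBARC,
    "pfam00931": DomainClass.NBARC,
    "nb-arc": DomainClass.NBARC,
    "nbarc": DomainClass.NBARC,
    # TIR
    "pfam01582": DomainClass.TIR,
    "pf01582": DomainClass.TIR,
    "cl23801": DomainClass.TIR,
    "smart00255": DomainClass.TIR,
    "tir": DomainClass.TIR,
    # RPW8
    "pfam05659": DomainClass.RPW8,
    "pf05659": DomainClass.RPW8,
    "cl05301": DomainClass.RPW8,
    "rpw8": DomainClass.RPW8,
    # coiled-coil has no Pfam accession; COILS-style calls come pre-labelled
    "cc": DomainClass.CC,
    "coils": DomainClass.CC,
    # LRR
    "pfam00560": DomainClass.LRR,
    "pf00560": DomainClass.LRR,
    "pfam07723": DomainClass.LRR,
    "pfam07725": DomainClass.LRR,
    "pfam12799": DomainClass.LRR,
    "pfam13306": DomainClass.LRR,
    "pfam13516": DomainClass.LRR,
    "pfam13855": DomainClass.LRR,
    "pfam14850": DomainClass.LRR,
    "cl19480": DomainClass.LRR,
    "smart00370": DomainClass.LRR,
    "cog4886": DomainClass.LRR,
    "lrr": DomainClass.LRR,
}


def map_accession(token: str) -> DomainClass | None:
    """Resolve a domain accession or class name to a :class:`DomainClass`."""
    key = token.strip().lower()
    if "." in key:
        key = key.split(".", 1)[0]
    return ACCESSION_MAP.get(key)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a protein FASTA; ids are the first whitespace token of each header.

    Raises on duplicate ids; an empty file yields an empty list with a
    warning. Record order is preserved.
    """
    path = Path(path)
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        seen.add(rec.id)
        out.append((rec.id, str(rec.seq).upper()))
    if not out:
        warnings.warn(f"empty FASTA file: {path}", stacklevel=2)
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path: str | Path, species: str) -> list[GeneModel]:
    """Load gene models from GFF3, counting exons of each gene's first mRNA.

    Exon count comes from the first-listed mRNA of each gene; genes whose
    mRNAs carry no exon features (or that have no mRNA at all) fall back to
    exons parented directly on the gene, and finally to 1 with a warning.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    out: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        n_exons = 0
        if mrnas:
            n_exons = sum(1 for _ in db.children(mrnas[0], featuretype="exon"))
        if n_exons == 0:
            n_exons = sum(1 for _ in db.children(gene, featuretype="exon", level=1))
        if n_exons == 0:
            warnings.warn(
                f"gene {gene.id} has no exon features; exon_count set to 1",
                stacklevel=2,
            )
            n_exons = 1
        out.append(
            GeneModel(
                gene_id=gene.id,
                species=species,
                seq_id=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand if gene.strand in {"+", "-"} else ".",
                exon_count=n_exons,
            )
        )
    return out


def write_gff3(genes: Sequence[GeneModel], path: str | Path, exon_layout: dict[str, list[tuple[int, int]]] | None = None) -> None:
    """Write gene/mRNA/exon rows. ``exon_layout`` may give explicit exon
    coordinates per gene; otherwise the gene span is split evenly."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.seq_id}\tnbscensus\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{g.seq_id}\tnbscensus\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={mrna_id};Parent={g.gene_id}\n"
            )
            if exon_layout and g.gene_id in exon_layout:
                exons = exon_layout[g.gene_id]
            else:
                exons = _split_span(g.start, g.end, g.exon_count)
            for k, (s, e) in enumerate(exons, 1):
                fh.write(
                    f"{g.seq_id}\tnbscensus\texon\t{s}\t{e}\t.\t{g.strand}\t.\tID={mrna_id}.e{k};Parent={mrna_id}\n"
                )


def _split_span(start: int, end: int, n: int) -> list[tuple[int, int]]:
    """Split [start, end] into n disjoint 1-based inclusive chunks."""
    length = end - start + 1
    n = min(n, max(1, length // 2))
    # leave a 1-bp gap between consecutive exons where possible
    size = max(1, (length - (n - 1)) // n)
    out = []
    s = start
    for i in range(n):
        e = end if i == n - 1 else min(end, s + size - 1)
        out.append((s, e))
        s = e + 2
        if s > end:
            out = out[: i + 1]
            break
    return out


# ---------------------------------------------------------------------------
# Domain-hit tables


def read_domain_table(
    path: str | Path,
    dialect: str = "simple_tsv",
    protein_lengths: dict[str, int] | None = None,
) -> list[DomainHit]:
    """Read domain hits; dialect is ``simple_tsv`` or ``domtblout``.

    Hits are returned sorted by (gene_id, p_start) with domain classes
    normalized to the five-value enum via :data:`ACCESSION_MAP`. Hits with
    unmappable accessions are skipped with a warning. If ``protein_lengths``
    is given, a hit extending beyond its protein raises.
    """
    if dialect == "simple_tsv":
        hits = _read_simple_tsv(Path(path))
    elif dialect == "domtblout":
        hits = _read_domtblout(Path(path))
    else:
        raise ValueError(f"unknown domain-table dialect: {dialect}")
    if protein_lengths is not None:
        for h in hits:
            plen = protein_lengths.get(h.gene_id)
            if plen is not None and h.p_end > plen:
                raise ValueError(
                    f"hit on {h.gene_id} ends at {h.p_end}, beyond protein length {plen}"
                )
    hits.sort(key=lambda h: (h.gene_id, h.p_start, h.p_end))
    return hits


def _read_simple_tsv(path: Path) -> list[DomainHit]:
    hits: list[DomainHit] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        return hits
    body = lines[1:] if lines[0].lower().startswith("gene_id") else lines
    for ln in body:
        parts = ln.split("\t")
        if len(parts) < 5:
            raise ValueError(f"malformed domain-table row: {ln!r}")
        gene_id, token, p_start, p_end, score = parts[:5]
        source = parts[5] if len(parts) > 5 else token
        dclass = map_accession(token)
        if dclass is None:
            warnings.warn(f"unmappable domain accession {token!r}; hit skipped", stacklevel=3)
            continue
        hits.append(
            DomainHit(gene_id, dclass, int(p_start), int(p_end), float(score), source)
        )
    return hits


def _read_domtblout(path: Path) -> list[DomainHit]:
    """HMMER3 per-domain table from hmmscan: query = protein, target = model.

    Envelope coordinates define the domain extent.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for ln in fh:
            if not ln.strip() or ln.startswith("#"):
                continue
            parts = ln.split()
            if len(parts) < 22:
                raise ValueError(f"malformed domtblout row: {ln!r}")
            target_name, target_acc = parts[0], parts[1]
            gene_id = parts[3]
            dom_score = float(parts[13])
            env_from, env_to = int(parts[19]), int(parts[20])
            dclass = map_accession(target_acc) or map_accession(target_name)
            if dclass is None:
                warnings.warn(
                    f"unmappable domain accession {target_acc!r}; hit skipped",
                    stacklevel=3,
                )
                continue
            hits.append(
                DomainHit(gene_id, dclass, env_from, env_to, dom_score, target_acc)
            )
    return hits


def write_domain_table(hits: Sequence[DomainHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tdclass_or_accession\tp_start\tp_end\tscore\tsource\n")
        for h in hits:
            fh.write(
                f"{h.gene_id}\t{h.dclass.value}\t{h.p_start}\t{h.p_end}\t{h.score}\t{h.source}\n"
            )


# ---------------------------------------------------------------------------
# Joint loading


def load_species(
    fasta_path: str | Path,
    gff3_path: str | Path,
    domain_path: str | Path,
    species: str,
    dialect: str = "simple_tsv",
) -> tuple[list[GeneModel], list[DomainHit]]:
    """Load one species' proteins, gene models and domain hits jointly.

    Attaches protein sequences to gene models, validates that every domain
    hit names a known gene and lies within its protein.
    """
    proteins = dict(read_fasta(fasta_path))
    genes = read_gff3(gff3_path, species)
    for g in genes:
        if g.gene_id not in proteins:
            raise ValueError(f"gene {g.gene_id} has no protein in {fasta_path}")
        g.protein = proteins[g.gene_id]
        g.validate_protein()
    lengths = {g.gene_id: len(g.protein) for g in genes}
    hits = read_domain_table(domain_path, dialect=dialect, protein_lengths=lengths)
    for h in hits:
        if h.gene_id not in lengths:
            raise ValueError(f"domain hit on unknown gene {h.gene_id}")
    return genes, hits


# ---------------------------------------------------------------------------
# Newick


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Write a tree with branch lengths and integer supports as node labels."""
    if tree.count(tips=True) < 2:
        raise ValueError("tree must have at least 2 leaves")
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
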
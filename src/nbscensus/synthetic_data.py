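"""Synthetic genomes with the statistical structure the analysis assumes.

Each gene is a concatenation of domain "blocks" (TIR, CC, RPW8, NB-ARC,
LRR) drawn from shared per-class seed motifs. Species identity comes from
mutating those motifs at a configurable species divergence; individual
genes add a small per-gene noise on top. The domain table records the true
block coordinates, so classification can be validated as a round trip.

Gene placement honours the same 200-kb adjacency rule the cluster detector
uses: genes of one cluster group are spaced so that each adjacent pair
links, and groups are separated by more than the window.

Allotetraploids are derived from two diploid parents: a configurable
fraction of the gene complement descends from parent A (the inheritance
bias), each inherited copy is mutated at a per-parent divergence rate,
and optional gene loss and tandem duplication are applied. Parent gene
order is preserved per subgenome, so collinearity with the parents is
built in.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import io as nbio
from .models import (
    DomainClass,
    DomainHit,
    GeneModel,
    GenomeConfig,
    NBSType,
    SyntheticGenome,
    TetraploidConfig,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Domain block lengths (aa). NB-ARC is kept long enough that same-type
#: gene pairs comfortably exceed the 200-aa matched-length filter.
BLOCK_LENGTHS: dict[DomainClass, int] = {
    DomainClass.TIR: 150,
    DomainClass.CC: 60,
    DomainClass.RPW8: 140,
    DomainClass.NBARC: 280,
    DomainClass.LRR: 70,
}

#: Architecture templates per NBS type (two LRR repeats for L types).
ARCHITECTURES: dict[NBSType, list[DomainClass]] = {
    NBSType.N: [DomainClass.NBARC],
    NBSType.CN: [DomainClass.CC, DomainClass.NBARC],
    NBSType.RN: [DomainClass.RPW8, DomainClass.NBARC],
    NBSType.TN: [DomainClass.TIR, DomainClass.NBARC],
    NBSType.NL: [DomainClass.NBARC, DomainClass.LRR, DomainClass.LRR],
    NBSType.CNL: [DomainClass.CC, DomainClass.NBARC, DomainClass.LRR, DomainClass.LRR],
    NBSType.RNL: [DomainClass.RPW8, DomainClass.NBARC, DomainClass.LRR, DomainClass.LRR],
    NBSType.TNL: [DomainClass.TIR, DomainClass.NBARC, DomainClass.LRR, DomainClass.LRR],
}

_ACCESSION_OF = {
    DomainClass.NBARC: "PF00931",
    DomainClass.TIR: "pfam01582",
    DomainClass.RPW8: "pfam05659",
    DomainClass.LRR: "pfam00560",
    DomainClass.CC: "COILS",
}

_LINKER = 5
# Fixed seed for the ancestral per-class motifs, shared by every generated
# species so that between-species divergence is controlled by config alone.
_MOTIF_SEED = 9931


def _base_motifs() -> dict[DomainClass, str]:
    rng = np.random.default_rng(_MOTIF_SEED)
    return {
        dc: "".join(rng.choice(list(AA20), size=n))
        for dc, n in BLOCK_LENGTHS.items()
    }


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AA20), size=n))


def mutate_protein(seq: str, rate: float, rng: np.random.Generator | int) -> str:
    """Substitute each position independently with probability ``rate``.

    Substitutions are uniform over the 19 other canonical residues; length
    is always preserved.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if rate == 0.0:
        return seq
    chars = list(seq)
    hit = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hit:
        choices = [c for c in AA20 if c != chars[i]]
        chars[i] = choices[rng.integers(0, len(choices))]
    return "".join(chars)


def _sample_groups(n: int, cluster_fraction: float, size_p: float, rng) -> list[int]:
    """Group sizes: clusters (>= 2 genes) covering ~cluster_fraction of n,
    then singletons."""
    n_clustered = int(round(cluster_fraction * n))
    if n_clustered == 1:
        n_clustered = 2 if n >= 2 else 0
    sizes: list[int] = []
    remaining = n_clustered
    while remaining >= 2:
        size = 1 + int(rng.geometric(size_p))
        size = min(size, remaining)
        if remaining - size == 1:
            size += 1
        sizes.append(size)
        remaining -= size
    sizes.extend([1] * (n - sum(sizes)))
    return sizes


def _place_groups(
    group_sizes_per_chrom: list[list[int]],
    chrom_names: list[str],
    rng,
    max_len: int | None = None,
) -> list[tuple[str, int, int, int]]:
    """Lay out groups along chromosomes.

    Returns (seq_id, start, end, group_id) per gene in placement order.
    Adjacent genes within a group always satisfy end(i+1) - start(i) <
    200 kb; consecutive groups never link.
    """
    out = []
    gid = 0
    for chrom, sizes in zip(chrom_names, group_sizes_per_chrom):
        cursor = int(rng.integers(10_000, 50_000))
        for size in sizes:
            start = cursor
            prev_start = None
            for k in range(size):
                glen = int(rng.integers(2_000, 6_001))
                if prev_start is not None:
                    start = prev_start + prev_len + int(rng.integers(1_000, 110_000))
                out.append((chrom, start, start + glen - 1, gid))
                prev_start, prev_len = start, glen
            cursor = prev_start + 250_000 + int(rng.integers(0, 100_000))
            gid += 1
        if max_len is not None and cursor > max_len:
            raise ValueError(
                f"placement on {chrom} exceeds chromosome length {max_len}; "
                "configure longer chromosomes or fewer genes"
            )
    return out


def _distribute(sizes: list[int], n_chrom: int, rng) -> list[list[int]]:
    order = list(rng.permutation(len(sizes)))
    per = [[] for _ in range(n_chrom)]
    for k, gi in enumerate(order):
        per[k % n_chrom].append(sizes[gi])
    return per


def _build_gene(
    species: str,
    gene_id: str,
    nbs_type: NBSType,
    motifs: dict[DomainClass, str],
    gene_noise: float,
    rng,
) -> tuple[str, list[tuple[DomainClass, int, int]]]:
    """Protein sequence plus true (class, p_start, p_end) block coordinates."""
    parts: list[str] = []
    coords: list[tuple[DomainClass, int, int]] = []
    pos = 0
    for dclass in ARCHITECTURES[nbs_type]:
        linker = _random_protein(rng, _LINKER)
        parts.append(linker)
        pos += _LINKER
        block = mutate_protein(motifs[dclass], gene_noise, rng)
        coords.append((dclass, pos + 1, pos + len(block)))
        parts.append(block)
        pos += len(block)
    parts.append(_random_protein(rng, _LINKER))
    return "".join(parts), coords


def generate_diploid(config: GenomeConfig) -> SyntheticGenome:
    """Generate one diploid species' NBS gene complement."""
    rng = np.random.default_rng(config.seed)
    base = _base_motifs()
    motifs = {dc: mutate_protein(m, config.species_divergence, rng) for dc, m in base.items()}

    types = list(ARCHITECTURES)
    probs = np.array([config.type_proportions.get(t, 0.0) for t in types])
    probs = probs / probs.sum()
    n = config.n_nbs_genes
    sampled = [types[i] for i in rng.choice(len(types), size=n, p=probs)]

    sizes = _sample_groups(n, config.cluster_fraction, config.cluster_size_p, rng)
    chrom_names = [f"{config.chrom_prefix}{i:02d}" for i in range(1, config.n_chromosomes + 1)]
    per_chrom = _distribute(sizes, config.n_chromosomes, rng)
    placement = _place_groups(per_chrom, chrom_names, rng, config.chromosome_length_bp)

    genes: list[GeneModel] = []
    hits: list[DomainHit] = []
    true_types: dict[str, NBSType] = {}
    groups: dict[str, int] = {}
    for i, ((seq_id, start, end, gid), nbs_type) in enumerate(zip(placement, sampled)):
        gene_id = f"{config.species_name}_{i:04d}"
        protein, coords = _build_gene(
            config.species_name, gene_id, nbs_type, motifs, config.gene_noise, rng
        )
        mean = config.exon_mean_by_type.get(nbs_type, 2.0)
        exon_count = 1 + int(rng.poisson(max(mean - 1.0, 0.0)))
        genes.append(
            GeneModel(
                gene_id=gene_id,
                species=config.species_name,
                seq_id=seq_id,
                start=start,
                end=end,
                strand="+" if rng.random() < 0.5 else "-",
                exon_count=exon_count,
                protein=protein,
            )
        )
        for dclass, ps, pe in coords:
            hits.append(
                DomainHit(
                    gene_id,
                    dclass,
                    ps,
                    pe,
                    score=float(np.round(50.0 + 100.0 * rng.random(), 1)),
                    source=_ACCESSION_OF[dclass],
                )
            )
        true_types[gene_id] = nbs_type
        groups[gene_id] = gid
    manifest = {"kind": "diploid", "config": _config_dict(config)}
    return SyntheticGenome(config.species_name, genes, hits, true_types, groups, manifest)


def derive_allotetraploid(
    parent_a: SyntheticGenome,
    parent_d: SyntheticGenome,
    config: TetraploidConfig,
) -> SyntheticGenome:
    """Derive an allotetraploid gene set from two diploid parents.

    A fraction ``inheritance_bias`` of the (pre-loss) gene complement
    descends from ``parent_a``; each inherited copy is mutated at the
    per-parent divergence rate. Copies keep their parent's chromosome
    order; subgenome chromosomes are prefixed A/D. Extra copies beyond one
    per parent gene, and tandem duplicates, are placed adjacent to their
    source so they cluster with it.
    """
    rng = np.random.default_rng(config.seed)
    n_total = len(parent_a.genes) + len(parent_d.genes)
    n_from_a = int(round(config.inheritance_bias * n_total))
    n_from_d = n_total - n_from_a

    copies_a = _copy_counts(len(parent_a.genes), n_from_a, rng)
    copies_d = _copy_counts(len(parent_d.genes), n_from_d, rng)

    entries = []  # (subgenome, parent_gene, copy_count)
    for parent, copies, sub in ((parent_a, copies_a, "A"), (parent_d, copies_d, "D")):
        ordered = sorted(parent.genes, key=lambda g: (g.seq_id, g.start, g.gene_id))
        for g, c in zip(ordered, copies[_order_index(parent.genes, ordered)]):
            if c > 0:
                entries.append((sub, parent, g, int(c)))

    # flatten to individual copies, then loss and tandem duplication
    flat = []
    for sub, parent, g, c in entries:
        for _ in range(c):
            flat.append((sub, parent, g))
    n_loss = int(round(config.loss_fraction * len(flat)))
    if n_loss:
        drop = set(rng.choice(len(flat), size=n_loss, replace=False).tolist())
        flat = [e for k, e in enumerate(flat) if k not in drop]
    n_dup = int(round(config.duplication_fraction * len(flat)))
    if n_dup:
        dup_at = set(rng.choice(len(flat), size=n_dup, replace=False).tolist())
        flat = [e for k, item in enumerate(flat) for e in ([item, item] if k in dup_at else [item])]

    hits_by_gene: dict[str, list[DomainHit]] = {}
    for parent in (parent_a, parent_d):
        for h in parent.hits:
            hits_by_gene.setdefault(h.gene_id, []).append(h)

    # group consecutive copies by (subgenome, parent seq, parent group)
    genes: list[GeneModel] = []
    hits: list[DomainHit] = []
    true_types: dict[str, NBSType] = {}
    groups: dict[str, int] = {}
    per_chrom_sizes: dict[str, list[int]] = {}
    chrom_of: list[str] = []
    prev_key = None
    for sub, parent, g in flat:
        chrom = f"{sub}{g.seq_id[-2:] if g.seq_id[-2:].isdigit() else '01'}"
        key = (chrom, parent.groups.get(g.gene_id, -1))
        if key != prev_key:
            per_chrom_sizes.setdefault(chrom, []).append(0)
            prev_key = key
        per_chrom_sizes[chrom][-1] += 1
        chrom_of.append(chrom)

    chrom_names = sorted(per_chrom_sizes)
    placement = _place_groups([per_chrom_sizes[c] for c in chrom_names], chrom_names, rng)
    slots: dict[str, list[tuple[str, int, int, int]]] = {}
    for p in placement:
        slots.setdefault(p[0], []).append(p)
    cursor = {c: 0 for c in chrom_names}

    for i, ((sub, parent, g), chrom) in enumerate(zip(flat, chrom_of)):
        seq_id, start, end, gid = slots[chrom][cursor[chrom]]
        cursor[chrom] += 1
        gene_id = f"{config.species_name}_{i:04d}"
        rate = config.divergence_a if sub == "A" else config.divergence_d
        protein = mutate_protein(g.protein, rate, rng)
        genes.append(
            GeneModel(
                gene_id=gene_id,
                species=config.species_name,
                seq_id=seq_id,
                start=start,
                end=end,
                strand=g.strand,
                exon_count=g.exon_count,
                protein=protein,
            )
        )
        for h in hits_by_gene.get(g.gene_id, []):
            hits.append(DomainHit(gene_id, h.dclass, h.p_start, h.p_end, h.score, h.source))
        true_types[gene_id] = parent.true_types[g.gene_id]
        groups[gene_id] = gid
    manifest = {
        "kind": "allotetraploid",
        "config": _config_dict(config),
        "parent_a": parent_a.species,
        "parent_d": parent_d.species,
    }
    return SyntheticGenome(config.species_name, genes, hits, true_types, groups, manifest)


def _copy_counts(n_parent: int, n_needed: int, rng) -> np.ndarray:
    counts = np.zeros(n_parent, dtype=int)
    if n_needed <= 0 or n_parent == 0:
        return counts
    if n_needed <= n_parent:
        idx = rng.choice(n_parent, size=n_needed, replace=False)
        counts[idx] = 1
    else:
        counts[:] = 1
        extra = rng.choice(n_parent, size=n_needed - n_parent, replace=True)
        np.add.at(counts, extra, 1)
    return counts


def _order_index(original: list[GeneModel], ordered: list[GeneModel]) -> list[int]:
    pos = {g.gene_id: i for i, g in enumerate(original)}
    return [pos[g.gene_id] for g in ordered]


def _config_dict(config) -> dict:
    d = dataclasses.asdict(config)
    for k, v in list(d.items()):
        if isinstance(v, dict):
            d[k] = {key.value if hasattr(key, "value") else key: val for key, val in v.items()}
    return d


def write_genome(genome: SyntheticGenome, outdir: str | Path) -> dict[str, Path]:
    """Emit FASTA / GFF3 / domain TSV / manifest JSON for one genome."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    name = genome.species
    paths = {
        "fasta": outdir / f"{name}.faa",
        "gff3": outdir / f"{name}.gff3",
        "domains": outdir / f"{name}.domains.tsv",
        "manifest": outdir / f"{name}.manifest.json",
    }
    genes = sorted(genome.genes, key=lambda g: (g.seq_id, g.start, g.gene_id))
    nbio.write_fasta([(g.gene_id, g.protein) for g in genes], paths["fasta"])
    nbio.write_gff3(genes, paths["gff3"])
    hits = sorted(genome.hits, key=lambda h: (h.gene_id, h.p_start, h.p_end))
    nbio.write_domain_table(hits, paths["domains"])
    with open(paths["manifest"], "w") as fh:
        json.dump(genome.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


# ---------------------------------------------------------------------------
# Presets mirroring the published diploid census shapes


def preset(name: str, n_genes: int | None = None, n_chromosomes: int | None = None, seed: int = 0) -> GenomeConfig:
    """Named diploid presets: ``arboreum-like`` (A-genome) and
    ``raimondii-like`` (D-genome) census shapes, scalable via ``n_genes``."""
    if name == "arboreum-like":
        counts = {"CN": 44, "CNL": 80, "N": 59, "NL": 53, "RN": 0, "RNL": 3, "TN": 2, "TNL": 5}
        exon_means = {"CN": 2.0, "CNL": 2.1, "N": 2.0, "NL": 2.6, "RN": 4.0, "RNL": 4.0, "TN": 4.5, "TNL": 4.4}
        cfg = dict(cluster_fraction=182 / 246, cluster_size_p=0.45, chrom_prefix="A")
        default_n, default_c = 246, 13
    elif name == "raimondii-like":
        counts = {"CN": 39, "CNL": 107, "N": 62, "NL": 89, "RN": 1, "RNL": 3, "TN": 14, "TNL": 50}
        exon_means = {"CN": 2.2, "CNL": 2.4, "N": 2.2, "NL": 2.7, "RN": 5.0, "RNL": 5.0, "TN": 5.0, "TNL": 5.0}
        cfg = dict(cluster_fraction=287 / 365, cluster_size_p=0.22, chrom_prefix="D")
        default_n, default_c = 365, 13
    else:
        raise ValueError(f"unknown preset: {name}")
    total = sum(counts.values())
    return GenomeConfig(
        species_name=name.split("-")[0],
        n_chromosomes=n_chromosomes or default_c,
        n_nbs_genes=n_genes or default_n,
        type_proportions={NBSType(k): v / total for k, v in counts.items()},
        exon_mean_by_type={NBSType(k): v for k, v in exon_means.items()},
        seed=seed,
        **cfg,
    )
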
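"""Domain types shared across the pipeline.

All genomic coordinates follow the GFF3 convention: 1-based, inclusive,
and are never converted internally. Protein coordinates are likewise
1-based inclusive positions on the amino-acid sequence.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
AA_ALPHABET_X = AA_ALPHABET | {"X"}


class DomainClass(enum.Enum):
    """The five domain classes relevant to NBS-protein architecture."""

    TIR = "TIR"
    CC = "CC"
    RPW8 = "RPW8"
    NBARC = "NBARC"
    LRR = "LRR"


class NBSType(enum.Enum):
    """The eight mutually exclusive NBS architecture types.

    The letter before ``N`` names the N-terminal domain found upstream of
    NB-ARC (T = TIR, C = coiled-coil, R = RPW8); a trailing ``L`` marks a
    leucine-rich repeat downstream of NB-ARC.
    """

    CN = "CN"
    CNL = "CNL"
    N = "N"
    NL = "NL"
    RN = "RN"
    RNL = "RNL"
    TN = "TN"
    TNL = "TNL"


#: Canonical report order, matching the usual census table layout.
NBS_TYPE_ORDER = [
    NBSType.CN,
    NBSType.CNL,
    NBSType.N,
    NBSType.NL,
    NBSType.RN,
    NBSType.RNL,
    NBSType.TN,
    NBSType.TNL,
]


@dataclass
class GeneModel:
    """One annotated protein-coding gene.

    ``protein`` may be empty until a protein FASTA has been joined in; the
    joint loader validates the full invariants.
    """

    gene_id: str
    species: str
    seq_id: str
    start: int
    end: int
    strand: str = "+"
    exon_count: int = 1
    protein: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.exon_count < 1:
            raise ValueError(f"gene {self.gene_id}: exon_count must be >= 1")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    def validate_protein(self) -> None:
        if not self.protein:
            raise ValueError(f"gene {self.gene_id}: empty protein sequence")
        bad = set(self.protein) - AA_ALPHABET_X
        if bad:
            raise ValueError(
                f"gene {self.gene_id}: non-amino-acid characters {sorted(bad)}"
            )


@dataclass
class DomainHit:
    """One occurrence of a domain class on a protein."""

    gene_id: str
    dclass: DomainClass
    p_start: int
    p_end: int
    score: float = 0.0
    source: str = ""

    def __post_init__(self) -> None:
        if self.p_start > self.p_end:
            raise ValueError(
                f"hit on {self.gene_id}: p_start {self.p_start} > p_end {self.p_end}"
            )
        if self.p_start < 1:
            raise ValueError(f"hit on {self.gene_id}: protein coordinates are 1-based")


@dataclass
class NBSRecord:
    """A gene with at least one NB-ARC domain, its architecture code and type."""

    gene: GeneModel
    hits: list[DomainHit]
    code: str
    nbs_type: NBSType

    @property
    def gene_id(self) -> str:
        return self.gene.gene_id


@dataclass
class TypeCensus:
    """Per-species count and percentage of each NBS type."""

    species: str
    counts: dict[NBSType, int]
    percentages: dict[NBSType, float]
    total: int


@dataclass
class GeneCluster:
    """A maximal chain of NBS genes linked by the 200-kb adjacency rule."""

    seq_id: str
    member_ids: list[str]
    span_start: int
    span_end: int

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class ClusterSummary:
    species: str
    n_genes: int
    n_cluster_genes: int
    proportion_cluster_genes: float
    n_clusters: int
    mean_members: float
    mean_members_defined: bool = True


@dataclass
class ExonSummary:
    species: str
    mean_overall: float
    mean_by_type: dict[NBSType, float]
    n_by_type: dict[NBSType, int]


@dataclass
class SimilarityRecord:
    """Aligned gene pair with identity-based distance.

    ``matched_length`` counts alignment columns carrying a residue in both
    rows; distance is one minus the fraction of those columns that are
    identical, and similarity is one minus the distance.
    """

    gene_a: str
    gene_b: str
    matched_length: int
    distance: float
    similarity: float
    score: float = 0.0
    usable: bool = True


@dataclass
class ThresholdCensus:
    """Non-redundant gene counts of species A at descending similarity levels."""

    species_pair: tuple[str, str]
    thresholds: list[int]
    n_nonredundant: dict[int, int]
    proportion: dict[int, float]
    total_a: int


@dataclass
class Anchor:
    """A candidate collinear gene pair with per-chromosome order ranks."""

    gene_a: str
    gene_b: str
    seq_a: str
    seq_b: str
    rank_a: int
    rank_b: int
    score: float


@dataclass
class SyntenyBlock:
    seq_a: str
    seq_b: str
    pairs: list[Anchor]
    orientation: str  # "same" or "inverted"

    @property
    def size(self) -> int:
        return len(self.pairs)


@dataclass
class SyntenySummary:
    n_blocks: int
    n_pairs: int
    n_syntenic_a: int
    n_syntenic_b: int
    proportion_a: float
    proportion_b: float


@dataclass
class GenomeConfig:
    """Parameters of one synthetic diploid NBS gene complement.

    ``type_proportions`` must sum to one; ``cluster_fraction`` is the target
    fraction of genes placed inside physical clusters under the 200-kb rule.
    ``species_divergence`` mutates the shared per-class seed motifs into
    species-private motifs; ``gene_noise`` adds per-gene variation on top.
    """

    species_name: str
    n_chromosomes: int
    n_nbs_genes: int
    type_proportions: dict[NBSType, float]
    cluster_fraction: float
    exon_mean_by_type: dict[NBSType, float]
    seed: int
    cluster_size_p: float = 0.45
    species_divergence: float = 0.25
    gene_noise: float = 0.15
    chrom_prefix: str = "Chr"
    chromosome_length_bp: int | None = None

    def __post_init__(self) -> None:
        s = sum(self.type_proportions.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"type_proportions sum to {s}, expected 1")
        if not 0.0 <= self.cluster_fraction <= 1.0:
            raise ValueError("cluster_fraction must be in [0, 1]")


@dataclass
class TetraploidConfig:
    """Parameters deriving an allotetraploid from two diploid parents.

    ``inheritance_bias`` is the fraction of the tetraploid gene complement
    descending from ``parent_a``; divergences are per-site substitution
    probabilities applied to inherited proteins.
    """

    species_name: str
    inheritance_bias: float
    divergence_a: float
    divergence_d: float
    seed: int
    loss_fraction: float = 0.0
    duplication_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.inheritance_bias <= 1.0:
            raise ValueError("inheritance_bias must be in [0, 1]")
        for d in (self.divergence_a, self.divergence_d):
            if not 0.0 <= d <= 0.6:
                raise ValueError("divergence must be in [0, 0.6]")


@dataclass
class SyntheticGenome:
    """In-memory product of the generator, convertible to on-disk formats."""

    species: str
    genes: list[GeneModel]
    hits: list[DomainHit]
    true_types: dict[str, NBSType]
    groups: dict[str, int] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)
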
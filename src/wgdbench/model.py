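"""Core in-memory containers shared across the toolkit.

Everything here is a plain, hashable-where-sensible dataclass: proteomes,
similarity hits, reciprocal ortholog pairs, predicted orthogroups, and the
curated homolog "pillars" (pre-WGD genes plus the two post-WGD tracks) that
serve as evaluation truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field

POST_WGD_SLOTS = 3  # post-WGD species in the clade; 2 tracks -> 6 gene slots
LOSS_CLASSES = ("0", "I", "II", "III", "IV")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: a gene id, its species, and an amino-acid sequence."""

    gene_id: str
    species_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


class SpeciesMap:
    """Resolves every gene id to exactly one species, with optional
    pre-WGD / post-WGD lineage flags."""

    def __init__(
        self,
        gene_to_species: dict[str, str] | None = None,
        pre_species: set[str] | None = None,
        post_species: set[str] | None = None,
    ):
        self._gene_to_species: dict[str, str] = dict(gene_to_species or {})
        self.pre_species: set[str] = set(pre_species or ())
        self.post_species: set[str] = set(post_species or ())

    @classmethod
    def from_records(cls, records) -> "SpeciesMap":
        sm = cls()
        for rec in records:
            sm.add(rec.gene_id, rec.species_id)
        return sm

    def add(self, gene_id: str, species_id: str) -> None:
        existing = self._gene_to_species.get(gene_id)
        if existing is not None and existing != species_id:
            raise ValueError(
                f"gene id {gene_id!r} maps to both species "
                f"{existing!r} and {species_id!r}"
            )
        self._gene_to_species[gene_id] = species_id

    def species_of(self, gene_id: str) -> str:
        try:
            return self._gene_to_species[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._gene_to_species

    def __len__(self) -> int:
        return len(self._gene_to_species)

    @property
    def species(self) -> set[str]:
        return set(self._gene_to_species.values())

    def genes(self):
        return self._gene_to_species.keys()

    def restrict(self, species_subset) -> "SpeciesMap":
        """A new map containing only genes of the given species."""
        keep = set(species_subset)
        return SpeciesMap(
            {g: s for g, s in self._gene_to_species.items() if s in keep},
            self.pre_species & keep,
            self.post_species & keep,
        )


@dataclass(frozen=True)
class SimilarityHit:
    """One row of an all-vs-all similarity search (12-column tabular dialect)."""

    query_id: str
    subject_id: str
    pident: float
    aln_length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float


@dataclass(frozen=True)
class OrthologPair:
    """An unordered reciprocal pair of genes from two species.

    ``support`` is the mean bitscore for RBH pairs and the evolutionary
    distance for RSD pairs. gene_x is always the lexicographically smaller id.
    """

    gene_x: str
    gene_y: str
    support: float
    method: str  # "rbh" | "rsd"

    def __post_init__(self):
        x, y = self.gene_x, self.gene_y
        if x == y:
            raise ValueError(f"self-pair {x!r}")
        if x > y:
            object.__setattr__(self, "gene_x", y)
            object.__setattr__(self, "gene_y", x)

    @property
    def genes(self) -> tuple[str, str]:
        return (self.gene_x, self.gene_y)


@dataclass(frozen=True)
class Orthogroup:
    """A predicted set of genes; native cRBH/cRSD groups hold at most one
    gene per species, imported third-party groups may not (multi_copy)."""

    group_id: str
    members: frozenset[str]
    multi_copy: bool = False

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GoldPillar:
    """One curated homologous group: up to one gene per pre-WGD species and
    up to two genes (track A / track B) per post-WGD species."""

    pillar_id: str
    pre_genes: dict[str, str] = field(default_factory=dict)
    track_a: dict[str, str] = field(default_factory=dict)
    track_b: dict[str, str] = field(default_factory=dict)
    loss_class: str = "unclassified"

    def all_genes(self) -> set[str]:
        return (
            set(self.pre_genes.values())
            | set(self.track_a.values())
            | set(self.track_b.values())
        )

    def restrict(self, species_subset) -> "GoldPillar":
        keep = set(species_subset)
        return GoldPillar(
            self.pillar_id,
            {s: g for s, g in self.pre_genes.items() if s in keep},
            {s: g for s, g in self.track_a.items() if s in keep},
            {s: g for s, g in self.track_b.items() if s in keep},
            self.loss_class,
        )


@dataclass(frozen=True)
class GoldSubgroup:
    """One single-copy half of a pillar: the pre-WGD genes plus one track."""

    pillar_id: str
    track: str  # "A" | "B"
    members: frozenset[str]

    @property
    def subgroup_id(self) -> str:
        return f"{self.pillar_id}:{self.track}"


@dataclass(frozen=True)
class GroupMatch:
    """Best gold-subgroup match for one test group."""

    group_id: str
    subgroup_id: str | None
    shared: int
    status: str  # "defined" | "undefined"
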
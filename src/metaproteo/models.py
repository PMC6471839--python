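"""Core domain types shared across the pipeline.

The atomic unit of quantitation throughout is the spectral count: one
peptide-spectrum match (PSM) contributes one count to whatever feature
(protein group, metacluster, taxon) its peptide is assigned to.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

RANKS = ("family", "genus", "species", "strain")

#: Gene names matching this pattern are auto-generated locus tags, not
#: characterized gene names, and therefore do not count as useful
#: annotation nor form gene-name edges between protein groups.
DEFAULT_LOCUS_TAG_PATTERN = r"^[A-Z]{1,4}_?\d{3,}$"


def is_characterized(gene_name: Optional[str],
                     locus_tag_pattern: str = DEFAULT_LOCUS_TAG_PATTERN) -> bool:
    """True if ``gene_name`` is a characterized gene name.

    A characterized name is non-empty and does not look like an
    auto-generated locus tag (e.g. ``BL_1034``).
    """
    if not gene_name:
        return False
    return re.match(locus_tag_pattern, gene_name) is None


@dataclass(frozen=True, order=True)
class Lineage:
    """Ordered taxonomic lineage family -> genus -> species -> strain."""

    family: str
    genus: str
    species: str
    strain: str

    def at(self, rank: str) -> str:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return getattr(self, rank)

    def as_tuple(self) -> tuple[str, str, str, str]:
        return (self.family, self.genus, self.species, self.strain)


@dataclass(frozen=True)
class ProteinRecord:
    """One database sequence with its annotation and provenance flags."""

    accession: str
    sequence: str
    gene_name: str = ""  # empty string = no annotation
    uniref50_id: str = ""
    lineage: Optional[Lineage] = None
    is_decoy: bool = False
    is_host: bool = False

    def has_useful_annotation(
            self, locus_tag_pattern: str = DEFAULT_LOCUS_TAG_PATTERN) -> bool:
        return is_characterized(self.gene_name, locus_tag_pattern)


@dataclass(frozen=True)
class PSM:
    """One identified spectrum: a stripped peptide matched in one sample.

    ``matched_accessions`` lists every database protein (target or decoy)
    compatible with the peptide; a PSM whose matches are all decoys is a
    decoy hit for FDR purposes.
    """

    spectrum_id: str
    subject_id: str
    peptide: str
    matched_accessions: frozenset[str]
    score: float

    def __post_init__(self):
        if not self.peptide:
            raise ValueError("PSM peptide must be non-empty")
        if not self.matched_accessions:
            raise ValueError(
                f"PSM {self.spectrum_id}: matched_accessions must be non-empty")


@dataclass
class FdrResult:
    """Outcome of target-decoy filtering at a chosen score threshold."""

    score_threshold: float
    n_target: int
    n_decoy: int
    fdr: float


@dataclass
class ProteinGroup:
    """A parsimony-reported protein: indistinguishable members + evidence."""

    group_id: str
    member_accessions: tuple[str, ...]
    peptide_set: frozenset[str]
    is_host: bool = False
    # subject id -> spectral count, filled by assign_spectral_counts
    spectral_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.peptide_set:
            raise ValueError(f"group {self.group_id} has empty peptide set")


@dataclass
class Metacluster:
    """Connected component of protein groups under the homology relations.

    Groups are linked when they share a characterized gene name, share
    peptide evidence, or share a UniRef50 cluster id; a metacluster is one
    component under the transitive closure of those mixed edges and is
    treated as a single functional feature across taxa.
    """

    metacluster_id: str
    group_ids: tuple[str, ...]
    member_accessions: tuple[str, ...]
    gene_names: frozenset[str]
    uniref50_ids: frozenset[str]
    has_useful_annotation: bool
    is_host: bool
    #: number of member proteins flagged host; a value strictly between 0
    #: and the member count marks an (invalid) mixed-stratum cluster
    n_host_members: int
    peptide_set: frozenset[str]
    # peptides assignable only to this metacluster; by the partition property
    # of shared-peptide closure this equals peptide_set on every run
    unique_peptide_set: frozenset[str] = frozenset()
    spectral_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class CorrelationResult:
    """Spearman/Pearson agreement between two paired count vectors."""

    pair: tuple[str, str]
    spearman_rho: float
    pearson_r: float
    r_squared: float
    n: int


@dataclass
class RankProfile:
    """Taxon x subject spectral counts from peptides unique at one rank."""

    rank: str
    matrix: "pandas.DataFrame"  # noqa: F821 - avoid hard import at type time
    unique_peptide_counts: "pandas.DataFrame"  # noqa: F821


@dataclass
class PathwayContrast:
    """Per-pathway treated-vs-untreated spectral-count comparison."""

    pathway_id: str
    # rows: (feature id, gene name, treated count, untreated mean, untreated sd,
    #        member verdict)
    rows: list[tuple[str, str, float, float, float, str]]
    verdict: str  # higher | lower | equivalent


class ProteinDatabase:
    """Indexed collection of :class:`ProteinRecord`.

    Provides accession lookup and a lazily built tryptic peptide index
    mapping each peptide to every database protein (target or decoy) whose
    in-silico digest contains it. The index is what makes shared-peptide
    relations and per-rank uniqueness queries cheap.
    """

    def __init__(self, records: Iterable[ProteinRecord],
                 max_missed_cleavages: int = 2,
                 min_peptide_len: int = 6,
                 max_peptide_len: int = 30):
        self.records: list[ProteinRecord] = list(records)
        self.by_accession: dict[str, ProteinRecord] = {}
        for rec in self.records:
            if rec.accession in self.by_accession:
                raise ValueError(f"duplicate accession {rec.accession!r}")
            self.by_accession[rec.accession] = rec
        self.max_missed_cleavages = max_missed_cleavages
        self.min_peptide_len = min_peptide_len
        self.max_peptide_len = max_peptide_len
        self._peptide_index: Optional[dict[str, set[str]]] = None
        self._digests: Optional[dict[str, tuple[str, ...]]] = None

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, accession: str) -> bool:
        return accession in self.by_accession

    def __getitem__(self, accession: str) -> ProteinRecord:
        return self.by_accession[accession]

    @property
    def targets(self) -> list[ProteinRecord]:
        return [r for r in self.records if not r.is_decoy]

    @property
    def decoys(self) -> list[ProteinRecord]:
        return [r for r in self.records if r.is_decoy]

    def digest_of(self, accession: str) -> tuple[str, ...]:
        """Sorted tryptic peptides of one protein (cached)."""
        from .simulate import digest  # local import to avoid a cycle
        if self._digests is None:
            self._digests = {}
        if accession not in self._digests:
            rec = self.by_accession[accession]
            self._digests[accession] = tuple(sorted(digest(
                rec.sequence,
                max_missed_cleavages=self.max_missed_cleavages,
                min_len=self.min_peptide_len,
                max_len=self.max_peptide_len)))
        return self._digests[accession]

    @property
    def peptide_index(self) -> Mapping[str, set[str]]:
        """peptide -> set of accessions (targets and decoys) containing it."""
        if self._peptide_index is None:
            index: dict[str, set[str]] = {}
            for rec in self.records:
                for pep in self.digest_of(rec.accession):
                    index.setdefault(pep, set()).add(rec.accession)
            self._peptide_index = index
        return self._peptide_index

    def accessions_for_peptide(self, peptide: str,
                               include_decoys: bool = True) -> set[str]:
        accs = self.peptide_index.get(peptide, set())
        if include_decoys:
            return set(accs)
        return {a for a in accs if not self.by_accession[a].is_decoy}
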
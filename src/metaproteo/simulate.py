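"""Synthetic multi-subject gut-community metaproteome generator.

Emulates the data structure a shotgun metaproteomics study of infant fecal
samples produces: a custom protein database spanning strains of a handful of
genera plus host proteins and reversed decoys, per-subject PSM tables drawn
by spectral counting from a known community composition, a noisy 16S
genus-level read-count table over the same truth, and a gene-to-pathway
annotation table. Ground truth is retained so downstream stages can be
tested as parameter-recovery problems.

The default community preset ships eight subjects shaped like a typical
infant cohort: most subjects dominated by *Bifidobacterium*, one
*Enterobacteriaceae*-dominated antibiotic-treated subject, and a
monozygotic twin pair with identical profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pyteomics import parser as _pyt_parser

from .models import (RANKS, Lineage, ProteinRecord, ProteinDatabase, PSM,
                     is_characterized)

#: Trypsin cleaves C-terminal to K or R except when the next residue is P.
TRYPSIN_RULE = r"[KR](?!P)"

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Residue sampling weights for synthetic sequences. K+R get ~11% combined
#: mass so tryptic peptides average a realistic ~9 residues.
_AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_WEIGHTS = np.array([
    8.3, 1.4, 5.5, 6.8, 3.9, 7.1, 2.3, 6.0, 5.9, 9.7,
    2.4, 4.1, 4.7, 3.9, 5.5, 6.6, 5.4, 6.9, 1.1, 2.9])
_AA_WEIGHTS = _AA_WEIGHTS / _AA_WEIGHTS.sum()

HOST_LINEAGE = Lineage(family="Hominidae", genus="Homo",
                       species="Homo sapiens", strain="Homo sapiens")
DECOY_PREFIX = "DECOY_"


def digest(sequence: str, max_missed_cleavages: int = 2,
           min_len: int = 6, max_len: int = 30,
           alphabet: frozenset[str] = STANDARD_AA) -> set[str]:
    """In-silico tryptic digest of a protein sequence.

    Cleaves C-terminal to K/R except before P, keeps every product with up
    to ``max_missed_cleavages`` internal missed cleavage sites, filters by
    length, and deduplicates.

    Parameters
    ----------
    alphabet
        Allowed residue characters. Exposed so tests can admit placeholder
        residues; defaults to the 20 standard amino acids.
    """
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - alphabet
    if bad:
        raise ValueError(
            f"invalid residue characters {sorted(bad)} in sequence")
    if max_missed_cleavages < 0:
        raise ValueError("max_missed_cleavages must be >= 0")
    peps = _pyt_parser.cleave(sequence, TRYPSIN_RULE,
                              missed_cleavages=max_missed_cleavages)
    return {p for p in peps if min_len <= len(p) <= max_len}


def build_taxonomy(n_genera: int, species_per_genus: int,
                   strains_per_species: int, seed: int = 0) -> list[Lineage]:
    """Generate a balanced strain->species->genus->family taxonomy.

    Each genus sits in its own family; names are unique within every rank.
    The seed is accepted for interface symmetry with the other generators
    (the balanced tree itself is deterministic in the counts).
    """
    for name, val in (("n_genera", n_genera),
                      ("species_per_genus", species_per_genus),
                      ("strains_per_species", strains_per_species)):
        if val < 1:
            raise ValueError(f"{name} must be >= 1, got {val}")
    lineages = []
    for g in range(n_genera):
        genus = f"Genus{g + 1:02d}"
        family = f"Family{g + 1:02d}"
        for s in range(species_per_genus):
            species = f"{genus} species{s + 1:02d}"
            for t in range(strains_per_species):
                strain = f"{species} strain{t + 1:02d}"
                lineages.append(Lineage(family, genus, species, strain))
    return lineages


@dataclass
class ScoreModel:
    """Gaussian search-score model: targets score higher than decoy/noise."""

    mu_target: float = 60.0
    mu_decoy: float = 30.0
    sigma: float = 8.0

    def __post_init__(self):
        if self.mu_target <= self.mu_decoy:
            raise ValueError("mu_target must exceed mu_decoy")


@dataclass
class CommunitySpec:
    """Declarative description of a synthetic multi-subject community.

    ``profiles`` maps each subject to a strain -> relative-abundance map
    over microbial strains; abundances must sum to 1 per subject.
    ``depth`` is the target total spectral count per subject, either one
    integer for all subjects or a per-subject map.
    """

    subjects: list[str]
    profiles: dict[str, dict[str, float]]
    host_spectrum_fraction: float = 0.18
    depth: int | dict[str, int] = 20000
    decoy_hit_rate: float = 0.05
    homolog_family_count: int = 150
    gene_annotation_rate: float = 0.54
    seed: int = 0
    noise_sd_16s: float = 0.3
    proteins_per_strain: int = 30
    n_host_proteins: int = 40
    host_family_count: int = 12
    max_missed_cleavages: int = 2
    min_peptide_len: int = 6
    max_peptide_len: int = 30
    score_model: ScoreModel = field(default_factory=ScoreModel)

    def __post_init__(self):
        if not self.subjects:
            raise ValueError("at least one subject required")
        if set(self.subjects) != set(self.profiles):
            raise ValueError("profiles must cover exactly the subject list")
        for subj, prof in self.profiles.items():
            total = sum(prof.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"subject {subj}: abundances sum to {total}, not 1")
            if any(v < 0 for v in prof.values()):
                raise ValueError(f"subject {subj}: negative abundance")
        if not (0.0 <= self.host_spectrum_fraction < 1.0):
            raise ValueError("host_spectrum_fraction must be in [0, 1)")
        if not (0.0 <= self.decoy_hit_rate <= 0.1):
            raise ValueError("decoy_hit_rate must be in [0, 0.1]")
        if not (0.0 <= self.gene_annotation_rate <= 1.0):
            raise ValueError("gene_annotation_rate must be in [0, 1]")
        if self.homolog_family_count < 1:
            raise ValueError("homolog_family_count must be >= 1")
        if self.noise_sd_16s < 0:
            raise ValueError("noise_sd_16s must be >= 0")
        for subj in self.subjects:
            if self.depth_for(subj) < 1:
                raise ValueError(f"depth for subject {subj} must be >= 1")

    def depth_for(self, subject: str) -> int:
        if isinstance(self.depth, dict):
            return int(self.depth[subject])
        return int(self.depth)


@dataclass
class SyntheticTruth:
    """Ground truth retained from a simulation for recovery tests.

    ``abundances[rank]`` is a taxon x subject table of true microbial
    fractions; rollups are exact (species truth is the sum of its strains'
    truth, and so on up the ranks).
    """

    abundances: dict[str, pd.DataFrame]
    protein_partition: dict[str, str]  # accession -> homolog family id

    @property
    def genus_matrix(self) -> pd.DataFrame:
        return self.abundances["genus"]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    idx = rng.choice(len(_AA_ORDER), size=length, p=_AA_WEIGHTS)
    return "".join(_AA_ORDER[i] for i in idx)


def _mutate(rng: np.random.Generator, template: str,
            max_divergence: float = 0.15) -> str:
    """Point-mutate a family template, keeping >=80% sequence identity."""
    n = len(template)
    rate = rng.uniform(0.02, max_divergence)
    n_mut = min(int(rng.binomial(n, rate)), int(0.2 * n))
    if n_mut == 0:
        return template
    positions = rng.choice(n, size=n_mut, replace=False)
    seq = list(template)
    for pos in positions:
        choices = [a for a in _AA_ORDER if a != seq[pos]]
        seq[pos] = choices[rng.integers(len(choices))]
    return "".join(seq)


def _gene_name(rng: np.random.Generator, used: set[str]) -> str:
    """A characterized-style bacterial gene name, e.g. ``gltB``."""
    letters = "abcdefghijklmnopqrstuvwxyz"
    while True:
        name = ("".join(letters[rng.integers(26)] for _ in range(3))
                + chr(ord("A") + rng.integers(26)))
        if name not in used:
            used.add(name)
            return name


def _host_gene_name(rng: np.random.Generator, used: set[str]) -> str:
    while True:
        name = "".join(chr(ord("A") + rng.integers(26)) for _ in range(3))
        if name not in used:
            used.add(name)
            return name


def synthesize_proteomes(taxonomy: Sequence[Lineage],
                         proteins_per_strain: int,
                         homolog_family_count: int,
                         gene_annotation_rate: float,
                         seed: int,
                         n_host_proteins: int = 40,
                         host_family_count: int = 12) -> list[ProteinRecord]:
    """Generate a protein database with cross-taxon homolog structure.

    Every microbial protein belongs to one of ``homolog_family_count``
    UniRef50-like families; members of a family are point mutations of a
    shared template (>=80% identity), so homologs in different taxa share
    most tryptic peptides. A fraction ``gene_annotation_rate`` of families
    carries a shared characterized gene name; the rest carry either an
    auto-generated locus tag or no name at all. Host proteins form their
    own families under a *Homo sapiens* lineage and are always annotated.
    For every target protein a reversed-sequence decoy twin is emitted.
    """
    if not taxonomy:
        raise ValueError("taxonomy must be non-empty")
    if homolog_family_count < 1:
        raise ValueError("homolog_family_count must be >= 1")
    rng = np.random.default_rng([int(seed) % (2**31), 11])

    # family templates + annotation
    templates = [_random_sequence(rng, int(rng.integers(150, 350)))
                 for _ in range(homolog_family_count)]
    used_names: set[str] = set()
    n_annotated = int(round(gene_annotation_rate * homolog_family_count))
    annotated = set(rng.choice(homolog_family_count,
                               size=n_annotated, replace=False).tolist())
    family_gene = {f: _gene_name(rng, used_names) if f in annotated else ""
                   for f in range(homolog_family_count)}

    records: list[ProteinRecord] = []
    acc_counter = 0
    for lineage in taxonomy:
        for _ in range(proteins_per_strain):
            fam = int(rng.integers(homolog_family_count))
            acc_counter += 1
            records.append(ProteinRecord(
                accession=f"SP{acc_counter:06d}",
                sequence=_mutate(rng, templates[fam]),
                gene_name=family_gene[fam],
                uniref50_id=f"UniRef50_F{fam:05d}",
                lineage=lineage,
                is_decoy=False, is_host=False))

    # host proteins: disjoint sequences, own families, always annotated
    host_templates = [_random_sequence(rng, int(rng.integers(150, 350)))
                      for _ in range(host_family_count)]
    host_used: set[str] = set()
    host_gene = {f: _host_gene_name(rng, host_used)
                 for f in range(host_family_count)}
    for i in range(n_host_proteins):
        fam = i % host_family_count
        acc_counter += 1
        records.append(ProteinRecord(
            accession=f"HP{acc_counter:06d}",
            sequence=_mutate(rng, host_templates[fam]),
            gene_name=host_gene[fam],
            uniref50_id=f"UniRef50_H{fam:05d}",
            lineage=HOST_LINEAGE,
            is_decoy=False, is_host=True))

    decoys = [ProteinRecord(
        accession=DECOY_PREFIX + rec.accession,
        sequence=rec.sequence[::-1],
        gene_name=rec.gene_name,
        uniref50_id=rec.uniref50_id,
        lineage=rec.lineage,
        is_decoy=True, is_host=rec.is_host) for rec in records]
    return records + decoys


def _truth_from_profiles(spec: CommunitySpec,
                         taxonomy: Sequence[Lineage]) -> dict[str, pd.DataFrame]:
    by_strain = {lin.strain: lin for lin in taxonomy}
    strain_df = pd.DataFrame(
        {subj: pd.Series(spec.profiles[subj], dtype=float)
         for subj in spec.subjects}).fillna(0.0)
    strain_df = strain_df.sort_index()
    abund = {"strain": strain_df}
    for rank in ("species", "genus", "family"):
        mapping = {s: by_strain[s].at(rank) for s in strain_df.index}
        abund[rank] = strain_df.groupby(mapping).sum().sort_index()
    return abund


def sample_psms(spec: CommunitySpec,
                proteomes: Sequence[ProteinRecord],
                taxonomy: Sequence[Lineage]
                ) -> tuple[dict[str, list[PSM]], SyntheticTruth]:
    """Draw per-subject PSM tables by spectral counting from the truth.

    Each of the ``depth`` spectra of a subject is a decoy hit with
    probability ``decoy_hit_rate``; otherwise it is host with probability
    ``host_spectrum_fraction`` or microbial. A microbial spectrum picks a
    strain by abundance, a protein uniformly within the strain, and a
    tryptic peptide uniformly within the protein. The PSM's matches list
    every database protein whose digest contains the peptide; decoy hits
    match decoys only and draw scores from the low-scoring distribution.
    """
    if isinstance(proteomes, ProteinDatabase):
        db = proteomes  # reuse a prebuilt digest index (replicate studies)
    else:
        db = ProteinDatabase(proteomes,
                             max_missed_cleavages=spec.max_missed_cleavages,
                             min_peptide_len=spec.min_peptide_len,
                             max_peptide_len=spec.max_peptide_len)
    db.peptide_index  # force index construction once

    microbial = [r for r in db.targets
                 if not r.is_host and db.digest_of(r.accession)]
    host = [r for r in db.targets
            if r.is_host and db.digest_of(r.accession)]
    decoys = [r for r in db.decoys if db.digest_of(r.accession)]
    if not microbial:
        raise ValueError("proteomes contain no digestible microbial protein")
    if spec.host_spectrum_fraction > 0 and not host:
        raise ValueError("host spectra requested but no host protein present")
    if spec.decoy_hit_rate > 0 and not decoys:
        raise ValueError("decoy hits requested but no decoy present")

    by_strain: dict[str, list[ProteinRecord]] = {}
    for rec in microbial:
        by_strain.setdefault(rec.lineage.strain, []).append(rec)

    sm = spec.score_model
    psms: dict[str, list[PSM]] = {}
    for si, subj in enumerate(spec.subjects):
        rng = np.random.default_rng([int(spec.seed) % (2**31), 23, si])
        depth = spec.depth_for(subj)
        prof = spec.profiles[subj]
        strains = sorted(s for s, a in prof.items() if a > 0)
        missing = [s for s in strains if s not in by_strain]
        if missing:
            raise ValueError(
                f"subject {subj}: no proteins for strains {missing}")
        p_strain = np.array([prof[s] for s in strains], dtype=float)
        p_strain = p_strain / p_strain.sum()

        p_decoy = spec.decoy_hit_rate
        p_host = (1 - p_decoy) * spec.host_spectrum_fraction
        cats = rng.choice(3, size=depth,
                          p=[p_decoy, p_host, 1 - p_decoy - p_host])
        strain_idx = rng.choice(len(strains), size=depth, p=p_strain)
        u_protein = rng.random(depth)
        u_peptide = rng.random(depth)
        scores_t = rng.normal(sm.mu_target, sm.sigma, size=depth)
        scores_d = rng.normal(sm.mu_decoy, sm.sigma, size=depth)

        rows: list[PSM] = []
        for i in range(depth):
            cat = cats[i]
            if cat == 0:  # decoy hit
                rec = decoys[int(u_protein[i] * len(decoys))]
                peps = db.digest_of(rec.accession)
                pep = peps[int(u_peptide[i] * len(peps))]
                matches = frozenset(
                    a for a in db.accessions_for_peptide(pep)
                    if db[a].is_decoy)
                score = scores_d[i]
            else:
                if cat == 1:  # host
                    pool = host
                    rec = pool[int(u_protein[i] * len(pool))]
                else:
                    pool = by_strain[strains[strain_idx[i]]]
                    rec = pool[int(u_protein[i] * len(pool))]
                peps = db.digest_of(rec.accession)
                pep = peps[int(u_peptide[i] * len(peps))]
                matches = frozenset(db.accessions_for_peptide(pep))
                score = scores_t[i]
            rows.append(PSM(spectrum_id=f"{subj}_S{i + 1:06d}",
                            subject_id=subj, peptide=pep,
                            matched_accessions=matches,
                            score=round(float(score), 4)))
        psms[subj] = rows

    truth = SyntheticTruth(
        abundances=_truth_from_profiles(spec, taxonomy),
        protein_partition={r.accession: r.uniref50_id
                           for r in microbial})
    return psms, truth


def sample_16s(truth: SyntheticTruth, read_depth: int,
               noise_sd_16s: float, seed: int) -> pd.DataFrame:
    """Simulate a genus x subject 16S read-count table.

    Per subject, expected reads are proportional to true genus abundance
    times multiplicative lognormal noise; counts are multinomial at
    ``read_depth`` total reads.
    """
    if read_depth < 1:
        raise ValueError("read_depth must be >= 1")
    genus = truth.genus_matrix
    rng = np.random.default_rng([int(seed) % (2**31), 31])
    out = {}
    for subj in genus.columns:
        frac = genus[subj].to_numpy(dtype=float)
        noise = rng.lognormal(mean=0.0, sigma=noise_sd_16s, size=len(frac)) \
            if noise_sd_16s > 0 else np.ones(len(frac))
        w = frac * noise
        if w.sum() == 0:
            raise ValueError(f"subject {subj} has zero total abundance")
        out[subj] = rng.multinomial(read_depth, w / w.sum())
    return pd.DataFrame(out, index=genus.index)


def make_pathway_table(proteomes: Sequence[ProteinRecord],
                       n_pathways: int = 3, seed: int = 0) -> pd.DataFrame:
    """Assign characterized microbial gene names to synthetic pathways.

    Returns a two-column (pathway_id, gene_name) table, the offline
    stand-in for a gene-to-pathway mapping service.
    """
    genes = sorted({r.gene_name for r in proteomes
                    if not r.is_decoy and not r.is_host
                    and is_characterized(r.gene_name)})
    rng = np.random.default_rng([int(seed) % (2**31), 41])
    order = rng.permutation(len(genes))
    rows = [(f"PWY{(i % n_pathways) + 1:04d}", genes[j])
            for i, j in enumerate(order)]
    return (pd.DataFrame(rows, columns=["pathway_id", "gene_name"])
            .sort_values(["pathway_id", "gene_name"])
            .reset_index(drop=True))


# ---------------------------------------------------------------------------
# Default community preset: eight infant subjects
# ---------------------------------------------------------------------------

_PRESET_TAXA: list[tuple[str, str, str, list[str]]] = [
    # (family, genus, species, strain suffixes)
    ("Bifidobacteriaceae", "Bifidobacterium", "Bifidobacterium breve",
     ["NCB1", "NCB2"]),
    ("Bifidobacteriaceae", "Bifidobacterium", "Bifidobacterium longum",
     ["INF1", "LON1"]),
    ("Bifidobacteriaceae", "Bifidobacterium", "Bifidobacterium bifidum",
     ["BIF1", "BIF2"]),
    ("Bifidobacteriaceae", "Bifidobacterium",
     "Bifidobacterium pseudocatenulatum", ["PSC1", "PSC2"]),
    ("Bacteroidaceae", "Bacteroides", "Bacteroides fragilis",
     ["FRA1", "FRA2"]),
    ("Bacteroidaceae", "Bacteroides", "Bacteroides vulgatus", ["VUL1"]),
    ("Tannerellaceae", "Parabacteroides", "Parabacteroides distasonis",
     ["DIS1", "DIS2"]),
    ("Veillonellaceae", "Veillonella", "Veillonella parvula",
     ["PAR1", "PAR2"]),
    ("Lactobacillaceae", "Lactobacillus", "Lactobacillus gasseri",
     ["GAS1", "GAS2"]),
    ("Enterobacteriaceae", "Klebsiella", "Klebsiella pneumoniae",
     ["PNE1", "PNE2"]),
    ("Enterobacteriaceae", "Klebsiella", "Klebsiella oxytoca", ["OXY1"]),
    ("Enterobacteriaceae", "Escherichia", "Escherichia coli",
     ["COL1", "COL2"]),
    ("Enterobacteriaceae", "Citrobacter", "Citrobacter freundii", ["FRE1"]),
    ("Streptococcaceae", "Streptococcus", "Streptococcus salivarius",
     ["SAL1"]),
    ("Enterococcaceae", "Enterococcus", "Enterococcus faecalis", ["FAE1"]),
]

#: Genus-level relative abundances per subject. R is the antibiotic-treated
#: subject dominated by Enterobacteriaceae genera; M and N are identical
#: twins; P carries Parabacteroides on par with Bifidobacterium.
_PRESET_GENUS_WEIGHTS: dict[str, dict[str, float]] = {
    "C": {"Bifidobacterium": .70, "Bacteroides": .08, "Parabacteroides": .04,
          "Veillonella": .05, "Lactobacillus": .04, "Klebsiella": .02,
          "Escherichia": .02, "Citrobacter": .01, "Streptococcus": .02,
          "Enterococcus": .02},
    "T": {"Bifidobacterium": .55, "Bacteroides": .20, "Parabacteroides": .05,
          "Veillonella": .05, "Lactobacillus": .03, "Klebsiella": .03,
          "Escherichia": .03, "Citrobacter": .01, "Streptococcus": .03,
          "Enterococcus": .02},
    "B": {"Bifidobacterium": .65, "Bacteroides": .10, "Parabacteroides": .05,
          "Veillonella": .06, "Lactobacillus": .04, "Klebsiella": .03,
          "Escherichia": .02, "Citrobacter": .01, "Streptococcus": .02,
          "Enterococcus": .02},
    "P": {"Bifidobacterium": .35, "Bacteroides": .10, "Parabacteroides": .30,
          "Veillonella": .05, "Lactobacillus": .04, "Klebsiella": .05,
          "Escherichia": .04, "Citrobacter": .02, "Streptococcus": .03,
          "Enterococcus": .02},
    "M": {"Bifidobacterium": .62, "Bacteroides": .08, "Parabacteroides": .04,
          "Veillonella": .07, "Lactobacillus": .05, "Klebsiella": .04,
          "Escherichia": .03, "Citrobacter": .01, "Streptococcus": .04,
          "Enterococcus": .02},
    "N": {"Bifidobacterium": .62, "Bacteroides": .08, "Parabacteroides": .04,
          "Veillonella": .07, "Lactobacillus": .05, "Klebsiella": .04,
          "Escherichia": .03, "Citrobacter": .01, "Streptococcus": .04,
          "Enterococcus": .02},
    "E": {"Bifidobacterium": .60, "Bacteroides": .12, "Parabacteroides": .05,
          "Veillonella": .05, "Lactobacillus": .05, "Klebsiella": .04,
          "Escherichia": .03, "Citrobacter": .01, "Streptococcus": .03,
          "Enterococcus": .02},
    "R": {"Bifidobacterium": .03, "Bacteroides": .05, "Parabacteroides": .02,
          "Veillonella": .03, "Lactobacillus": .02, "Klebsiella": .45,
          "Escherichia": .20, "Citrobacter": .10, "Streptococcus": .05,
          "Enterococcus": .05},
}

#: Within-Bifidobacterium species emphasis per subject (B. breve dominates
#: in most, B. longum in the young breastfed subject C, B.
#: pseudocatenulatum in the C-section subject P, B. bifidum second in the
#: twins). Other genera split evenly across their species.
_PRESET_BIFIDO_SPECIES: dict[str, dict[str, float]] = {
    "C": {"Bifidobacterium breve": .25, "Bifidobacterium longum": .55,
          "Bifidobacterium bifidum": .10,
          "Bifidobacterium pseudocatenulatum": .10},
    "P": {"Bifidobacterium breve": .25, "Bifidobacterium longum": .15,
          "Bifidobacterium bifidum": .10,
          "Bifidobacterium pseudocatenulatum": .50},
    "M": {"Bifidobacterium breve": .55, "Bifidobacterium longum": .10,
          "Bifidobacterium bifidum": .25,
          "Bifidobacterium pseudocatenulatum": .10},
    "N": {"Bifidobacterium breve": .55, "Bifidobacterium longum": .10,
          "Bifidobacterium bifidum": .25,
          "Bifidobacterium pseudocatenulatum": .10},
}
_PRESET_BIFIDO_DEFAULT = {
    "Bifidobacterium breve": .55, "Bifidobacterium longum": .20,
    "Bifidobacterium bifidum": .15,
    "Bifidobacterium pseudocatenulatum": .10}


def preset_taxonomy() -> list[Lineage]:
    """The default infant-community taxonomy (15 species, 25 strains)."""
    lineages = []
    for family, genus, species, strains in _PRESET_TAXA:
        for suffix in strains:
            lineages.append(Lineage(family, genus, species,
                                    f"{species} {suffix}"))
    return lineages


def default_community(seed: int = 0, depth: int = 20000,
                      **overrides) -> tuple[CommunitySpec, list[Lineage]]:
    """Build the 8-subject infant community preset.

    Keyword overrides are forwarded to :class:`CommunitySpec`.
    """
    taxonomy = preset_taxonomy()
    by_species: dict[str, list[str]] = {}
    species_of_genus: dict[str, list[str]] = {}
    for lin in taxonomy:
        by_species.setdefault(lin.species, []).append(lin.strain)
        if lin.species not in species_of_genus.setdefault(lin.genus, []):
            species_of_genus[lin.genus].append(lin.species)

    profiles: dict[str, dict[str, float]] = {}
    for subj, gw in _PRESET_GENUS_WEIGHTS.items():
        prof: dict[str, float] = {}
        for genus, g_ab in gw.items():
            if genus == "Bifidobacterium":
                sw = _PRESET_BIFIDO_SPECIES.get(subj, _PRESET_BIFIDO_DEFAULT)
            else:
                spp = species_of_genus[genus]
                sw = {sp: 1.0 / len(spp) for sp in spp}
            for sp, s_frac in sw.items():
                strains = by_species[sp]
                for strain in strains:
                    prof[strain] = prof.get(strain, 0.0) \
                        + g_ab * s_frac / len(strains)
        total = sum(prof.values())
        profiles[subj] = {k: v / total for k, v in sorted(prof.items())}

    spec = CommunitySpec(subjects=list(_PRESET_GENUS_WEIGHTS),
                         profiles=profiles, depth=depth, seed=seed,
                         **overrides)
    return spec, taxonomy
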
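"""Per-rank taxonomic profiling from uniquely assignable peptides.

A peptide is unique at a rank (strain, species, genus, family) when every
non-decoy database protein containing it falls inside a single taxon of
that rank; uniqueness is evaluated independently per rank, so a peptide
shared between two strains of one species is unusable at strain rank but
still counts at species rank. Spectral counts of unique peptides build the
taxon x subject abundance profile.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .models import RANKS, ProteinDatabase, PSM, RankProfile

HOST_ROW = "host"


def peptide_uniqueness(peptide: str, database: ProteinDatabase,
                       rank: str) -> Optional[str]:
    """The single taxon owning ``peptide`` at ``rank``, or None if shared.

    Considers every non-decoy database protein containing the peptide
    (not just parsimony-reported ones): uniqueness is about possible
    assignment. Raises if the peptide is absent from the database digest.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    accs = database.accessions_for_peptide(peptide, include_decoys=False)
    if not accs:
        raise KeyError(f"peptide {peptide!r} not in any non-decoy protein")
    taxa = {database[a].lineage.at(rank) for a in accs}
    if len(taxa) == 1:
        return taxa.pop()
    return None


def build_rank_profile(psms: Sequence[PSM], database: ProteinDatabase,
                       rank: str, include_host_row: bool = False
                       ) -> RankProfile:
    """Taxon x subject spectral counts from peptides unique at ``rank``.

    Host-unique peptides are excluded from the microbial matrix; with
    ``include_host_row`` they appear as a separate ``host`` QC row.
    Shared peptides contribute nothing at this rank.
    """
    host_taxa = {rec.lineage.at(rank) for rec in database.targets
                 if rec.is_host and rec.lineage is not None}
    subjects = sorted({p.subject_id for p in psms})
    counts: dict[tuple[str, str], int] = {}
    unique_peps: dict[tuple[str, str], set[str]] = {}
    cache: dict[str, Optional[str]] = {}
    for psm in psms:
        pep = psm.peptide
        if pep not in cache:
            try:
                cache[pep] = peptide_uniqueness(pep, database, rank)
            except KeyError:
                cache[pep] = None  # decoy-only peptide: unusable
        taxon = cache[pep]
        if taxon is None:
            continue
        if taxon in host_taxa:
            if not include_host_row:
                continue
            taxon = HOST_ROW
        key = (taxon, psm.subject_id)
        counts[key] = counts.get(key, 0) + 1
        unique_peps.setdefault(key, set()).add(pep)

    taxa = sorted({t for t, _ in counts})
    matrix = pd.DataFrame(0, index=taxa, columns=subjects, dtype=int)
    pep_counts = pd.DataFrame(0, index=taxa, columns=subjects, dtype=int)
    for (taxon, subj), n in counts.items():
        matrix.at[taxon, subj] = n
    for (taxon, subj), peps in unique_peps.items():
        pep_counts.at[taxon, subj] = len(peps)
    return RankProfile(rank=rank, matrix=matrix,
                       unique_peptide_counts=pep_counts)


def strain_detection_tiers(profile: RankProfile,
                           thresholds: Sequence[int] = (1, 2, 5)
                           ) -> pd.DataFrame:
    """Per-subject counts of strains detected at >=1 / >=2 / >=5 spectra.

    Rows are monotone: each higher-confidence tier is a subset of the
    tiers below it.
    """
    matrix = profile.matrix.drop(index=HOST_ROW, errors="ignore")
    rows = {f">={t} unique spectra": (matrix >= t).sum(axis=0)
            for t in thresholds}
    return pd.DataFrame(rows).T.astype(int)


def species_rollup(strain_profile: RankProfile,
                   database: ProteinDatabase,
                   genus: Optional[str] = None,
                   normalize: bool = False) -> pd.DataFrame:
    """Sum strain-level spectral counts up to species.

    With ``genus`` given, restricts to that genus's species (raising if
    the genus is unknown to the database); ``normalize`` rescales each
    subject column to fractions.
    """
    strain_to_species = {}
    strain_to_genus = {}
    for rec in database.targets:
        if rec.lineage is not None and not rec.is_host:
            strain_to_species[rec.lineage.strain] = rec.lineage.species
            strain_to_genus[rec.lineage.strain] = rec.lineage.genus
    if genus is not None and genus not in set(strain_to_genus.values()):
        raise ValueError(f"unknown genus {genus!r}")

    matrix = strain_profile.matrix.drop(index=HOST_ROW, errors="ignore")
    if genus is not None:
        keep = [s for s in matrix.index if strain_to_genus.get(s) == genus]
        matrix = matrix.loc[keep]
    rolled = matrix.groupby(
        lambda s: strain_to_species[s]).sum().sort_index()
    if normalize:
        totals = rolled.sum(axis=0)
        rolled = rolled.div(totals.where(totals > 0, 1), axis=1)
    return rolled


def genus_rollup(strain_profile: RankProfile,
                 database: ProteinDatabase) -> pd.DataFrame:
    """Sum strain-level counts up to genus (for cross-method comparison).

    Note this differs from a genus-rank profile: here only strain-unique
    peptides contribute, whereas the genus-rank profile admits every
    genus-unique peptide.
    """
    strain_to_genus = {rec.lineage.strain: rec.lineage.genus
                       for rec in database.targets
                       if rec.lineage is not None and not rec.is_host}
    matrix = strain_profile.matrix.drop(index=HOST_ROW, errors="ignore")
    return matrix.groupby(lambda s: strain_to_genus[s]).sum().sort_index()


def abundant_strain_filter(profile: RankProfile,
                           min_spectra: int = 20) -> list[str]:
    """Strains reaching ``min_spectra`` in at least one subject."""
    matrix = profile.matrix.drop(index=HOST_ROW, errors="ignore")
    keep = matrix.max(axis=1) >= min_spectra
    return sorted(matrix.index[keep])
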
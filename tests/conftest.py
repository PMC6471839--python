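"""Shared fixtures: small and deep synthetic studies, record factories."""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

import metaproteo as mp
from metaproteo.models import Lineage, ProteinRecord


def make_lineage(family="F1", genus="G1", species="S1", strain="T1"):
    return Lineage(family, genus, species, strain)


def make_record(accession, sequence="AAAAKBBBBK", gene_name="",
                uniref50_id="", lineage=None, is_decoy=False,
                is_host=False):
    return ProteinRecord(accession=accession, sequence=sequence,
                         gene_name=gene_name, uniref50_id=uniref50_id,
                         lineage=lineage or make_lineage(),
                         is_decoy=is_decoy, is_host=is_host)


def random_tryptic_peptide(rng, length=7):
    """A tryptic peptide: no internal K/R/P, C-terminal K."""
    alphabet = "ACDEFGHILMNQSTVWY"
    return "".join(alphabet[rng.integers(len(alphabet))]
                   for _ in range(length - 1)) + "K"


def protein_from_peptides(accession, peptides, **kwargs):
    """A record whose 0-missed-cleavage digest is exactly ``peptides``."""
    return make_record(accession, sequence="".join(peptides), **kwargs)


def run_stages(db, psms, target_fdr=0.016):
    retained, fdr = mp.fdr_filter(psms, db, target_fdr)
    groups = mp.infer_protein_groups(retained, db)
    mp.assign_spectral_counts(groups, retained)
    clusters = mp.build_metaclusters(groups, db)
    counts = mp.count_metacluster_spectra(clusters, retained)
    return SimpleNamespace(retained=retained, fdr=fdr, groups=groups,
                           clusters=clusters, counts=counts)


@pytest.fixture(scope="session")
def small_study():
    """Complete 8-subject study at reduced scale (depth 2000/subject)."""
    spec, taxonomy = mp.default_community(
        seed=7, depth=2000, proteins_per_strain=10,
        homolog_family_count=40)
    proteomes = mp.synthesize_proteomes(
        taxonomy, spec.proteins_per_strain, spec.homolog_family_count,
        spec.gene_annotation_rate, spec.seed,
        n_host_proteins=spec.n_host_proteins,
        host_family_count=spec.host_family_count)
    db = mp.ProteinDatabase(proteomes)
    psms, truth = mp.sample_psms(spec, db, taxonomy)
    all_psms = [p for rows in psms.values() for p in rows]
    stages = run_stages(db, all_psms)
    return SimpleNamespace(spec=spec, taxonomy=taxonomy,
                           proteomes=proteomes, db=db,
                           psms_by_subject=psms, all_psms=all_psms,
                           truth=truth, **vars(stages))


@pytest.fixture(scope="session")
def deep_study():
    """Deep (20,000 spectra/subject) decoy-free study for recovery tests."""
    spec, taxonomy = mp.default_community(seed=1, depth=20000,
                                          decoy_hit_rate=0.0)
    proteomes = mp.synthesize_proteomes(
        taxonomy, spec.proteins_per_strain, spec.homolog_family_count,
        spec.gene_annotation_rate, spec.seed,
        n_host_proteins=spec.n_host_proteins,
        host_family_count=spec.host_family_count)
    db = mp.ProteinDatabase(proteomes)
    psms, truth = mp.sample_psms(spec, db, taxonomy)
    all_psms = [p for rows in psms.values() for p in rows]
    retained, fdr = mp.fdr_filter(all_psms, db, 0.016)
    return SimpleNamespace(spec=spec, taxonomy=taxonomy, db=db,
                           truth=truth, all_psms=all_psms,
                           retained=retained, fdr=fdr)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
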
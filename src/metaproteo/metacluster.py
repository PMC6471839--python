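"""Homology metaclustering of inferred protein groups.

Protein groups are linked when they share a characterized gene name
(case-insensitive), share peptide evidence, or share a UniRef50 cluster
id; metaclusters are the connected components under the transitive closure
of those mixed relations, computed independently of taxonomic assignment.
Host and microbial groups are clustered separately, so host peptide
evidence never bridges into bacterial clusters.
"""

from __future__ import annotations

import itertools
import logging
from typing import Sequence

import networkx as nx
import pandas as pd

from .models import (DEFAULT_LOCUS_TAG_PATTERN, Metacluster,
                     ProteinDatabase, ProteinGroup, PSM, is_characterized)

log = logging.getLogger("metaproteo")


def build_metaclusters(groups: Sequence[ProteinGroup],
                       database: ProteinDatabase,
                       min_shared_peptides: int = 1,
                       locus_tag_pattern: str = DEFAULT_LOCUS_TAG_PATTERN
                       ) -> list[Metacluster]:
    """Partition protein groups into metaclusters.

    Edges between two groups: (a) any two member proteins share a
    characterized gene name; (b) the groups' peptide sets share at least
    ``min_shared_peptides`` peptides; (c) any two members share a UniRef50
    id. Components are computed per host/microbial stratum; ids are
    assigned deterministically from the smallest member accession.
    """
    if not groups:
        raise ValueError("no protein groups to cluster")
    graph = nx.Graph()
    for g in groups:
        graph.add_node(g.group_id)
    by_id = {g.group_id: g for g in groups}

    def stratum(g: ProteinGroup) -> bool:
        return g.is_host

    # relation (a): shared characterized gene name, and (c): shared uniref
    gene_map: dict[str, list[str]] = {}
    uniref_map: dict[str, list[str]] = {}
    for g in groups:
        genes, unirefs = set(), set()
        for acc in g.member_accessions:
            rec = database[acc]
            if is_characterized(rec.gene_name, locus_tag_pattern):
                genes.add(rec.gene_name.lower())
            if rec.uniref50_id:
                unirefs.add(rec.uniref50_id)
        for key in genes:
            gene_map.setdefault((stratum(g), key), []).append(g.group_id)
        for key in unirefs:
            uniref_map.setdefault((stratum(g), key), []).append(g.group_id)
    for mapping in (gene_map, uniref_map):
        for members in mapping.values():
            for a, b in zip(members, members[1:]):
                graph.add_edge(a, b)

    # relation (b): shared peptide evidence
    if min_shared_peptides == 1:
        pep_map: dict[tuple[bool, str], list[str]] = {}
        for g in groups:
            for pep in g.peptide_set:
                pep_map.setdefault((stratum(g), pep), []).append(g.group_id)
        for members in pep_map.values():
            for a, b in zip(members, members[1:]):
                graph.add_edge(a, b)
    else:
        for g1, g2 in itertools.combinations(groups, 2):
            if stratum(g1) == stratum(g2) and \
                    len(g1.peptide_set & g2.peptide_set) >= min_shared_peptides:
                graph.add_edge(g1.group_id, g2.group_id)

    clusters = []
    for component in nx.connected_components(graph):
        members = sorted(component)
        accs = sorted({a for gid in members
                       for a in by_id[gid].member_accessions})
        genes = {database[a].gene_name for a in accs
                 if is_characterized(database[a].gene_name,
                                     locus_tag_pattern)}
        unirefs = {database[a].uniref50_id for a in accs
                   if database[a].uniref50_id}
        peptides = frozenset().union(
            *(by_id[gid].peptide_set for gid in members))
        clusters.append(Metacluster(
            metacluster_id=f"MC_{accs[0]}",
            group_ids=tuple(members),
            member_accessions=tuple(accs),
            gene_names=frozenset(genes),
            uniref50_ids=frozenset(unirefs),
            has_useful_annotation=bool(genes),
            is_host=all(database[a].is_host for a in accs),
            n_host_members=sum(database[a].is_host for a in accs),
            peptide_set=peptides,
            unique_peptide_set=peptides))
    # A peptide can occur by sequence coincidence in both a host and a
    # microbial protein; because the strata are clustered separately it
    # would otherwise belong to two metaclusters. Such peptides are
    # assigned to the microbial stratum (host is contaminant background),
    # keeping the peptide -> metacluster map a function.
    microbial_peps = frozenset().union(
        frozenset(), *(m.peptide_set for m in clusters if not m.is_host))
    for i, mc in enumerate(clusters):
        if mc.is_host and mc.peptide_set & microbial_peps:
            kept = mc.peptide_set - microbial_peps
            clusters[i] = Metacluster(
                **{**mc.__dict__, "peptide_set": kept,
                   "unique_peptide_set": kept})

    clusters.sort(key=lambda m: m.metacluster_id)
    assert sum(len(m.group_ids) for m in clusters) == len(groups)
    log.info("metaclustering: %d groups -> %d metaclusters",
             len(groups), len(clusters))
    return clusters


def peptide_to_metacluster(metaclusters: Sequence[Metacluster]
                           ) -> dict[str, str]:
    """The peptide -> metacluster map.

    Because shared-peptide edges are absorbed into components, every
    peptide belongs to exactly one metacluster within a stratum; a peptide
    may not map to two metaclusters (checked).
    """
    mapping: dict[str, str] = {}
    for mc in metaclusters:
        for pep in mc.peptide_set:
            prev = mapping.get(pep)
            if prev is not None and prev != mc.metacluster_id:
                raise AssertionError(
                    f"peptide {pep} maps to both {prev} and "
                    f"{mc.metacluster_id}: shared-peptide closure violated")
            mapping[pep] = mc.metacluster_id
    return mapping


def count_metacluster_spectra(metaclusters: Sequence[Metacluster],
                              psms: Sequence[PSM]) -> pd.DataFrame:
    """Metacluster x subject spectral-count matrix.

    A PSM contributes one count to the metacluster owning its peptide;
    within a component a shared peptide is counted once per spectrum, so
    column totals equal the number of retained PSMs.
    """
    mapping = peptide_to_metacluster(metaclusters)
    subjects = sorted({p.subject_id for p in psms})
    counts = pd.DataFrame(0, index=[m.metacluster_id for m in metaclusters],
                          columns=subjects, dtype=int)
    for psm in psms:
        mc_id = mapping.get(psm.peptide)
        if mc_id is not None:
            counts.at[mc_id, psm.subject_id] += 1
    for mc in metaclusters:
        mc.spectral_counts = counts.loc[mc.metacluster_id].to_dict()
    return counts


ACCOUNTING_COLUMNS = ["source", "annotation", "spectral_counts",
                      "unique_peptide_sequences", "metaclusters"]


def annotation_summary(metaclusters: Sequence[Metacluster],
                       counts: pd.DataFrame) -> pd.DataFrame:
    """Accounting of spectra, distinct peptides and metaclusters.

    Rows stratify by source (Bacterial/Human) and annotation status (with
    or without a characterized gene name). A metacluster mixing host and
    microbial members would make the strata ill-defined and raises.
    """
    strata: dict[tuple[str, str], dict[str, int | set]] = {}
    for mc in metaclusters:
        if 0 < mc.n_host_members < len(mc.member_accessions):
            raise ValueError(
                f"metacluster {mc.metacluster_id} mixes host and "
                "microbial proteins; strata would be ill-defined")
        source = "Human" if mc.is_host else "Bacterial"
        annot = ("With useful annotation" if mc.has_useful_annotation
                 else "Without useful annotation")
        key = (source, annot)
        entry = strata.setdefault(
            key, {"spectra": 0, "peptides": set(), "n": 0})
        entry["spectra"] += int(counts.loc[mc.metacluster_id].sum())
        entry["peptides"] |= set(mc.peptide_set)
        entry["n"] += 1
    rows = []
    for source in ("Bacterial", "Human"):
        for annot in ("With useful annotation", "Without useful annotation"):
            entry = strata.get((source, annot))
            if entry is None:
                continue
            rows.append((source, annot, entry["spectra"],
                         len(entry["peptides"]), entry["n"]))
    return pd.DataFrame(rows, columns=ACCOUNTING_COLUMNS)


def accounting_totals(accounting: pd.DataFrame) -> dict[str, int]:
    """Totals the accounting table implies (cross-checked in reports).

    Returns overall and bacterial-only sums of spectra, distinct peptide
    sequences, and metaclusters.
    """
    bact = accounting[accounting["source"] == "Bacterial"]
    return {
        "total_spectral_counts": int(accounting["spectral_counts"].sum()),
        "total_unique_peptides": int(
            accounting["unique_peptide_sequences"].sum()),
        "total_metaclusters": int(accounting["metaclusters"].sum()),
        "bacterial_spectral_counts": int(bact["spectral_counts"].sum()),
        "bacterial_unique_peptides": int(
            bact["unique_peptide_sequences"].sum()),
        "bacterial_metaclusters": int(bact["metaclusters"].sum()),
    }
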
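"""Pathway-level spectral-count contrasts between subject groups.

Annotated metaclusters are joined to pathways through an offline
gene-to-pathway table, metacluster counts are deduplicated at the genus
level (a peptide matching several same-genus proteins within a metacluster
contributes its spectra once), and pathway members are contrasted between
a treated subject group and the untreated rest via mean +/- SD bands.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import Metacluster, PathwayContrast, ProteinDatabase, PSM

VERDICTS = ("higher", "lower", "equivalent")


def deduplicate_at_genus(metaclusters: Sequence[Metacluster],
                         psms: Sequence[PSM],
                         database: ProteinDatabase) -> pd.DataFrame:
    """Metacluster x subject counts with peptide redundancy removed at genus.

    Within a metacluster, a peptide contributes its spectra once per
    genus whose member proteins contain it — never once per protein. The
    result is element-wise <= the per-protein redundant counting.
    """
    subjects = sorted({p.subject_id for p in psms})
    # spectra per (peptide, subject)
    spectra: dict[tuple[str, str], int] = {}
    for psm in psms:
        key = (psm.peptide, psm.subject_id)
        spectra[key] = spectra.get(key, 0) + 1

    out = pd.DataFrame(0, index=[m.metacluster_id for m in metaclusters],
                       columns=subjects, dtype=int)
    for mc in metaclusters:
        # genus multiplicity of each peptide within this metacluster
        members = [database[a] for a in mc.member_accessions]
        pep_genera: dict[str, set[str]] = {}
        for rec in members:
            genus = rec.lineage.genus if rec.lineage else "unknown"
            for pep in database.digest_of(rec.accession):
                if pep in mc.peptide_set:
                    pep_genera.setdefault(pep, set()).add(genus)
        for pep, genera in pep_genera.items():
            mult = len(genera)
            for subj in subjects:
                n = spectra.get((pep, subj), 0)
                if n:
                    out.at[mc.metacluster_id, subj] += n * mult
    return out


def per_protein_counts(metaclusters: Sequence[Metacluster],
                       psms: Sequence[PSM],
                       database: ProteinDatabase) -> pd.DataFrame:
    """Redundant metacluster counting: once per member protein match.

    The fully redundant upper bound against which genus-level
    deduplication is checked.
    """
    subjects = sorted({p.subject_id for p in psms})
    spectra: dict[tuple[str, str], int] = {}
    for psm in psms:
        key = (psm.peptide, psm.subject_id)
        spectra[key] = spectra.get(key, 0) + 1
    out = pd.DataFrame(0, index=[m.metacluster_id for m in metaclusters],
                       columns=subjects, dtype=int)
    for mc in metaclusters:
        pep_mult: dict[str, int] = {}
        for acc in mc.member_accessions:
            for pep in database.digest_of(acc):
                if pep in mc.peptide_set:
                    pep_mult[pep] = pep_mult.get(pep, 0) + 1
        for pep, mult in pep_mult.items():
            for subj in subjects:
                n = spectra.get((pep, subj), 0)
                if n:
                    out.at[mc.metacluster_id, subj] += n * mult
    return out


def map_to_pathways(metaclusters: Sequence[Metacluster],
                    pathway_table: pd.DataFrame
                    ) -> dict[str, list[str]]:
    """Join annotated metaclusters to pathways by gene name.

    Only metaclusters carrying useful annotation participate; a
    metacluster joins every pathway whose gene set intersects its gene
    names (case-insensitive). Multi-pathway membership is allowed.
    """
    if pathway_table.empty:
        raise ValueError("pathway table is empty")
    gene_to_pathways: dict[str, set[str]] = {}
    for row in pathway_table.itertuples(index=False):
        gene_to_pathways.setdefault(
            row.gene_name.lower(), set()).add(row.pathway_id)
    members: dict[str, list[str]] = {}
    for mc in metaclusters:
        if not mc.has_useful_annotation:
            continue
        hit = set()
        for gene in mc.gene_names:
            hit |= gene_to_pathways.get(gene.lower(), set())
        for pw in hit:
            members.setdefault(pw, []).append(mc.metacluster_id)
    return {pw: sorted(ids) for pw, ids in sorted(members.items())}


def contrast_groups(pathway_members: Mapping[str, Sequence[str]],
                    counts: pd.DataFrame,
                    treated: Sequence[str],
                    untreated: Sequence[str],
                    gene_of: Mapping[str, str] | None = None,
                    majority: float = 0.5) -> list[PathwayContrast]:
    """Contrast pathway spectral counts between subject groups.

    Per member feature: the treated count (sum over treated subjects when
    there are several), and mean and standard deviation (n-1 denominator)
    over the untreated subjects. A member is "higher" when its treated
    count exceeds mean + 1 SD, "lower" below mean - 1 SD, else
    "equivalent"; the pathway verdict requires a strict ``majority`` of
    members to agree on higher (resp. lower).
    """
    treated, untreated = list(treated), list(untreated)
    if not treated or not untreated:
        raise ValueError("both subject groups must be non-empty")
    if set(treated) & set(untreated):
        raise ValueError("treated and untreated subjects overlap")
    for s in treated + untreated:
        if s not in counts.columns:
            raise ValueError(f"subject {s!r} not in count matrix")

    results = []
    for pw, member_ids in pathway_members.items():
        rows = []
        verdict_tally = {v: 0 for v in VERDICTS}
        for mid in member_ids:
            t = float(counts.loc[mid, treated].sum())
            u = counts.loc[mid, untreated].to_numpy(dtype=float)
            mean = float(u.mean())
            sd = float(u.std(ddof=1)) if len(u) > 1 else 0.0
            if t > mean + sd:
                member_verdict = "higher"
            elif t < mean - sd:
                member_verdict = "lower"
            else:
                member_verdict = "equivalent"
            verdict_tally[member_verdict] += 1
            gene = gene_of.get(mid, "") if gene_of else ""
            rows.append((mid, gene, t, mean, sd, member_verdict))
        n = len(member_ids)
        if n and verdict_tally["higher"] / n > majority:
            verdict = "higher"
        elif n and verdict_tally["lower"] / n > majority:
            verdict = "lower"
        else:
            verdict = "equivalent"
        results.append(PathwayContrast(pathway_id=pw, rows=rows,
                                       verdict=verdict))
    return results


def contrasts_to_frame(contrasts: Sequence[PathwayContrast]) -> pd.DataFrame:
    rows = []
    for c in contrasts:
        for (mid, gene, t, mean, sd, mv) in c.rows:
            rows.append((c.pathway_id, c.verdict, mid, gene, t, mean,
                         round(sd, 6), mv))
    return pd.DataFrame(rows, columns=[
        "pathway_id", "pathway_verdict", "metacluster_id", "gene_name",
        "treated_count", "untreated_mean", "untreated_sd",
        "member_verdict"])
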
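"""Target-decoy FDR filtering and parsimony protein inference.

A PSM whose matches are all decoy sequences is a decoy hit; the ratio of
surviving decoy to target hits above a score threshold estimates the false
discovery rate. After filtering, the simplest list of proteins that
explains the observed peptides is derived: proteins indistinguishable by
their observed peptides merge into one group, groups subsumed by another's
evidence are removed, and a deterministic greedy set cover reports the
final list.
"""

from __future__ import annotations

import logging
from typing import Sequence

from .models import FdrResult, ProteinDatabase, ProteinGroup, PSM

log = logging.getLogger("metaproteo")


def is_decoy_psm(psm: PSM, database: ProteinDatabase) -> bool:
    """True when every matched accession is a decoy sequence."""
    return all(database[a].is_decoy for a in psm.matched_accessions)


def fdr_filter(psms: Sequence[PSM], database: ProteinDatabase,
               target_fdr: float) -> tuple[list[PSM], FdrResult]:
    """Filter PSMs at the lowest score threshold meeting ``target_fdr``.

    Scans candidate thresholds (the observed scores, ascending) and keeps
    the lowest threshold at which decoy/target among surviving PSMs is at
    most ``target_fdr``; estimator is n_decoy / max(n_target, 1). Decoy
    PSMs are removed from the returned retained set. If no threshold
    reaches the target, an empty set is returned with a warning.
    """
    if target_fdr < 0:
        raise ValueError("target_fdr must be >= 0")
    flagged = [(p.score, is_decoy_psm(p, database), p) for p in psms]
    flagged.sort(key=lambda t: t[0])
    n = len(flagged)
    n_target_total = sum(1 for _, d, _ in flagged if not d)
    n_decoy_total = n - n_target_total

    # suffix counts: surviving = score >= threshold at position i
    chosen = None
    n_target, n_decoy = n_target_total, n_decoy_total
    i = 0
    while i < n:
        score = flagged[i][0]
        fdr = n_decoy / max(n_target, 1)
        if n_target > 0 and fdr <= target_fdr:
            chosen = (score, n_target, n_decoy, fdr)
            break
        # drop every PSM at this exact score, move threshold up
        while i < n and flagged[i][0] == score:
            if flagged[i][1]:
                n_decoy -= 1
            else:
                n_target -= 1
            i += 1

    if chosen is None:
        log.warning("no score threshold reaches FDR <= %g; "
                    "returning empty retained set", target_fdr)
        return [], FdrResult(score_threshold=float("inf"),
                             n_target=0, n_decoy=0, fdr=0.0)
    threshold, n_t, n_d, fdr = chosen
    retained = [p for s, d, p in flagged if s >= threshold and not d]
    log.info("FDR filter: threshold=%.4f, %d targets, %d decoys, fdr=%.4f",
             threshold, n_t, n_d, fdr)
    return retained, FdrResult(score_threshold=threshold,
                               n_target=n_t, n_decoy=n_d, fdr=fdr)


def infer_protein_groups(retained: Sequence[PSM],
                         database: ProteinDatabase) -> list[ProteinGroup]:
    """Derive the simplest list of protein groups explaining the peptides.

    1. Proteins with identical observed-peptide sets merge into a group.
    2. Groups whose peptide set is a strict subset of another group's are
       removed; their peptides stay explained by the superset group.
    3. A greedy set cover over the retained peptides (most uncovered
       peptides first, ties broken by lexicographically smallest member
       accession) selects the reported list.

    Decoy accessions never enter groups.
    """
    # observed peptide -> candidate (non-decoy) proteins
    pep_to_prots: dict[str, set[str]] = {}
    for psm in retained:
        targets = {a for a in psm.matched_accessions
                   if not database[a].is_decoy}
        if not targets:
            continue  # all-decoy PSM; nothing to explain
        pep_to_prots.setdefault(psm.peptide, set()).update(targets)

    prot_to_peps: dict[str, set[str]] = {}
    for pep, prots in pep_to_prots.items():
        for acc in prots:
            prot_to_peps.setdefault(acc, set()).add(pep)

    # step 1: indistinguishable proteins
    by_pepset: dict[frozenset[str], list[str]] = {}
    for acc, peps in prot_to_peps.items():
        by_pepset.setdefault(frozenset(peps), []).append(acc)
    candidates = [(sorted(accs), peps) for peps, accs in by_pepset.items()]

    # step 2: strict-subset removal
    maximal = []
    for accs, peps in candidates:
        if not any(peps < other for _, other in candidates):
            maximal.append((accs, peps))

    # step 3: deterministic greedy cover
    uncovered = set(pep_to_prots)
    remaining = sorted(maximal, key=lambda t: t[0][0])
    selected: list[tuple[list[str], frozenset[str]]] = []
    while uncovered:
        # most uncovered peptides first; ties -> smallest accession wins
        best = min(remaining,
                   key=lambda t: (-len(t[1] & uncovered), t[0][0]))
        gain = best[1] & uncovered
        if not gain:  # cannot happen while uncovered peptides have owners
            raise RuntimeError("uncoverable peptides remain")
        selected.append(best)
        remaining.remove(best)
        uncovered -= gain

    groups = []
    for accs, peps in sorted(selected, key=lambda t: t[0][0]):
        host_flags = {database[a].is_host for a in accs}
        groups.append(ProteinGroup(
            group_id=f"PG_{accs[0]}",
            member_accessions=tuple(accs),
            peptide_set=peps,
            is_host=host_flags == {True}))
    log.info("parsimony inference: %d peptides -> %d reported groups",
             len(pep_to_prots), len(groups))
    return groups


def assign_spectral_counts(groups: Sequence[ProteinGroup],
                           retained: Sequence[PSM]) -> None:
    """Accumulate per-subject spectral counts onto the reported groups.

    Each PSM contributes one count to every reported group whose peptide
    set contains its peptide (shared peptides count once per covering
    group; per-level uniqueness is handled downstream).
    """
    pep_to_groups: dict[str, list[ProteinGroup]] = {}
    for g in groups:
        g.spectral_counts = {}
        for pep in g.peptide_set:
            pep_to_groups.setdefault(pep, []).append(g)
    for psm in retained:
        for g in pep_to_groups.get(psm.peptide, ()):
            g.spectral_counts[psm.subject_id] = \
                g.spectral_counts.get(psm.subject_id, 0) + 1


def protein_level_fdr(groups: Sequence[ProteinGroup],
                      psms: Sequence[PSM],
                      database: ProteinDatabase,
                      score_threshold: float) -> float:
    """Achieved protein-level FDR: decoy groups over target groups.

    Decoy "groups" are counted by running the same grouping logic over the
    decoy-only PSMs surviving the score threshold; reported for the run
    manifest, not used for filtering.
    """
    decoy_peps: dict[str, set[str]] = {}
    for psm in psms:
        if psm.score >= score_threshold and is_decoy_psm(psm, database):
            for acc in psm.matched_accessions:
                decoy_peps.setdefault(acc, set()).add(psm.peptide)
    n_decoy_groups = len({frozenset(p) for p in decoy_peps.values()})
    return n_decoy_groups / max(len(groups), 1)
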
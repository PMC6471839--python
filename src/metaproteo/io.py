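"""Readers and writers for the pipeline's plain-text formats.

Formats: protein database FASTA with a structured header, per-subject PSM
TSV tables, genus x subject 16S count TSV, truth/manifest JSON, and the
report tables the pipeline emits. All TSVs are UTF-8 with a header row, no
quoting, and tabs forbidden inside fields, so golden-file tests can be
bit-exact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from .models import Lineage, ProteinRecord, ProteinDatabase, PSM, FdrResult
from .simulate import CommunitySpec, ScoreModel

log = logging.getLogger("metaproteo")

PSM_COLUMNS = ["spectrum_id", "subject_id", "peptide", "accessions", "score"]
_MOD_TAG = re.compile(r"\[[^\]]*\]")
_HEADER_FIELDS = ("GN", "UR", "TX", "DECOY", "HOST")


def format_header(rec: ProteinRecord) -> str:
    tx = ";".join(rec.lineage.as_tuple()) if rec.lineage else "-;-;-;-"
    return (f"{rec.accession}|GN={rec.gene_name or '-'}"
            f"|UR={rec.uniref50_id or '-'}|TX={tx}"
            f"|DECOY={int(rec.is_decoy)}|HOST={int(rec.is_host)}")


def _parse_header(header: str, lineno: int) -> dict:
    parts = header.split("|")
    if len(parts) != 6:
        raise ValueError(
            f"line {lineno}: malformed header (expected 6 |-fields, "
            f"got {len(parts)}): {header!r}")
    fields = {"accession": parts[0]}
    for part, expected in zip(parts[1:], _HEADER_FIELDS):
        key, sep, value = part.partition("=")
        if key != expected or not sep:
            raise ValueError(
                f"line {lineno}: malformed header, expected "
                f"{expected}=... got {part!r}")
        fields[key] = value
    tx = fields["TX"].split(";")
    if len(tx) != 4:
        raise ValueError(
            f"line {lineno}: TX field must hold 4 ;-separated ranks, "
            f"got {fields['TX']!r}")
    if fields["DECOY"] not in "01" or fields["HOST"] not in "01":
        raise ValueError(f"line {lineno}: DECOY/HOST flags must be 0 or 1")
    return {
        "accession": fields["accession"],
        "gene_name": "" if fields["GN"] == "-" else fields["GN"],
        "uniref50_id": "" if fields["UR"] == "-" else fields["UR"],
        "lineage": None if tx == ["-"] * 4 else Lineage(*tx),
        "is_decoy": fields["DECOY"] == "1",
        "is_host": fields["HOST"] == "1",
    }


def write_database(records: Iterable[ProteinRecord], path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            fh.write(f">{format_header(rec)}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def read_database(path, **db_kwargs) -> ProteinDatabase:
    """Load a protein database FASTA.

    Raises on malformed headers (naming the offending line) and on
    duplicate accessions. Logs target/decoy/host record counts.
    """
    path = Path(path)
    # SeqIO handles sequence assembly; a pre-scan maps each header to its
    # line number so parse errors can point at the file location.
    header_lines = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                header_lines.append(lineno)
    records = []
    for i, seqrec in enumerate(SeqIO.parse(str(path), "fasta")):
        header = seqrec.description
        fields = _parse_header(header, header_lines[i])
        records.append(ProteinRecord(sequence=str(seqrec.seq), **fields))
    db = ProteinDatabase(records, **db_kwargs)
    n_target = sum(1 for r in records if not r.is_decoy)
    n_decoy = len(records) - n_target
    n_host = sum(1 for r in records if r.is_host and not r.is_decoy)
    log.info("loaded %d records from %s: %d targets (%d host), %d decoys",
             len(records), path.name, n_target, n_host, n_decoy)
    return db


def write_psms(psms: Sequence[PSM], path) -> None:
    rows = [(p.spectrum_id, p.subject_id, p.peptide,
             ";".join(sorted(p.matched_accessions)), repr(p.score))
            for p in psms]
    df = pd.DataFrame(rows, columns=PSM_COLUMNS)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def strip_modifications(peptide: str) -> str:
    """Remove bracketed modification tags: ``PEPT[+0.98]IDER`` -> bare."""
    return _MOD_TAG.sub("", peptide)


def read_psms(path, database: Optional[ProteinDatabase] = None) -> list[PSM]:
    """Load a PSM TSV, stripping modification tags from peptides.

    If ``database`` is given, every accession must resolve against it;
    unresolvable accessions raise with the full offender list.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    psms = []
    unresolved: set[str] = set()
    for row in df.itertuples(index=False):
        accs = frozenset(row.accessions.split(";"))
        if database is not None:
            unresolved |= {a for a in accs if a not in database}
        psms.append(PSM(spectrum_id=row.spectrum_id,
                        subject_id=row.subject_id,
                        peptide=strip_modifications(row.peptide),
                        matched_accessions=accs,
                        score=float(row.score)))
    if unresolved:
        raise ValueError(
            f"{path}: {len(unresolved)} accession(s) not in database: "
            f"{sorted(unresolved)[:10]}")
    return psms


def write_counts(df: pd.DataFrame, path, index_label: str = "feature") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, lineterminator="\n")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_16s(df: pd.DataFrame, path) -> None:
    write_counts(df, path, index_label="genus")


read_16s = read_counts


def write_pathway_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_pathway_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("pathway_id", "gene_name"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df


# ---------------------------------------------------------------------------
# Config and truth serialization
# ---------------------------------------------------------------------------

def spec_to_yaml(spec: CommunitySpec, path) -> None:
    data = dataclasses.asdict(spec)
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def spec_from_yaml(path) -> CommunitySpec:
    with Path(path).open(encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if "score_model" in data and isinstance(data["score_model"], dict):
        data["score_model"] = ScoreModel(**data["score_model"])
    return CommunitySpec(**data)


def config_hash(spec: CommunitySpec) -> str:
    canon = yaml.safe_dump(dataclasses.asdict(spec), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_truth(truth, path) -> None:
    data = {
        "abundances": {rank: {t: {s: float(v) for s, v in row.items()}
                              for t, row in df.iterrows()}
                       for rank, df in truth.abundances.items()},
        "protein_partition": truth.protein_partition,
    }
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ResultsBundle:
    """Everything a full pipeline run produces, ready for writing."""

    accounting: Optional[pd.DataFrame] = None
    strain_tiers: Optional[pd.DataFrame] = None
    rank_profiles: dict[str, pd.DataFrame] = dataclasses.field(
        default_factory=dict)
    metacluster_counts: Optional[pd.DataFrame] = None
    metacluster_table: Optional[pd.DataFrame] = None
    group_table: Optional[pd.DataFrame] = None
    correlations: Optional[pd.DataFrame] = None
    heatmap: Optional[pd.DataFrame] = None
    pathway_contrasts: Optional[pd.DataFrame] = None
    fdr: Optional[FdrResult] = None
    protein_level_fdr: Optional[float] = None
    manifest: dict = dataclasses.field(default_factory=dict)


def write_reports(bundle: ResultsBundle, outdir) -> list[Path]:
    """Write every populated report table of a results bundle as TSV.

    Returns the list of files written; always includes a run manifest
    (config hash, seed, achieved FDR) as JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _emit(df, name, index_label=None):
        p = outdir / name
        if index_label is None:
            df.to_csv(p, sep="\t", index=False, lineterminator="\n")
        else:
            df.to_csv(p, sep="\t", index_label=index_label,
                      lineterminator="\n")
        written.append(p)

    if bundle.accounting is not None:
        _emit(bundle.accounting, "accounting.tsv")
    if bundle.strain_tiers is not None:
        _emit(bundle.strain_tiers, "strain_tiers.tsv", index_label="tier")
    for rank, df in bundle.rank_profiles.items():
        _emit(df, f"profile_{rank}.tsv", index_label=rank)
    if bundle.metacluster_counts is not None:
        _emit(bundle.metacluster_counts, "metacluster_counts.tsv",
              index_label="metacluster_id")
    if bundle.metacluster_table is not None:
        _emit(bundle.metacluster_table, "metaclusters.tsv")
    if bundle.group_table is not None:
        _emit(bundle.group_table, "protein_groups.tsv")
    if bundle.correlations is not None:
        _emit(bundle.correlations, "correlations.tsv")
    if bundle.heatmap is not None:
        _emit(bundle.heatmap, "heatmap_matrix.tsv", index_label="taxon")
    if bundle.pathway_contrasts is not None:
        _emit(bundle.pathway_contrasts, "pathway_contrasts.tsv")

    manifest = dict(bundle.manifest)
    if bundle.fdr is not None:
        manifest["psm_fdr"] = dataclasses.asdict(bundle.fdr)
    if bundle.protein_level_fdr is not None:
        manifest["protein_level_fdr"] = bundle.protein_level_fdr
    mpath = outdir / "manifest.json"
    with mpath.open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    written.append(mpath)
    return written
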
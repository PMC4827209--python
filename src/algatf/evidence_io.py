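"""Readers and writers for the pipeline's file formats.

Supported inputs: proteome FASTA, 12-column tabular BLAST output,
profile-HMM per-domain tables (``--domtblout`` dialect) and InterProScan
TSV annotation. Outputs: assignments and benchmark reports as TSV.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional

from Bio import SeqIO

from .records import (
    Assignment,
    BlastHit,
    DomainHit,
    EvidenceSource,
    GoldStandard,
    ProteinRecord,
)


class FormatError(ValueError):
    """A file did not match the expected dialect."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> list[ProteinRecord]:
    """Read a predicted proteome.

    Duplicate ids are a hard error: every downstream join keys on
    ``protein_id``.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"empty sequence for FASTA id {rec.id!r} in {path}")
        records.append(ProteinRecord(protein_id=rec.id, sequence=seq))
    return records


def write_fasta(path: str | os.PathLike, records: Iterable[ProteinRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# BLAST 12-column tabular

_BLAST_NCOLS = 12


def read_blast_tab(path: str | os.PathLike) -> list[BlastHit]:
    """Read 12-column tabular BLAST output (qseqid..bitscore), order preserved."""
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _BLAST_NCOLS:
                raise FormatError(
                    f"{path}:{lineno}: expected {_BLAST_NCOLS} tab-separated "
                    f"columns, found {len(fields)}"
                )
            try:
                hit = BlastHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_blast_tab(path: str | os.PathLike, hits: Iterable[BlastHit]) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id,
                        h.subject_id,
                        f"{h.percent_identity:.2f}",
                        h.alignment_length,
                        h.mismatches,
                        h.gap_opens,
                        h.q_start,
                        h.q_end,
                        h.s_start,
                        h.s_end,
                        f"{h.evalue:.3g}",
                        f"{h.bitscore:.1f}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# profile-HMM per-domain table (hmmscan --domtblout dialect)
#
# Column layout (whitespace-delimited; description free-text at the end):
#  0 target name   1 target accession  2 tlen  3 query name  4 query accession
#  5 qlen  6 full E-value  7 full score  8 full bias  9 dom #  10 of
#  11 c-Evalue  12 i-Evalue  13 dom score  14 dom bias
#  15 hmm from  16 hmm to  17 ali from  18 ali to  19 env from  20 env to
#  21 acc  22+ description
_DOMTBL_MIN_COLS = 22


def read_domtblout(path: str | os.PathLike) -> list[DomainHit]:
    """Read a per-domain table from a profile-HMM scan.

    The per-domain *independent* e-value (column 13, ``i-Evalue``) becomes
    ``DomainHit.evalue``; the per-domain bit score becomes ``score``; the
    ``ali`` coordinate pair becomes ``ali_start``/``ali_end``.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < _DOMTBL_MIN_COLS:
                raise FormatError(
                    f"{path}:{lineno}: expected >= {_DOMTBL_MIN_COLS} columns "
                    f"in per-domain table, found {len(fields)}"
                )
            try:
                hit = DomainHit(
                    protein_id=fields[3],
                    source=EvidenceSource.HMMER_CUSTOM,
                    domain_accession=fields[1] if fields[1] != "-" else fields[0],
                    domain_name=fields[0],
                    evalue=float(fields[12]),
                    score=float(fields[13]),
                    ali_start=int(fields[17]),
                    ali_end=int(fields[18]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_domtblout(path: str | os.PathLike, hits: Iterable[DomainHit]) -> None:
    """Write DomainHits back out in the per-domain table dialect (for fixtures)."""
    with open(path, "w") as fh:
        fh.write("# per-domain hits table\n")
        fh.write(
            "# target_name accession tlen query_name accession qlen "
            "E-value score bias # of c-Evalue i-Evalue score bias "
            "hmm_from hmm_to ali_from ali_to env_from env_to acc description\n"
        )
        for h in hits:
            ev = f"{h.evalue:.2g}" if h.evalue is not None else "-"
            fh.write(
                f"{h.domain_name} {h.domain_accession} 200 {h.protein_id} - 500 "
                f"{ev} {h.score:.1f} 0.1 1 1 {ev} {ev} {h.score:.1f} 0.1 "
                f"1 80 {h.ali_start} {h.ali_end} {h.ali_start} {h.ali_end} "
                f"0.98 -\n"
            )


# ---------------------------------------------------------------------------
# InterProScan TSV
#
# Column layout used (tab-separated):
#  0 protein id  1 sequence md5 (may be '-')  2 sequence length
#  3 member database  4 signature accession  5 signature description
#  6 start  7 stop  8 score/e-value  (optional trailing columns ignored)
_IPR_MIN_COLS = 9


def read_interproscan_tsv(path: str | os.PathLike) -> list[DomainHit]:
    """Read member-database annotation rows from an InterProScan TSV.

    A non-numeric score field (typically ``-``) yields a hit with
    ``evalue=None`` and ``evalue_missing=True``.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < _IPR_MIN_COLS:
                raise FormatError(
                    f"{path}:{lineno}: expected >= {_IPR_MIN_COLS} tab-separated "
                    f"columns in annotation TSV, found {len(fields)}"
                )
            raw_ev = fields[8].strip()
            evalue: Optional[float]
            try:
                evalue = float(raw_ev)
            except ValueError:
                evalue = None
            try:
                hit = DomainHit(
                    protein_id=fields[0],
                    source=EvidenceSource.INTERPROSCAN,
                    domain_accession=fields[4],
                    domain_name=fields[5],
                    evalue=evalue,
                    score=0.0,
                    ali_start=int(fields[6]),
                    ali_end=int(fields[7]),
                    member_db=fields[3],
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_interproscan_tsv(path: str | os.PathLike, hits: Iterable[DomainHit]) -> None:
    with open(path, "w") as fh:
        for h in hits:
            ev = f"{h.evalue:.2g}" if h.evalue is not None else "-"
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.protein_id,
                        "-",
                        500,
                        h.member_db or "PFAM",
                        h.domain_accession,
                        h.domain_name,
                        h.ali_start,
                        h.ali_end,
                        ev,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# assignments TSV

_ASSIGN_HEADER = [
    "protein_id",
    "family",
    "subfamily",
    "supporting_accessions",
    "evidence_sources",
    "curation_flags",
]


def write_assignments(path: str | os.PathLike, assignments: Iterable[Assignment]) -> None:
    """Write assignments as TSV, sorted by protein id (deterministic bytes)."""
    rows = sorted(assignments, key=lambda a: a.protein_id)
    with open(path, "w") as fh:
        fh.write("\t".join(_ASSIGN_HEADER) + "\n")
        for a in rows:
            accs = ",".join(sorted({h.domain_accession for h in a.supporting_hits}))
            sources = ",".join(sorted({h.source.value for h in a.supporting_hits}))
            flags = ",".join(sorted(a.curation_flags))
            fh.write(
                "\t".join(
                    [
                        a.protein_id,
                        a.family,
                        a.subfamily or "-",
                        accs or "-",
                        sources or "-",
                        flags or "-",
                    ]
                )
                + "\n"
            )


def read_assignments(path: str | os.PathLike) -> list[Assignment]:
    """Read an assignments TSV back (content round-trip of write_assignments)."""
    out: list[Assignment] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _ASSIGN_HEADER:
            raise FormatError(f"{path}: unexpected assignments header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(_ASSIGN_HEADER):
                raise FormatError(f"{path}:{lineno}: bad column count")
            pid, family, subfamily, accs, _sources, flags = fields
            out.append(
                Assignment(
                    protein_id=pid,
                    family=family,
                    subfamily=None if subfamily == "-" else subfamily,
                    all_dbd_types=frozenset(accs.split(",")) if accs != "-" else frozenset(),
                    curation_flags=set() if flags == "-" else set(flags.split(",")),
                )
            )
    return out


# ---------------------------------------------------------------------------
# gold-standard labels


def read_gold(path: str | os.PathLike, source_tag: str = "") -> GoldStandard:
    """Read a protein_id <tab> family table (with or without a header row)."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            pid, family = fields[0], fields[1]
            if lineno == 1 and pid.lower() in {"protein_id", "id"}:
                continue
            if pid in labels:
                raise FormatError(f"{path}:{lineno}: duplicate gold label for {pid!r}")
            labels[pid] = family
    return GoldStandard(labels=labels, source_tag=source_tag)


def write_gold(path: str | os.PathLike, gold: GoldStandard) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tfamily\n")
        for pid in sorted(gold.labels):
            fh.write(f"{pid}\t{gold.labels[pid]}\n")
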
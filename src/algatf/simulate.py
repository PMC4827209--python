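"""Synthetic proteomes and matched evidence files with known truth.

The generator plants, for each requested family, proteins whose domain
architecture is exactly the family rule's minimal requirement (copy
numbers included; SHAQKYF proteins carry the motif inside their MYB
repeat). Evidence is then written to real files in the three standard
dialects — 12-column BLAST tabular, profile-HMM per-domain table for the
custom ALG_* profiles, InterProScan TSV for standard accessions — so the
readers and filters are exercised by every integration test.

Noise model:

* ``fn_rate`` — per planted domain instance, the probability it is
  omitted from the domain channels; a protein losing every domain also
  loses its BLAST best hit (the same divergent sequences defeat both
  searches), so it surfaces as a false negative.
* ``fp_rate`` — expected spurious hits per protein. Spurious hits on
  true proteins are written with non-significant e-values or non-DBD
  accessions (they must be removed by the filters); convincing false
  positives are planted as separate decoy proteins carrying a full
  family architecture while being absent from the gold standard.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from . import evidence_io
from .classify import classify_proteome
from .records import (
    Assignment,
    BlastHit,
    DomainHit,
    EvidenceSource,
    GoldStandard,
    ProteinRecord,
)
from .rules import RuleSet

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
DOMAIN_LEN = 40
LINKER_LEN = 20
LEAD_LEN = 30
SHAQKYF_MOTIF = "SHAQKY"

#: the default simulation panel: 12 families spanning the pipeline's
#: special cases (copy numbers, subfamilies, custom profiles, motif path)
DEFAULT_PANEL = [
    "AP2",
    "ERF",
    "bZIP",
    "C2H2",
    "HSF",
    "MYB (3R)",
    "MYB (2R)",
    "MYB-rel",
    "MYB-SHAQKYF",
    "GARP-G2-like",
    "NF-YB",
    "Fungal TRF",
]


@dataclass(frozen=True)
class NoiseModel:
    """Noise injection parameters; identical seed -> identical output."""

    fn_rate: float = 0.0
    fp_rate: float = 0.0
    seed: int = 0
    sig_evalue_exponent_range: tuple[float, float] = (8.0, 30.0)
    junk_evalue_range: tuple[float, float] = (0.01, 10.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.fn_rate <= 1.0:
            raise ValueError("fn_rate must be in [0, 1]")
        if self.fp_rate < 0:
            raise ValueError("fp_rate must be >= 0")


@dataclass(frozen=True)
class TruthEntry:
    label: str
    architecture: tuple[tuple[str, int, int], ...]
    length: int


TruthTable = dict[str, TruthEntry]


@dataclass
class NoiseLog:
    """What the noise model actually did (for independent accounting)."""

    dropped: dict[str, tuple[tuple[str, int, int], ...]] = field(default_factory=dict)
    fully_dropped: set[str] = field(default_factory=set)
    junk_hits: int = 0


def _domain_placeholder(accession: str) -> str:
    """Fixed recognizable subsequence for one accession (deterministic)."""
    rng = np.random.default_rng(abs(hash_stable(accession)) % (2**31))
    while True:
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=DOMAIN_LEN))
        if SHAQKYF_MOTIF[:5] not in seq:  # keep motif scans unambiguous
            return seq


def hash_stable(text: str) -> int:
    """Stable (process-independent) string hash."""
    h = 2166136261
    for ch in text.encode():
        h = (h ^ ch) * 16777619 % (2**32)
    return h


def _architecture_for(label: str, ruleset: RuleSet) -> list[str]:
    """Ordered accession list of the minimal planted architecture."""
    rule = ruleset.rule(label)
    accs: list[str] = []
    for rs in rule.required:
        acc = sorted(rs.accessions)[0]
        accs.extend([acc] * rs.min_copies)
    return accs


def _make_protein(
    pid: str, label: str, ruleset: RuleSet, rng: np.random.Generator
) -> tuple[ProteinRecord, TruthEntry]:
    accs = _architecture_for(label, ruleset)
    arch: list[tuple[str, int, int]] = []
    pos = LEAD_LEN  # 0-based position where the next domain starts
    chunks: list[str] = ["".join(rng.choice(list(AMINO_ACIDS), size=LEAD_LEN))]
    for acc in accs:
        body = _domain_placeholder(acc)
        if label == "MYB-SHAQKYF":
            body = body[:5] + SHAQKYF_MOTIF + body[5 + len(SHAQKYF_MOTIF):]
        arch.append((acc, pos + 1, pos + DOMAIN_LEN))  # 1-based inclusive
        chunks.append(body)
        chunks.append("".join(rng.choice(list(AMINO_ACIDS), size=LINKER_LEN)))
        pos += DOMAIN_LEN + LINKER_LEN
    seq = "".join(chunks)
    record = ProteinRecord(protein_id=pid, sequence=seq)
    return record, TruthEntry(label=label, architecture=tuple(arch), length=len(seq))


def generate_proteome(
    n_per_family: int,
    ruleset: RuleSet,
    seed: int,
    families: Optional[Sequence[str]] = None,
    id_prefix: str = "syn",
) -> tuple[list[ProteinRecord], TruthTable]:
    """Synthetic proteome with planted family architectures.

    One record per (family, replicate); ids ``<prefix>_<slug>_<i>``.
    Deterministic per seed.
    """
    families = list(families) if families is not None else list(DEFAULT_PANEL)
    for f in families:
        if f not in ruleset:
            raise ValueError(f"family {f!r} not in the rule set")
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    truth: TruthTable = {}
    for label in families:
        slug = RuleSet.slug(label).replace("(", "").replace(")", "").replace("/", "-")
        for i in range(n_per_family):
            pid = f"{id_prefix}_{slug}_{i:03d}"
            rec, entry = _make_protein(pid, label, ruleset, rng)
            records.append(rec)
            truth[pid] = entry
    return records, truth


@dataclass
class EvidencePaths:
    blast: Path
    domtbl: Path
    interpro: Path


def generate_evidence(
    truth: TruthTable,
    noise: NoiseModel,
    ruleset: RuleSet,
    outdir: str | os.PathLike,
    basename: str = "evidence",
) -> tuple[EvidencePaths, NoiseLog]:
    """Write the three evidence files for a truth table, with noise.

    Planted domains route to the per-domain table when the accession is a
    custom ALG_* profile and to the InterProScan TSV otherwise. Every
    surviving protein gets a best BLAST hit whose subject id encodes its
    true family, plus one below-threshold decoy BLAST row.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(noise.seed)
    log = NoiseLog()

    blast_rows: list[BlastHit] = []
    dom_rows: list[DomainHit] = []
    ipr_rows: list[DomainHit] = []

    lo, hi = noise.sig_evalue_exponent_range
    for pid in sorted(truth):
        entry = truth[pid]
        dropped: list[tuple[str, int, int]] = []
        survivors: list[tuple[str, int, int]] = []
        for acc, start, end in entry.architecture:
            if noise.fn_rate > 0 and rng.random() < noise.fn_rate:
                dropped.append((acc, start, end))
                continue
            survivors.append((acc, start, end))
            evalue = 10.0 ** -rng.uniform(lo, hi)
            if acc.startswith("ALG_"):
                cutoff = ruleset.profile_thresholds.get(acc, 22.0)
                dom_rows.append(
                    DomainHit(
                        protein_id=pid,
                        source=EvidenceSource.HMMER_CUSTOM,
                        domain_accession=acc,
                        domain_name=acc,
                        evalue=evalue,
                        score=float(cutoff + rng.uniform(5.0, 40.0)),
                        ali_start=start,
                        ali_end=end,
                    )
                )
            else:
                ipr_rows.append(
                    DomainHit(
                        protein_id=pid,
                        source=EvidenceSource.INTERPROSCAN,
                        domain_accession=acc,
                        domain_name=acc,
                        evalue=evalue,
                        score=0.0,
                        ali_start=start,
                        ali_end=end,
                        member_db="PFAM",
                    )
                )
        if dropped:
            log.dropped[pid] = tuple(dropped)
        if not survivors:
            log.fully_dropped.add(pid)
        else:
            # best hit to a database subject named after the true family
            subject = f"{RuleSet.slug(entry.label)}|ref1"
            aln = int(rng.integers(100, 300))
            blast_rows.append(
                BlastHit(
                    query_id=pid,
                    subject_id=subject,
                    percent_identity=float(np.round(rng.uniform(40.0, 90.0), 2)),
                    alignment_length=aln,
                    mismatches=int(rng.integers(0, 50)),
                    gap_opens=int(rng.integers(0, 5)),
                    q_start=1,
                    q_end=aln,
                    s_start=1,
                    s_end=aln,
                    evalue=10.0 ** -rng.uniform(15.0, 50.0),
                    bitscore=float(np.round(rng.uniform(80.0, 300.0), 1)),
                )
            )
            # below-threshold decoy row: must be removed by the identity filter
            blast_rows.append(
                BlastHit(
                    query_id=pid,
                    subject_id="decoy|low_identity",
                    percent_identity=25.0,
                    alignment_length=120,
                    mismatches=90,
                    gap_opens=3,
                    q_start=1,
                    q_end=120,
                    s_start=1,
                    s_end=120,
                    evalue=1e-12,
                    bitscore=60.0,
                )
            )
        # spurious domain hits that the filters must remove
        if noise.fp_rate > 0:
            n_junk = int(rng.poisson(noise.fp_rate))
            # MYB accessions are excluded: the relaxed MYB curation path
            # bypasses the e-value filter by design and would accept them
            catalog = sorted(ruleset.dbd_catalog - ruleset.myb_accessions)
            jlo, jhi = noise.junk_evalue_range
            for _ in range(n_junk):
                if rng.random() < 0.5:
                    acc, evalue = str(rng.choice(catalog)), float(
                        rng.uniform(jlo, jhi)
                    )
                else:  # non-DBD accession, even with a convincing e-value
                    acc, evalue = "PF99999", 10.0 ** -rng.uniform(lo, hi)
                start = int(rng.integers(1, max(2, entry.length - 30)))
                ipr_rows.append(
                    DomainHit(
                        protein_id=pid,
                        source=EvidenceSource.INTERPROSCAN,
                        domain_accession=acc,
                        domain_name="junk",
                        evalue=evalue,
                        score=0.0,
                        ali_start=start,
                        ali_end=start + 25,
                        member_db="PFAM",
                    )
                )
                log.junk_hits += 1

    paths = EvidencePaths(
        blast=outdir / f"{basename}.blast.tsv",
        domtbl=outdir / f"{basename}.domtbl.txt",
        interpro=outdir / f"{basename}.interpro.tsv",
    )
    evidence_io.write_blast_tab(paths.blast, blast_rows)
    evidence_io.write_domtblout(paths.domtbl, dom_rows)
    evidence_io.write_interproscan_tsv(paths.interpro, ipr_rows)
    return paths, log


def expected_assignments(
    truth: TruthTable,
    log: NoiseLog,
    ruleset: RuleSet,
    sequences: Optional[Mapping[str, str]] = None,
) -> dict[str, str]:
    """Predicted post-noise label per protein, from the planted truth alone.

    Applies the family rules directly to each protein's surviving planted
    architecture, bypassing evidence files, parsers and filters — the
    generator-side account the pipeline output must match.
    """
    from .records import EvidenceBundle  # local import to avoid cycle noise

    bundles: dict[str, EvidenceBundle] = {}
    for pid, entry in truth.items():
        dropped = set(log.dropped.get(pid, ()))
        hits = [
            DomainHit(
                protein_id=pid,
                source=(
                    EvidenceSource.HMMER_CUSTOM
                    if acc.startswith("ALG_")
                    else EvidenceSource.INTERPROSCAN
                ),
                domain_accession=acc,
                domain_name=acc,
                evalue=1e-10,
                score=100.0,
                ali_start=start,
                ali_end=end,
                significant=True,
            )
            for acc, start, end in entry.architecture
            if (acc, start, end) not in dropped
        ]
        if hits:
            bundles[pid] = EvidenceBundle(protein_id=pid, domain_hits=hits)
    calls = classify_proteome(bundles, ruleset, sequences=sequences, strict=True)
    out = {pid: "unclassified" for pid in truth}
    for a in calls:
        out[a.protein_id] = a.label if a.is_classified else "unclassified"
    return out


@dataclass
class SimulationResult:
    records: list[ProteinRecord]
    truth: TruthTable
    decoy_truth: TruthTable
    gold: GoldStandard
    fasta: Path
    gold_path: Path
    evidence: EvidencePaths
    log: NoiseLog


def simulate_study(
    outdir: str | os.PathLike,
    families: Optional[Sequence[str]] = None,
    n_per_family: int = 5,
    fn_rate: float = 0.0,
    fp_rate: float = 0.0,
    seed: int = 0,
    ruleset: Optional[RuleSet] = None,
) -> SimulationResult:
    """End-to-end fixture: proteome FASTA + gold labels + evidence files.

    Convincing false positives are planted as decoy proteins (absent from
    the gold standard): their count is Binomial(n_true, min(fp_rate, 1)),
    each carrying the full architecture of a random panel family.
    """
    from .rules import default_rules

    ruleset = ruleset or default_rules()
    families = list(families) if families is not None else list(DEFAULT_PANEL)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    records, truth = generate_proteome(
        n_per_family, ruleset, seed=seed, families=families
    )

    rng = np.random.default_rng(seed + 1)
    decoy_truth: TruthTable = {}
    decoy_records: list[ProteinRecord] = []
    if fp_rate > 0:
        n_decoys = int(rng.binomial(len(records), min(fp_rate, 1.0)))
        for i in range(n_decoys):
            label = str(rng.choice(families))
            pid = f"decoy_{i:03d}"
            rec, entry = _make_protein(pid, label, ruleset, rng)
            decoy_records.append(rec)
            decoy_truth[pid] = entry

    all_records = records + decoy_records
    fasta = outdir / "proteome.fasta"
    evidence_io.write_fasta(fasta, all_records)

    gold = GoldStandard(
        labels={pid: e.label for pid, e in truth.items()}, source_tag="synthetic"
    )
    gold_path = outdir / "gold.tsv"
    evidence_io.write_gold(gold_path, gold)

    noise = NoiseModel(fn_rate=fn_rate, fp_rate=fp_rate, seed=seed + 2)
    evidence, log = generate_evidence(
        {**truth, **decoy_truth}, noise, ruleset, outdir
    )
    return SimulationResult(
        records=all_records,
        truth=truth,
        decoy_truth=decoy_truth,
        gold=gold,
        fasta=fasta,
        gold_path=gold_path,
        evidence=evidence,
        log=log,
    )


def assignments_to_labels(assignments: Sequence[Assignment]) -> dict[str, str]:
    return {a.protein_id: a.label for a in assignments if a.is_classified}
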
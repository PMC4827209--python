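"""False-positive filtering and evidence merging (Step Two).

Each evidence channel gets its own filter:

* BLAST — e-value <= 1e-10, identity >= 35 %, alignment length >= 100
  residues; then exactly one best hit per query (highest bit score,
  ties by lowest e-value, then lexicographically smallest subject id).
* InterProScan — e-value <= 1e-3 and the signature must be a known TF
  DBD. The threshold direction deliberately reads "at most": keeping
  matches *worse* than 1e-3 would retain noise in a step whose purpose
  is false-positive removal.
* profile-HMM — per-profile score (gathering-threshold style) cutoffs,
  with a fixed e-value fallback for profiles without a stated cutoff.

All comparisons are inclusive. Survivors of the three filters are merged
into one EvidenceBundle per protein.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field
from typing import Iterable, Literal, Mapping, Sequence

from .records import BlastHit, DomainHit, EvidenceBundle, ProteinRecord


@dataclass(frozen=True)
class FilterThresholds:
    """Cutoffs applied in the false-positive filtration step."""

    blast_max_evalue: float = 1e-10
    blast_min_identity: float = 35.0
    blast_min_alnlen: int = 100
    ipr_max_evalue: float = 1e-3
    hmmer_policy: Literal["per_profile_threshold", "fixed_evalue"] = (
        "per_profile_threshold"
    )
    hmmer_fallback_evalue: float = 1e-5

    def __post_init__(self) -> None:
        if self.blast_max_evalue <= 0 or self.ipr_max_evalue <= 0:
            raise ValueError("e-value thresholds must be positive")
        if self.hmmer_fallback_evalue <= 0:
            raise ValueError("hmmer fallback e-value must be positive")
        if not 0 < self.blast_min_identity <= 100:
            raise ValueError("identity threshold must be in (0, 100]")
        if self.blast_min_alnlen <= 0:
            raise ValueError("alignment length threshold must be positive")


def filter_blast(
    hits: Iterable[BlastHit], thresholds: FilterThresholds = FilterThresholds()
) -> dict[str, BlastHit]:
    """Apply the BLAST thresholds and keep the best hit per query.

    Deterministic tie-breaking: highest bitscore, then lowest e-value,
    then smallest subject_id.
    """
    best: dict[str, BlastHit] = {}
    for h in hits:
        if h.evalue > thresholds.blast_max_evalue:
            continue
        if h.percent_identity < thresholds.blast_min_identity:
            continue
        if h.alignment_length < thresholds.blast_min_alnlen:
            continue
        cur = best.get(h.query_id)
        if cur is None or _blast_rank(h) < _blast_rank(cur):
            best[h.query_id] = h
    return best


def _blast_rank(h: BlastHit) -> tuple[float, float, str]:
    return (-h.bitscore, h.evalue, h.subject_id)


def filter_interpro(
    hits: Iterable[DomainHit],
    thresholds: FilterThresholds,
    dbd_catalog: frozenset[str] | set[str],
) -> list[DomainHit]:
    """Keep annotation rows that are significant TF DBDs.

    Rows with a missing e-value do not pass (they can re-enter through the
    relaxed MYB curation path only).
    """
    out: list[DomainHit] = []
    for h in hits:
        if h.evalue is None or h.evalue > thresholds.ipr_max_evalue:
            continue
        if h.domain_accession not in dbd_catalog:
            continue
        out.append(replace(h, significant=True))
    return out


def filter_hmmer(
    hits: Iterable[DomainHit],
    thresholds: FilterThresholds,
    profile_thresholds: Mapping[str, float] | None = None,
) -> list[DomainHit]:
    """Keep profile-HMM domain hits with a significant match.

    Under the ``per_profile_threshold`` policy a hit passes when its bit
    score reaches the profile's cutoff; profiles without a cutoff fall
    back to the fixed e-value. Under ``fixed_evalue`` only the e-value
    cutoff applies.
    """
    profile_thresholds = profile_thresholds or {}
    out: list[DomainHit] = []
    for h in hits:
        if thresholds.hmmer_policy == "per_profile_threshold":
            cutoff = profile_thresholds.get(h.domain_accession)
            if cutoff is not None:
                ok = h.score >= cutoff
            else:
                ok = h.evalue is not None and h.evalue <= thresholds.hmmer_fallback_evalue
        else:
            ok = h.evalue is not None and h.evalue <= thresholds.hmmer_fallback_evalue
        if ok:
            out.append(replace(h, significant=True))
    return out


@dataclass
class MergeResult:
    """Evidence bundles plus the raw hits kept for the MYB curation path."""

    bundles: dict[str, EvidenceBundle]
    raw_ipr_hits: list[DomainHit] = field(default_factory=list)


def merge_evidence(
    proteome: Sequence[ProteinRecord],
    blast_best: Mapping[str, BlastHit],
    ipr_hits: Iterable[DomainHit],
    hmmer_hits: Iterable[DomainHit],
) -> dict[str, EvidenceBundle]:
    """Combine the per-channel survivors into one bundle per protein.

    Only proteins with at least one surviving evidence item appear in the
    result; an evidence record naming a protein absent from the proteome
    is a consistency error.
    """
    known = {p.protein_id for p in proteome}
    bundles: dict[str, EvidenceBundle] = {}

    def bundle(pid: str) -> EvidenceBundle:
        if pid not in known:
            raise ValueError(f"evidence references unknown protein id {pid!r}")
        if pid not in bundles:
            bundles[pid] = EvidenceBundle(protein_id=pid)
        return bundles[pid]

    for qid, hit in blast_best.items():
        bundle(qid).best_blast = hit
    for h in ipr_hits:
        bundle(h.protein_id).domain_hits.append(h)
    for h in hmmer_hits:
        bundle(h.protein_id).domain_hits.append(h)
    for b in bundles.values():
        b.domain_hits.sort(key=lambda h: (h.ali_start, h.ali_end, h.domain_accession))
    return bundles
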
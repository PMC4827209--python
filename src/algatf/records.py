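"""Core record types shared across the pipeline.

All alignment coordinates are 1-based inclusive, matching the BLAST tabular
and profile-HMM per-domain dialects; no other module converts coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class EvidenceSource(str, Enum):
    """Where a domain hit came from."""

    HMMER_CUSTOM = "hmmer_custom"
    INTERPROSCAN = "interproscan"
    BLAST_DERIVED = "blast_derived"


@dataclass(frozen=True)
class ProteinRecord:
    """One entry of a predicted proteome."""

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for protein {self.protein_id!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BlastHit:
    """One row of 12-column tabular BLAST output."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError(
                f"q_start {self.q_start} > q_end {self.q_end} "
                f"for query {self.query_id!r}"
            )
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"percent identity {self.percent_identity} outside [0, 100]"
            )
        if self.evalue < 0:
            raise ValueError(f"negative e-value {self.evalue}")


@dataclass
class DomainHit:
    """One domain instance on one protein, from any evidence channel.

    ``evalue`` is the per-domain independent e-value where the dialect
    distinguishes one (filtering and copy-number rules act per instance).
    ``evalue`` is ``None`` when the source reports no numeric e-value
    (``evalue_missing`` is then set). ``significant`` is decided by the
    filter engine, never by the readers.
    """

    protein_id: str
    source: EvidenceSource
    domain_accession: str
    domain_name: str
    evalue: Optional[float]
    score: float
    ali_start: int
    ali_end: int
    member_db: Optional[str] = None
    significant: bool = False
    evalue_missing: bool = False

    def __post_init__(self) -> None:
        if self.ali_start > self.ali_end:
            raise ValueError(
                f"ali_start {self.ali_start} > ali_end {self.ali_end} "
                f"for protein {self.protein_id!r} ({self.domain_accession})"
            )
        if self.evalue is None:
            self.evalue_missing = True
        elif self.evalue < 0:
            raise ValueError(f"negative e-value {self.evalue}")

    @property
    def span(self) -> tuple[int, int]:
        return (self.ali_start, self.ali_end)


@dataclass
class EvidenceBundle:
    """All evidence surviving the filters for one protein."""

    protein_id: str
    best_blast: Optional[BlastHit] = None
    domain_hits: list[DomainHit] = field(default_factory=list)

    @property
    def channels(self) -> frozenset[str]:
        out: set[str] = set()
        if self.best_blast is not None:
            out.add("blast")
        for hit in self.domain_hits:
            if hit.source is EvidenceSource.HMMER_CUSTOM:
                out.add("hmmer")
            elif hit.source is EvidenceSource.INTERPROSCAN:
                out.add("interproscan")
        return frozenset(out)


UNCLASSIFIED = "unclassified"

#: curation flags attached to assignments
FLAG_MYB_RELAXED = "myb_relaxed_path"
FLAG_COPY_NUMBER = "copy_number_checked"
FLAG_SHAQKYF = "shaqkyf_motif"
FLAG_G2LIKE_CROSSCHECK = "g2like_crosscheck"
FLAG_BLAST_ONLY = "blast_only"


@dataclass
class Assignment:
    """Final family call for one protein."""

    protein_id: str
    family: str
    subfamily: Optional[str] = None
    supporting_hits: list[DomainHit] = field(default_factory=list)
    all_dbd_types: frozenset[str] = frozenset()
    curation_flags: set[str] = field(default_factory=set)

    @property
    def label(self) -> str:
        """Row label used in count tables (subfamily-qualified)."""
        return self.subfamily if self.subfamily is not None else self.family

    @property
    def is_classified(self) -> bool:
        return self.family != UNCLASSIFIED


@dataclass(frozen=True)
class GoldStandard:
    """Reference protein -> family labels used for benchmarking."""

    labels: dict[str, str]
    source_tag: str = ""

    def members(self, family: str) -> frozenset[str]:
        return frozenset(p for p, f in self.labels.items() if f == family)
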
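"""End-to-end orchestration: read -> filter -> merge -> classify."""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

from . import evidence_io
from .classify import classify_proteome
from .filtering import (
    FilterThresholds,
    filter_blast,
    filter_hmmer,
    filter_interpro,
    merge_evidence,
)
from .records import Assignment
from .rules import RuleSet, default_rules


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (serializable)."""

    fasta: str
    blast: Optional[str] = None
    domtbl: Optional[str] = None
    interpro: Optional[str] = None
    rules_path: Optional[str] = None
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    strict: bool = False

    def to_dict(self) -> dict:
        d = {
            "fasta": self.fasta,
            "blast": self.blast,
            "domtbl": self.domtbl,
            "interpro": self.interpro,
            "rules_path": self.rules_path,
            "strict": self.strict,
        }
        t = self.thresholds
        d["thresholds"] = {
            "blast_max_evalue": t.blast_max_evalue,
            "blast_min_identity": t.blast_min_identity,
            "blast_min_alnlen": t.blast_min_alnlen,
            "ipr_max_evalue": t.ipr_max_evalue,
            "hmmer_policy": t.hmmer_policy,
            "hmmer_fallback_evalue": t.hmmer_fallback_evalue,
        }
        return d


def run_classify(config: RunConfig) -> list[Assignment]:
    """Execute the full identification pipeline for one proteome.

    Deterministic: identical inputs and configuration give identical
    assignments (and identical output bytes through write_assignments).
    """
    from .rules import load_rules

    ruleset = (
        load_rules(config.rules_path) if config.rules_path else default_rules()
    )
    proteome = evidence_io.read_fasta(config.fasta)
    sequences = {p.protein_id: p.sequence for p in proteome}

    blast_hits = (
        evidence_io.read_blast_tab(config.blast) if config.blast else []
    )
    dom_hits = (
        evidence_io.read_domtblout(config.domtbl) if config.domtbl else []
    )
    ipr_hits = (
        evidence_io.read_interproscan_tsv(config.interpro)
        if config.interpro
        else []
    )

    t = config.thresholds
    best_blast = filter_blast(blast_hits, t)
    ipr_pass = filter_interpro(ipr_hits, t, ruleset.dbd_catalog)
    hmm_pass = filter_hmmer(dom_hits, t, ruleset.profile_thresholds)
    bundles = merge_evidence(proteome, best_blast, ipr_pass, hmm_pass)

    return classify_proteome(
        bundles,
        ruleset,
        sequences=sequences,
        raw_ipr_hits=ipr_hits,
        strict=config.strict,
    )


def summarize(assignments: list[Assignment]) -> dict[str, int]:
    """Per-family assignment counts (unclassified included)."""
    counts: dict[str, int] = {}
    for a in assignments:
        counts[a.label] = counts.get(a.label, 0) + 1
    return dict(sorted(counts.items()))
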
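"""Rule-based family classification and curation (Step Three + Final step).

The generic engine evaluates every family rule against a protein's
significant domain hits; among matching rules the highest-priority one
wins. Three curation heuristics mirror the manual steps of the original
protocol and run automatically:

* MYB — the annotation e-value filter is bypassed for MYB-domain
  evidence (the calibration stage of the original protocol showed it
  produced false negatives there); the repeat count splits the family
  into MYB (3R) / MYB (2R) / MYB-rel, and a SHAQKYF motif scan inside
  the repeats promotes single-repeat proteins to MYB-SHAQKYF.
* G2-like vs MYB-SHAQKYF — the two domains cross-annotate; proteins
  carrying both signals are re-scored and the higher profile bit score
  wins.
* Copy-number families (DBB, AP2) — handled declaratively through
  ``min_copies`` in the rules, backed by non-overlapping copy counting.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

from .records import (
    Assignment,
    DomainHit,
    EvidenceBundle,
    FLAG_BLAST_ONLY,
    FLAG_COPY_NUMBER,
    FLAG_G2LIKE_CROSSCHECK,
    FLAG_MYB_RELAXED,
    FLAG_SHAQKYF,
    UNCLASSIFIED,
)
from .rules import FamilyRule, RuleSet

#: two instances overlapping by more than this fraction of the shorter
#: one count as the same domain copy
OVERLAP_FRACTION = 0.5


def count_copies(hits: Sequence[DomainHit], accession_set: Iterable[str]) -> int:
    """Number of non-overlapping instances from ``accession_set``.

    Greedy selection by ascending start coordinate; an instance is not
    counted when it overlaps an already selected one by more than half of
    the shorter instance's length.
    """
    return len(select_copies(hits, accession_set))


def select_copies(
    hits: Sequence[DomainHit], accession_set: Iterable[str]
) -> list[DomainHit]:
    """The instances count_copies keeps (used to anchor motif scans)."""
    accs = set(accession_set)
    cands = sorted(
        (h for h in hits if h.domain_accession in accs),
        key=lambda h: (h.ali_start, h.ali_end),
    )
    kept: list[DomainHit] = []
    for h in cands:
        if all(not _same_copy(h, k) for k in kept):
            kept.append(h)
    return kept


def _same_copy(a: DomainHit, b: DomainHit) -> bool:
    overlap = min(a.ali_end, b.ali_end) - max(a.ali_start, b.ali_start) + 1
    if overlap <= 0:
        return False
    shorter = min(a.ali_end - a.ali_start + 1, b.ali_end - b.ali_start + 1)
    return overlap > OVERLAP_FRACTION * shorter


def _rule_matches(rule: FamilyRule, hits: Sequence[DomainHit]) -> bool:
    present = {h.domain_accession for h in hits}
    if present & rule.forbidden:
        return False
    for rs in rule.required:
        if count_copies(hits, rs.accessions) < rs.min_copies:
            return False
    return True


def classify_protein(
    bundle: EvidenceBundle,
    ruleset: RuleSet,
    strict: bool = False,
) -> Assignment:
    """Assign one protein to the highest-priority matching family rule.

    A protein whose only evidence is a best BLAST hit inherits the family
    encoded in the matched database subject id (disabled by ``strict``).
    """
    hits = bundle.domain_hits
    all_dbd = frozenset(
        h.domain_accession for h in hits if h.domain_accession in ruleset.dbd_catalog
    )
    for rule in ruleset.by_priority():
        if rule.motif is not None:
            continue  # curation-path families (motif scans) are not generic
        if _rule_matches(rule, hits):
            supporting = [
                h
                for h in hits
                if any(h.domain_accession in rs.accessions for rs in rule.required)
            ]
            flags = set()
            if any(rs.min_copies > 1 for rs in rule.required):
                flags.add(FLAG_COPY_NUMBER)
            return Assignment(
                protein_id=bundle.protein_id,
                family=rule.family,
                subfamily=rule.subfamily,
                supporting_hits=supporting,
                all_dbd_types=all_dbd,
                curation_flags=flags,
            )

    if bundle.best_blast is not None and not hits and not strict:
        label = ruleset.label_from_subject(bundle.best_blast.subject_id)
        if label is not None:
            rule = ruleset.rule(label)
            return Assignment(
                protein_id=bundle.protein_id,
                family=rule.family,
                subfamily=rule.subfamily,
                all_dbd_types=all_dbd,
                curation_flags={FLAG_BLAST_ONLY},
            )

    return Assignment(
        protein_id=bundle.protein_id,
        family=UNCLASSIFIED,
        all_dbd_types=all_dbd,
    )


def classify_myb(
    bundle: EvidenceBundle,
    ruleset: RuleSet,
    sequence: Optional[str] = None,
    raw_myb_hits: Sequence[DomainHit] = (),
) -> Assignment:
    """MYB curation path: relaxed e-value filtering + repeat counting.

    ``raw_myb_hits`` are MYB-domain annotation rows *before* the e-value
    filter; they re-enter here (``myb_relaxed_path``). The repeat count r
    over non-overlapping MYB instances maps to MYB (3R) (r >= 3),
    MYB (2R) (r == 2) or MYB-rel (r == 1); single-repeat proteins whose
    repeat sequence carries the SHAQKYF signature become MYB-SHAQKYF.
    """
    myb_accs = ruleset.myb_accessions
    merged: list[DomainHit] = [
        h for h in bundle.domain_hits if h.domain_accession in myb_accs
    ]
    seen = {(h.ali_start, h.ali_end, h.domain_accession) for h in merged}
    for h in raw_myb_hits:
        key = (h.ali_start, h.ali_end, h.domain_accession)
        if h.domain_accession in myb_accs and key not in seen:
            merged.append(h)
            seen.add(key)

    repeats = select_copies(merged, myb_accs)
    r = len(repeats)
    flags = {FLAG_MYB_RELAXED}
    all_dbd = frozenset(
        h.domain_accession
        for h in list(bundle.domain_hits) + merged
        if h.domain_accession in ruleset.dbd_catalog
    )
    if r >= 3:
        label = "MYB (3R)"
    elif r == 2:
        label = "MYB (2R)"
    elif r == 1:
        label = "MYB-rel"
    else:
        return Assignment(
            protein_id=bundle.protein_id, family=UNCLASSIFIED, all_dbd_types=all_dbd
        )

    if label == "MYB-rel" and sequence is not None:
        pattern = ruleset.shaqkyf_pattern()
        for h in repeats:
            sub = sequence[h.ali_start - 1 : h.ali_end]
            if pattern.search(sub):
                label = "MYB-SHAQKYF"
                flags.add(FLAG_SHAQKYF)
                break

    rule = ruleset.rule(label)
    return Assignment(
        protein_id=bundle.protein_id,
        family=rule.family,
        subfamily=rule.subfamily,
        supporting_hits=repeats,
        all_dbd_types=all_dbd,
        curation_flags=flags,
    )


_MYB_LABELS = {"MYB (3R)", "MYB (2R)", "MYB-rel", "MYB-SHAQKYF"}


def crosscheck_g2like(
    assignments: Sequence[Assignment],
    bundles: Mapping[str, EvidenceBundle],
    ruleset: RuleSet,
) -> list[Assignment]:
    """Resolve G2-like vs MYB-SHAQKYF cross-annotation by profile score.

    Every protein carrying both a G2-like profile hit and a SHAQKYF call
    is examined (flagged); the signal with the higher bit score decides
    the family.
    """
    out: list[Assignment] = []
    for a in assignments:
        bundle = bundles.get(a.protein_id)
        if bundle is None:
            out.append(a)
            continue
        g2_hits = [
            h
            for h in bundle.domain_hits
            if h.domain_accession in ruleset.g2like_accessions
        ]
        is_shaqkyf_call = a.label == "MYB-SHAQKYF" or FLAG_SHAQKYF in a.curation_flags
        if not (g2_hits and is_shaqkyf_call):
            out.append(a)
            continue
        a.curation_flags.add(FLAG_G2LIKE_CROSSCHECK)
        g2_score = max(h.score for h in g2_hits)
        myb_hits = [
            h
            for h in bundle.domain_hits
            if h.domain_accession in ruleset.myb_accessions
        ] or a.supporting_hits
        myb_score = max((h.score for h in myb_hits), default=float("-inf"))
        if g2_score > myb_score:
            rule = ruleset.rule("GARP-G2-like")
            a.family, a.subfamily = rule.family, rule.subfamily
            a.supporting_hits = g2_hits
        out.append(a)
    return out


def classify_proteome(
    bundles: Mapping[str, EvidenceBundle],
    ruleset: RuleSet,
    sequences: Optional[Mapping[str, str]] = None,
    raw_ipr_hits: Sequence[DomainHit] = (),
    strict: bool = False,
) -> list[Assignment]:
    """Classify every evidenced protein; deterministic, sorted by id.

    ``sequences`` (protein_id -> amino-acid string) enables the SHAQKYF
    motif scan; ``raw_ipr_hits`` (pre-filter annotation rows) enable the
    relaxed MYB path. Proteins matching no rule are retained as
    "unclassified".
    """
    sequences = sequences or {}
    myb_accs = ruleset.myb_accessions
    raw_myb_by_pid: dict[str, list[DomainHit]] = {}
    for h in raw_ipr_hits:
        if h.domain_accession in myb_accs:
            raw_myb_by_pid.setdefault(h.protein_id, []).append(h)

    assignments: list[Assignment] = []
    for pid in sorted(bundles):
        bundle = bundles[pid]
        base = classify_protein(bundle, ruleset, strict=strict)
        has_myb = bool(raw_myb_by_pid.get(pid)) or any(
            h.domain_accession in myb_accs for h in bundle.domain_hits
        )
        if has_myb and (base.label in _MYB_LABELS or base.family == UNCLASSIFIED):
            myb = classify_myb(
                bundle,
                ruleset,
                sequence=sequences.get(pid),
                raw_myb_hits=raw_myb_by_pid.get(pid, ()),
            )
            if myb.family != UNCLASSIFIED:
                myb.curation_flags |= base.curation_flags
                base = myb
        assignments.append(base)

    return crosscheck_g2like(assignments, bundles, ruleset)
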
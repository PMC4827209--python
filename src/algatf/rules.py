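"""Declarative family-assignment rules.

A transcription-factor family is defined by its DNA-binding-domain (DBD)
content: accession sets that must be hit (each with a minimum number of
non-overlapping copies), accessions that must be absent, and an integer
priority used to resolve conflicts between matching rules (larger wins;
more specific multi-domain / copy-number rules outrank superfamily
catch-alls). The bundled default rules file reconstructs the family
definitions of the major plant/algal/fungal/cyanobacterial TF catalogues;
it is data, replaceable by the user, not part of the algorithm.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import yaml


class RuleError(ValueError):
    """Rules file failed validation."""


@dataclass(frozen=True)
class RequiredSet:
    """One accession set a protein must hit, with a copy-number floor."""

    accessions: frozenset[str]
    min_copies: int = 1

    def __post_init__(self) -> None:
        if not self.accessions:
            raise RuleError("empty required accession set")
        if self.min_copies < 1:
            raise RuleError(f"min_copies must be >= 1, got {self.min_copies}")


@dataclass(frozen=True)
class FamilyRule:
    """Assignment rule for one family (or subfamily) row.

    ``label`` is the unique row name used in count tables; ``family`` is
    the grouping name (identical to label except where subfamilies share a
    family, e.g. AP2 and ERF both belong to family "AP2/ERF").
    """

    label: str
    family: str
    subfamily: Optional[str] = None
    superfamily: Optional[str] = None
    required: tuple[RequiredSet, ...] = ()
    forbidden: frozenset[str] = frozenset()
    priority: int = 0
    motif: Optional[str] = None  # key into RuleSet.motifs; curation-path rules

    def __post_init__(self) -> None:
        if not self.required:
            raise RuleError(f"rule {self.label!r} has no required accession sets")

    @property
    def accessions(self) -> frozenset[str]:
        out: set[str] = set()
        for rs in self.required:
            out |= rs.accessions
        return frozenset(out) | self.forbidden


@dataclass
class RuleSet:
    """Validated, ordered collection of family rules plus shared metadata."""

    rules: list[FamilyRule]
    motifs: dict[str, str] = field(default_factory=dict)
    myb_accessions: frozenset[str] = frozenset()
    g2like_accessions: frozenset[str] = frozenset()
    profile_thresholds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [r.label for r in self.rules]
        dupes = {x for x in labels if labels.count(x) > 1}
        if dupes:
            raise RuleError(f"duplicate family labels: {sorted(dupes)}")
        prios = [r.priority for r in self.rules]
        pdupes = {p for p in prios if prios.count(p) > 1}
        if pdupes:
            offenders = sorted(r.label for r in self.rules if r.priority in pdupes)
            raise RuleError(f"priority ties between rules: {offenders}")
        self._by_label = {r.label: r for r in self.rules}

    # -- lookups ----------------------------------------------------------
    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.rules]

    @property
    def dbd_catalog(self) -> frozenset[str]:
        """Union of all accessions the rules reference (the TF-DBD catalogue)."""
        out: set[str] = set()
        for r in self.rules:
            out |= r.accessions
        out |= self.myb_accessions | self.g2like_accessions
        return frozenset(out)

    def rule(self, label: str) -> FamilyRule:
        try:
            return self._by_label[label]
        except KeyError:
            raise RuleError(f"unknown family label {label!r}") from None

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    def by_priority(self) -> list[FamilyRule]:
        """Rules sorted highest priority first (the evaluation order)."""
        return sorted(self.rules, key=lambda r: -r.priority)

    def family_of_label(self, label: str) -> str:
        return self.rule(label).family

    def shaqkyf_pattern(self) -> re.Pattern:
        return re.compile(self.motifs.get("shaqkyf", "SH[AL]QK[YF]"))

    # -- BLAST subject naming convention ----------------------------------
    @staticmethod
    def slug(label: str) -> str:
        """Family label as it appears in TF-database subject ids (no spaces)."""
        return label.replace(" ", "_")

    def label_from_subject(self, subject_id: str) -> Optional[str]:
        """Resolve the family label encoded in a TF-database subject id.

        Subjects follow the convention ``<family_slug>|<entry>``; returns
        None when the prefix is not a known family.
        """
        slug = subject_id.split("|", 1)[0]
        for r in self.rules:
            if self.slug(r.label) == slug:
                return r.label
        return None


def _parse_rule(entry: dict) -> FamilyRule:
    try:
        label = entry["label"]
        required = tuple(
            RequiredSet(
                accessions=frozenset(rs["accessions"]),
                min_copies=int(rs.get("min_copies", 1)),
            )
            for rs in entry["required"]
        )
        return FamilyRule(
            label=label,
            family=entry.get("family", label),
            subfamily=entry.get("subfamily"),
            superfamily=entry.get("superfamily"),
            required=required,
            forbidden=frozenset(entry.get("forbidden", [])),
            priority=int(entry["priority"]),
            motif=entry.get("motif"),
        )
    except KeyError as exc:
        raise RuleError(f"rule entry missing field {exc}: {entry}") from exc


def load_rules(path: str | os.PathLike) -> RuleSet:
    """Load and validate a rules file (YAML; see the bundled default)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "families" not in doc:
        raise RuleError(f"{path}: rules file must contain a 'families' list")
    rules = [_parse_rule(e) for e in doc["families"]]
    return RuleSet(
        rules=rules,
        motifs=dict(doc.get("motifs", {})),
        myb_accessions=frozenset(doc.get("myb_accessions", [])),
        g2like_accessions=frozenset(doc.get("g2like_accessions", [])),
        profile_thresholds={
            str(k): float(v) for k, v in dict(doc.get("profile_thresholds", {})).items()
        },
    )


def default_rules() -> RuleSet:
    """The bundled default RuleSet (algal + plant + cyanobacterial families)."""
    ref = resources.files("algatf") / "data" / "family_rules.yaml"
    with resources.as_file(ref) as path:
        return load_rules(path)
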
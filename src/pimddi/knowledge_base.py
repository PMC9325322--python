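"""Versioned knowledge base of interaction rules, PIM rules and code sets.

The knowledge base bundles, in one JSON file:

* ``interactions`` — bleeding-risk drug–drug interaction rules between ATC
  patterns, each carrying a Theriaque severity level (1 contraindicated,
  2 not recommended, 3 use with caution, 4 to take into account) and/or a
  Micromedex severity (contraindicated / major / moderate), plus a mechanism
  class (pharmacodynamic, or pharmacokinetic via CYP2C9/2C19, CYP3A4, P-gp,
  or combined CYP3A4 + P-gp inhibition);
* ``pim_rules`` — Beers-criteria conditions under which an oral anticoagulant
  is a potentially inappropriate medication (age threshold, age + renal
  impairment, or a named warfarin drug combination);
* ``code_sets`` — ICD-10 bleeding diagnoses, anticoagulant-antidote ATC
  codes, oral-anticoagulant ATC codes and renal-impairment ICD-10 roots;
* ``charlson`` — a Quan ICD-10 mapping with original Charlson weights.

The shipped mini-KB is a small curated bundle restricted to published
anticoagulant pairs; each rule carries a ``source`` tag so users can swap in
a licensed full interaction database with the same schema.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

from .data_model import is_full_atc, normalize_atc

SCHEMA_VERSION = 1

#: Anticoagulant-antidote ATC codes: phytomenadione (vitamin K), idarucizumab,
#: andexanet alfa, human prothrombin complex.
ANTIDOTE_ATC = frozenset({"B02BA02", "V03AB37", "V03AB38", "B02BD01"})


class Mechanism(str, enum.Enum):
    PD = "PD"
    PK_CYP2C9_2C19 = "PK_CYP2C9_2C19"
    PK_CYP3A4 = "PK_CYP3A4"
    PK_PGP = "PK_PGP"
    PK_CYP3A4_PGP = "PK_CYP3A4_PGP"

    @property
    def is_pharmacokinetic(self) -> bool:
        return self is not Mechanism.PD


class MicromedexSeverity(str, enum.Enum):
    CONTRAINDICATED = "contraindicated"
    MAJOR = "major"
    MODERATE = "moderate"


class HarmonizedSeverity(str, enum.Enum):
    """Harmonized severity class with total order major > moderate > minor."""

    MAJOR = "major"
    MODERATE = "moderate"
    MINOR = "minor"

    @property
    def rank(self) -> int:
        return {"major": 3, "moderate": 2, "minor": 1}[self.value]

    def __lt__(self, other):  # type: ignore[override]
        if not isinstance(other, HarmonizedSeverity):
            return NotImplemented
        return self.rank < other.rank

    def __le__(self, other):  # type: ignore[override]
        if not isinstance(other, HarmonizedSeverity):
            return NotImplemented
        return self.rank <= other.rank


def harmonize_severity(
    severity_theriaque: int | None,
    severity_micromedex: MicromedexSeverity | str | None,
) -> HarmonizedSeverity:
    """Map dual-source severities onto one harmonized class.

    Theriaque levels 1 ("contraindicated") and 2 ("not recommended") map to
    *major*, level 3 ("use with caution") to *moderate* and level 4 ("to take
    into account") to *minor*.  Micromedex "contraindicated" and "major" map
    to *major*, "moderate" to *moderate*.  When both sources are present the
    more severe harmonized class wins (pharmacovigilance-conservative
    conflict resolution).
    """
    if severity_theriaque is None and severity_micromedex is None:
        raise ValueError("at least one severity source must be present")
    candidates: list[HarmonizedSeverity] = []
    if severity_theriaque is not None:
        if severity_theriaque not in (1, 2, 3, 4):
            raise ValueError(f"invalid Theriaque level {severity_theriaque!r}")
        candidates.append(
            {1: HarmonizedSeverity.MAJOR, 2: HarmonizedSeverity.MAJOR,
             3: HarmonizedSeverity.MODERATE, 4: HarmonizedSeverity.MINOR}[severity_theriaque]
        )
    if severity_micromedex is not None:
        mmx = MicromedexSeverity(severity_micromedex)
        candidates.append(
            HarmonizedSeverity.MODERATE
            if mmx is MicromedexSeverity.MODERATE
            else HarmonizedSeverity.MAJOR
        )
    return max(candidates, key=lambda s: s.rank)


# --------------------------------------------------------------------------
# ATC patterns
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AtcPattern:
    """Full ATC code, or a prefix wildcard with optional exclusions.

    String forms: ``"B01AA03"`` (exact), ``"J01FA*"`` (prefix) and
    ``"J01FA*!J01FA10"`` (prefix with ``!``-separated exclusions, e.g.
    macrolides except azithromycin).
    """

    pattern: str
    exclude: tuple[str, ...] = ()

    def __post_init__(self):
        pat = normalize_atc(self.pattern)
        object.__setattr__(self, "pattern", pat)
        object.__setattr__(self, "exclude", tuple(normalize_atc(x) for x in self.exclude))
        stem = pat[:-1] if pat.endswith("*") else pat
        if not stem or not stem[0].isalpha() or not all(c.isalnum() for c in stem):
            raise ValueError(f"malformed ATC pattern {self.pattern!r}")
        if not pat.endswith("*") and not is_full_atc(pat):
            raise ValueError(f"exact ATC pattern {self.pattern!r} is not a full 7-char code")

    @property
    def is_prefix(self) -> bool:
        return self.pattern.endswith("*")

    @classmethod
    def parse(cls, spec: "str | AtcPattern | Mapping") -> "AtcPattern":
        if isinstance(spec, AtcPattern):
            return spec
        if isinstance(spec, Mapping):
            return cls(spec["pattern"], tuple(spec.get("exclude", ())))
        spec = str(spec)
        if "!" in spec:
            head, *excl = spec.split("!")
            return cls(head, tuple(excl))
        return cls(spec)

    def __str__(self) -> str:
        return "!".join((self.pattern, *self.exclude))


def match_atc(code: str, pattern: "str | AtcPattern | Mapping") -> bool:
    """True iff the full 7-char ATC *code* matches *pattern*.

    A prefix pattern like ``J01FA*`` matches any code starting with the
    prefix; exclusions (themselves codes or prefixes) veto the match.
    """
    code = normalize_atc(code)
    if not is_full_atc(code):
        raise ValueError(f"{code!r} is not a full 7-character ATC code")
    pat = AtcPattern.parse(pattern)
    if pat.is_prefix:
        if not code.startswith(pat.pattern[:-1]):
            return False
    elif code != pat.pattern:
        return False
    return not any(code == ex or code.startswith(ex) for ex in pat.exclude)


# --------------------------------------------------------------------------
# rule types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class KBInteraction:
    """One unordered bleeding-risk interaction rule between two ATC patterns."""

    drug_a: AtcPattern
    drug_b: AtcPattern
    mechanism: Mechanism
    severity_theriaque: int | None = None
    severity_micromedex: MicromedexSeverity | None = None
    bleeding_risk: bool = True
    source: str = "curated-default"

    def __post_init__(self):
        if self.severity_theriaque is None and self.severity_micromedex is None:
            raise ValueError(
                f"interaction {self.drug_a}–{self.drug_b}: severity absent from both sources"
            )
        if self.severity_theriaque is not None and self.severity_theriaque not in (1, 2, 3, 4):
            raise ValueError(f"invalid Theriaque level {self.severity_theriaque!r}")

    @property
    def harmonized_severity(self) -> HarmonizedSeverity:
        return harmonize_severity(self.severity_theriaque, self.severity_micromedex)

    def pair_key(self) -> frozenset[str]:
        return frozenset({str(self.drug_a), str(self.drug_b)})

    def match_pair(self, code_x: str, code_y: str) -> bool:
        """Unordered match of two full ATC codes against the rule."""
        return (match_atc(code_x, self.drug_a) and match_atc(code_y, self.drug_b)) or (
            match_atc(code_x, self.drug_b) and match_atc(code_y, self.drug_a)
        )


@dataclass(frozen=True)
class PIMRule:
    """One Beers condition for an oral anticoagulant.

    ``min_age_alone`` — PIM from this age regardless of renal function;
    ``min_age_with_renal`` — PIM from this age in the presence of renal
    impairment; ``partner_patterns`` — warfarin-style drug combinations that
    make the anticoagulant a PIM at ≥ 65 years.
    """

    anticoag_atc: str
    min_age_alone: int | None = None
    min_age_with_renal: int | None = None
    partner_patterns: tuple[AtcPattern, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "anticoag_atc", normalize_atc(self.anticoag_atc))
        if (
            self.min_age_alone is None
            and self.min_age_with_renal is None
            and not self.partner_patterns
        ):
            raise ValueError(f"PIM rule for {self.anticoag_atc} has no condition")


@dataclass(frozen=True)
class CodeSet:
    name: str
    codes: tuple[str, ...]

    def __post_init__(self):
        if not self.codes:
            raise ValueError(f"code set {self.name!r} is empty")

    def matches_icd10(self, code: str) -> bool:
        """Prefix match with dots ignored (3–4 character roots allowed)."""
        code = str(code).replace(".", "").strip().upper()
        return any(code.startswith(c.replace(".", "").strip().upper()) for c in self.codes)

    def matches_atc(self, code: str) -> bool:
        code = normalize_atc(code)
        return any(code == c or code.startswith(c) for c in (normalize_atc(c) for c in self.codes))


@dataclass(frozen=True)
class CharlsonCategory:
    name: str
    weight: int
    codes: tuple[str, ...]
    supersedes: str | None = None  # hierarchy: this category silences another


@dataclass
class KnowledgeBase:
    interactions: tuple[KBInteraction, ...]
    pim_rules: tuple[PIMRule, ...]
    code_sets: dict[str, CodeSet]
    charlson: tuple[CharlsonCategory, ...] = ()
    schema_version: int = SCHEMA_VERSION
    provenance: str = ""
    errors: list[str] = field(default_factory=list)

    # -- convenience views -------------------------------------------------
    @property
    def anticoagulants(self) -> CodeSet:
        return self.code_sets["anticoagulant_atc"]

    @property
    def bleeding_icd10(self) -> CodeSet:
        return self.code_sets["bleeding_icd10"]

    @property
    def antidote_atc(self) -> CodeSet:
        return self.code_sets["antidote_atc"]

    @property
    def renal_impairment_icd10(self) -> CodeSet:
        return self.code_sets["renal_impairment_icd10"]

    def is_anticoagulant(self, code: str) -> bool:
        return self.anticoagulants.matches_atc(code)

    def pim_rule_for(self, atc_code: str) -> PIMRule | None:
        code = normalize_atc(atc_code)
        for rule in self.pim_rules:
            if rule.anticoag_atc == code:
                return rule
        return None

    def find_interactions(self, code_x: str, code_y: str) -> list[KBInteraction]:
        """All bleeding-risk rules matching the unordered code pair."""
        return [
            r
            for r in self.interactions
            if r.bleeding_risk and r.match_pair(code_x, code_y)
        ]

    def validate(self) -> list[str]:
        """Re-run structural validation; returns a list of problems."""
        problems = list(self.errors)
        if "antidote_atc" in self.code_sets:
            got = set(self.code_sets["antidote_atc"].codes)
            if got != set(ANTIDOTE_ATC):
                problems.append(f"antidote set must be exactly {sorted(ANTIDOTE_ATC)}, got {sorted(got)}")
        for name in ("anticoagulant_atc", "bleeding_icd10", "renal_impairment_icd10"):
            if name not in self.code_sets:
                problems.append(f"missing code set {name!r}")
        return problems


class KBLoadError(ValueError):
    pass


def _default_kb_path() -> Path:
    return Path(str(resources.files("pimddi").joinpath("data/kb.json")))


def load_kb(
    path: str | Path | None = None,
    *,
    include_heparin_pairs: bool = True,
    strict: bool = True,
) -> KnowledgeBase:
    """Load and validate a knowledge base bundle.

    Parameters
    ----------
    path
        JSON bundle; ``None`` loads the shipped curated mini-KB.
    include_heparin_pairs
        Whether DOAC/VKA–heparin pharmacodynamic pairs (the temporary
        co-prescription during a switch) count as interactions.
    strict
        Raise :class:`KBLoadError` on any rejected rule instead of collecting
        rejection messages in ``kb.errors``.
    """
    path = _default_kb_path() if path is None else Path(path)
    if not path.exists():
        raise KBLoadError(f"{path}: knowledge base file not found")
    raw = json.loads(path.read_text(encoding="utf-8"))
    if raw.get("schema_version") != SCHEMA_VERSION:
        raise KBLoadError(
            f"{path}: schema_version {raw.get('schema_version')!r} != {SCHEMA_VERSION}"
        )

    errors: list[str] = []
    interactions: list[KBInteraction] = []
    seen_pairs: set[frozenset[str]] = set()
    for i, item in enumerate(raw.get("interactions", [])):
        try:
            mmx = item.get("severity_micromedex")
            rule = KBInteraction(
                drug_a=AtcPattern.parse(item["drug_a"]),
                drug_b=AtcPattern.parse(item["drug_b"]),
                mechanism=Mechanism(item["mechanism"]),
                severity_theriaque=item.get("severity_theriaque"),
                severity_micromedex=MicromedexSeverity(mmx) if mmx else None,
                bleeding_risk=bool(item.get("bleeding_risk", True)),
                source=item.get("source", "curated-default"),
            )
        except (KeyError, ValueError) as exc:
            errors.append(f"interactions[{i}]: rejected ({exc})")
            continue
        key = rule.pair_key()
        if key in seen_pairs:
            errors.append(f"interactions[{i}]: duplicate unordered pair {sorted(key)}")
            continue
        if not include_heparin_pairs and item.get("heparin_switch", False):
            continue
        seen_pairs.add(key)
        interactions.append(rule)

    pim_rules: list[PIMRule] = []
    for i, item in enumerate(raw.get("pim_rules", [])):
        try:
            pim_rules.append(
                PIMRule(
                    anticoag_atc=item["anticoag_atc"],
                    min_age_alone=item.get("min_age_alone"),
                    min_age_with_renal=item.get("min_age_with_renal"),
                    partner_patterns=tuple(
                        AtcPattern.parse(p) for p in item.get("partner_patterns", [])
                    ),
                )
            )
        except (KeyError, ValueError) as exc:
            errors.append(f"pim_rules[{i}]: rejected ({exc})")

    code_sets: dict[str, CodeSet] = {}
    for name, codes in raw.get("code_sets", {}).items():
        try:
            code_sets[name] = CodeSet(name, tuple(codes))
        except ValueError as exc:
            errors.append(f"code_sets[{name}]: rejected ({exc})")

    charlson = tuple(
        CharlsonCategory(
            name=c["name"],
            weight=int(c["weight"]),
            codes=tuple(c["codes"]),
            supersedes=c.get("supersedes"),
        )
        for c in raw.get("charlson", [])
    )

    kb = KnowledgeBase(
        interactions=tuple(interactions),
        pim_rules=tuple(pim_rules),
        code_sets=code_sets,
        charlson=charlson,
        provenance=raw.get("provenance", str(path)),
        errors=errors,
    )
    structural = kb.validate()
    if strict and structural:
        raise KBLoadError(f"{path}: " + "; ".join(structural))
    return kb
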
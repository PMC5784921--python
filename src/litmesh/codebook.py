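"""Declarative codebook: inclusion/exclusion screening and WHO-framework coding.

The corpus-curation rules the pipeline applies are MeSH-level and fully
declarative: a record enters the corpus if it carries at least one
cardiovascular-disease descriptor, is rejected if it carries an
other-disease descriptor, and is rejected if its only substantive content
(after setting aside demographic check-tags and the CVD terms themselves)
consists of classic risk factors.  Every surviving descriptor is assigned a
category of the WHO Commission on Social Determinants of Health framework:
structural determinants (context and socioeconomic position) versus
intermediary determinants (health system and other mediators).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import yaml

from .gazetteer import country_names
from .medline import Corpus, MeshEntity

CATEGORIES = (
    "structural-context",
    "structural-position",
    "intermediary-health-system",
    "intermediary-other",
    "cvd-outcome",
    "uncategorized",
)


class CodeBookError(ValueError):
    """Invalid codebook configuration."""


def _fold(terms) -> frozenset[str]:
    return frozenset(t.casefold() for t in terms)


@dataclass(frozen=True)
class CodeBook:
    """Inclusion/exclusion/stop lists plus descriptor → category mapping.

    All matching is case-insensitive on the descriptor and ignores the
    major-topic flag.
    """

    inclusion_terms: frozenset[str]
    exclusion_terms: frozenset[str]
    risk_factors: frozenset[str] = frozenset()
    demographics: frozenset[str] = frozenset()
    stoplist: frozenset[str] = frozenset()
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = _fold(self.inclusion_terms) & _fold(self.exclusion_terms)
        if overlap:
            raise CodeBookError(
                f"terms in both inclusion and exclusion lists: {sorted(overlap)}"
            )
        bad = set(self.categories.values()) - set(CATEGORIES)
        if bad:
            raise CodeBookError(f"unknown categories: {sorted(bad)}")

    # -- matching helpers (descriptor-level, case-insensitive) ------------

    def _has(self, record, terms: frozenset[str]) -> bool:
        folded = _fold(terms)
        return any(e.descriptor.casefold() in folded for e in record.mesh)

    def is_included(self, record) -> bool:
        return self._has(record, self.inclusion_terms)

    def is_excluded_disease(self, record) -> bool:
        return self._has(record, self.exclusion_terms)

    def is_risk_factor_only(self, record) -> bool:
        """True when all substantive descriptors are classic risk factors.

        Demographic check-tags, CVD (inclusion) terms and stop-listed terms
        are set aside; if the non-empty remainder lies entirely within the
        risk-factor list the record has no social-determinants content of
        its own.  An empty remainder is not grounds for rejection.
        """
        ignore = (
            _fold(self.demographics)
            | _fold(self.inclusion_terms)
            | _fold(self.stoplist)
        )
        remainder = {
            e.descriptor.casefold()
            for e in record.mesh
            if e.descriptor.casefold() not in ignore
        }
        return bool(remainder) and remainder <= _fold(self.risk_factors)

    def is_stoplisted(self, entity: MeshEntity) -> bool:
        return entity.descriptor.casefold() in _fold(self.stoplist)

    def category_of(self, entity: MeshEntity) -> str:
        return self.categories.get(entity.descriptor.casefold(), "uncategorized")


@dataclass
class FilterReport:
    """Per-rule audit of the screening stage."""

    retrieved: int = 0
    excluded_screening: int = 0
    assessed: int = 0
    per_rule: dict[str, int] = field(default_factory=dict)

    def check_arithmetic(self) -> None:
        dropped = sum(self.per_rule.values())
        if self.retrieved != self.assessed + dropped:
            raise AssertionError(
                f"filter arithmetic broken: {self.retrieved} != "
                f"{self.assessed} + {dropped}"
            )

    def to_frame(self):
        import pandas as pd

        rows = [("retrieved", self.retrieved)]
        rows += [(f"dropped:{k}", v) for k, v in self.per_rule.items()]
        rows.append(("assessed", self.assessed))
        return pd.DataFrame(rows, columns=["step", "count"])


def load_codebook(path: str | None = None, gazetteer: dict[str, str] | None = None) -> CodeBook:
    """Load a codebook from YAML; the packaged default when ``path`` is None.

    The ``categories`` section is written category → list-of-descriptors and
    inverted here; a descriptor listed under two categories is a
    configuration error, as is any overlap between inclusion and exclusion.
    With ``stoplist_countries: true`` every gazetteer country name joins the
    stoplist.
    """
    if path is None:
        with resources.files("litmesh.data").joinpath("codebook_default.yaml").open(
            encoding="utf-8"
        ) as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)

    categories: dict[str, str] = {}
    for cat, terms in (raw.get("categories") or {}).items():
        if cat not in CATEGORIES:
            raise CodeBookError(f"unknown category {cat!r}")
        for term in terms or []:
            key = term.casefold()
            if key in categories and categories[key] != cat:
                raise CodeBookError(
                    f"descriptor {term!r} mapped to both {categories[key]!r} and {cat!r}"
                )
            categories[key] = cat

    stoplist = set(raw.get("stoplist") or [])
    if raw.get("stoplist_countries"):
        stoplist |= country_names(gazetteer)

    return CodeBook(
        inclusion_terms=frozenset(raw.get("inclusion") or []),
        exclusion_terms=frozenset(raw.get("exclusion") or []),
        risk_factors=frozenset(raw.get("risk_factors") or []),
        demographics=frozenset(raw.get("demographics") or []),
        stoplist=frozenset(stoplist),
        categories=categories,
    )


def apply_inclusion_exclusion(corpus: Corpus, codebook: CodeBook):
    """Screen a deduplicated corpus; returns (filtered corpus, report).

    Rules, each applied to every record independently (record fate depends
    only on its own descriptors, so the operation is idempotent and
    order-independent across records):

    1. no inclusion (CVD) descriptor → excluded at screening;
    2. any exclusion-disease descriptor → dropped;
    3. risk-factor-only content → dropped.
    """
    report = FilterReport(retrieved=len(corpus.records))
    kept = []
    rules = {"no_inclusion_term": 0, "exclusion_disease": 0, "risk_factor_only": 0}
    for record in corpus.records:
        if not codebook.is_included(record):
            rules["no_inclusion_term"] += 1
        elif codebook.is_excluded_disease(record):
            rules["exclusion_disease"] += 1
        elif codebook.is_risk_factor_only(record):
            rules["risk_factor_only"] += 1
        else:
            kept.append(record)
    report.per_rule = rules
    report.excluded_screening = rules["no_inclusion_term"]
    report.assessed = len(kept)
    report.check_arithmetic()

    out = Corpus(records=kept, provenance=dict(corpus.provenance))
    out.log_step("inclusion_exclusion", len(corpus.records), len(kept))
    return out, report


def categorize_terms(graph_terms, codebook: CodeBook) -> dict[MeshEntity, str]:
    """Map every entity to its WHO-framework category ('uncategorized' default)."""
    return {entity: codebook.category_of(entity) for entity in graph_terms}


def edge_class(category_a: str, category_b: str) -> str:
    """Classify an edge by its endpoint categories.

    'structural' when both endpoints are structural determinants,
    'intermediary' when both are intermediary, 'mixed' otherwise.
    """
    if category_a.startswith("structural") and category_b.startswith("structural"):
        return "structural"
    if category_a.startswith("intermediary") and category_b.startswith("intermediary"):
        return "intermediary"
    return "mixed"
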
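"""Reading, validating and writing MEDLINE plain-text bibliographic records.

MEDLINE exports are line-oriented: a 4-character tag, a ``- `` separator and
a value, with continuation lines indented by six spaces.  Each record carries
the fields this pipeline consumes: the PubMed identifier (PMID), title (TI),
abstract (AB), MeSH headings (MH), publication date (DP) and author
affiliation (AD).  Parsing is delegated to :mod:`Bio.Medline`; a validation
pre-pass enforces the tagged-line grammar so malformed lines are warned about
and skipped instead of being silently misread as new tags.

MeSH headings may carry qualifiers after a ``/`` and an asterisk marking the
heading as a *major topic* of the article.  Qualifiers are stripped; the
asterisk (on the descriptor or on any qualifier) is kept as a flag, and a
major-topic heading is treated as a distinct entity from its plain form.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field

from Bio import Medline

logger = logging.getLogger(__name__)

_TAG_LINE = re.compile(r"^[A-Z0-9]{1,4}\s*- ")
_CONTINUATION = re.compile(r"^\s{5,}\S")

YEAR_MIN, YEAR_MAX = 1900, 2100


@dataclass(frozen=True, order=True)
class MeshEntity:
    """A MeSH descriptor with its major-topic flag.

    The flag is part of the identity: ``Social Class`` and major-topic
    ``*Social Class`` are distinct entities (and distinct network nodes).
    """

    descriptor: str
    major_topic: bool = False

    def __post_init__(self) -> None:
        if not self.descriptor:
            raise ValueError("MeSH descriptor must be non-empty")
        if "/" in self.descriptor:
            raise ValueError(f"descriptor contains qualifier text: {self.descriptor!r}")

    @property
    def label(self) -> str:
        """Display form: the descriptor, ``*``-prefixed when major topic."""
        return ("*" if self.major_topic else "") + self.descriptor

    @classmethod
    def from_label(cls, label: str) -> "MeshEntity":
        if label.startswith("*"):
            return cls(label[1:], True)
        return cls(label, False)

    @classmethod
    def from_mh_value(cls, value: str) -> "MeshEntity":
        """Parse one MH field value.

        Qualifiers after ``/`` are dropped; a leading ``*`` on the descriptor
        or on any qualifier sets the major-topic flag.
        """
        parts = value.strip().split("/")
        descriptor = parts[0].strip()
        major = descriptor.startswith("*") or any(
            q.strip().startswith("*") for q in parts[1:]
        )
        return cls(descriptor.lstrip("*").strip(), major)


@dataclass
class MedlineRecord:
    """One bibliographic record with the fields the pipeline consumes."""

    pmid: str
    title: str = ""
    abstract: str = ""
    mesh: tuple[MeshEntity, ...] = ()
    year: int | None = None
    country: str = "Unknown"
    raw_fields: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValueError("pmid must be non-empty")
        if len(set(self.mesh)) != len(self.mesh):
            raise ValueError(f"duplicate MeSH entities in record {self.pmid}")
        if self.year is not None and not (YEAR_MIN <= self.year <= YEAR_MAX):
            raise ValueError(f"year {self.year} outside [{YEAR_MIN}, {YEAR_MAX}]")


@dataclass
class Corpus:
    """An ordered collection of records plus a processing audit trail.

    ``provenance`` maps each processing step to its before/after record
    counts, in application order.
    """

    records: list[MedlineRecord] = field(default_factory=list)
    provenance: dict[str, dict[str, int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def log_step(self, name: str, before: int, after: int) -> None:
        if before < 0 or after < 0 or after > before:
            raise ValueError(f"provenance counts for {name!r} not non-increasing")
        self.provenance[name] = {"before": before, "after": after}

    def pmids(self) -> list[str]:
        return [r.pmid for r in self.records]


def extract_year(dp_field: str) -> int | None:
    """First 4-digit token of a MEDLINE DP value inside [1900, 2100].

    >>> extract_year("1996 Jul-Aug")
    1996
    >>> extract_year("n.d.") is None
    True
    """
    for token in re.findall(r"\d{4}", dp_field or ""):
        year = int(token)
        if YEAR_MIN <= year <= YEAR_MAX:
            return year
    return None


_EMAIL = re.compile(r"\S+@\S+")


def extract_country(ad_field: str, gazetteer: dict[str, str]) -> str:
    """Resolve the affiliation's country against a gazetteer.

    ``gazetteer`` maps lower-cased surface forms (``"uk"``, ``"united
    kingdom"``, ``"usa"``) to canonical country names.  The final
    comma-separated tokens of the first affiliation are tried from the end
    backwards, longest run first, so ``"London, UK."`` resolves via ``UK``
    and ``"Mexico City, Mexico"`` via the last token even when an earlier
    token ("Mexico City") also contains a country name.  Returns
    ``"Unknown"`` on no match.
    """
    if not ad_field:
        return "Unknown"
    text = _EMAIL.sub("", ad_field.split(";")[0])
    text = re.sub(r"(?i)electronic address:?", "", text)
    tokens = [t.strip(" .\t") for t in text.split(",")]
    tokens = [t for t in tokens if t]
    # Longest-match: try joined runs of trailing tokens, longest first,
    # then walk backwards token by token.
    for start in range(max(0, len(tokens) - 3), len(tokens)):
        joined = ", ".join(tokens[start:]).lower()
        if joined in gazetteer:
            return gazetteer[joined]
    for token in reversed(tokens):
        key = token.lower()
        if key in gazetteer:
            return gazetteer[key]
        # tolerate trailing postcodes: "Cambridge CB2 0QQ UK"
        words = key.split()
        for n in (3, 2, 1):
            if len(words) >= n and " ".join(words[-n:]) in gazetteer:
                return gazetteer[" ".join(words[-n:])]
    return "Unknown"


def _validate_lines(stream) -> tuple[list[str], int]:
    """Drop lines violating the tagged-format grammar, counting them."""
    kept: list[str] = []
    skipped = 0
    for lineno, line in enumerate(stream, 1):
        stripped = line.rstrip("\n")
        if not stripped.strip():
            kept.append(stripped)
        elif _TAG_LINE.match(stripped) or _CONTINUATION.match(stripped):
            kept.append(stripped)
        else:
            logger.warning("skipping malformed MEDLINE line %d: %r", lineno, stripped)
            skipped += 1
    return kept, skipped


def parse_medline(stream, gazetteer: dict[str, str] | None = None) -> Corpus:
    """Parse a MEDLINE plain-text stream into a :class:`Corpus`.

    One :class:`MedlineRecord` per input record; records lacking a PMID are
    dropped and counted in provenance; duplicate MeSH entities within a
    record are collapsed to the first occurrence.
    """
    if gazetteer is None:
        from .gazetteer import load_gazetteer

        gazetteer = load_gazetteer()
    if isinstance(stream, (str, bytes)):
        raise TypeError("parse_medline expects a text stream, not a string; wrap in io.StringIO")
    lines, n_malformed = _validate_lines(stream)
    raw_records = list(Medline.parse(io.StringIO("\n".join(lines) + "\n")))
    raw_records = [r for r in raw_records if r]

    corpus = Corpus()
    dropped_no_pmid = 0
    for raw in raw_records:
        pmid = (raw.get("PMID") or "").strip()
        if not pmid:
            logger.warning("dropping record without PMID: %s", dict(raw))
            dropped_no_pmid += 1
            continue
        mesh: list[MeshEntity] = []
        for mh in raw.get("MH", []):
            entity = MeshEntity.from_mh_value(mh)
            if entity not in mesh:
                mesh.append(entity)
        ad = raw.get("AD", "")
        if isinstance(ad, list):
            ad = ad[0] if ad else ""
        raw_fields = {
            tag: tuple(v) if isinstance(v, list) else (v,) for tag, v in raw.items()
        }
        corpus.records.append(
            MedlineRecord(
                pmid=pmid,
                title=raw.get("TI", ""),
                abstract=raw.get("AB", ""),
                mesh=tuple(mesh),
                year=extract_year(raw.get("DP", "")),
                country=extract_country(ad, gazetteer),
                raw_fields=raw_fields,
            )
        )
    corpus.log_step("parse", len(raw_records), len(corpus.records))
    if n_malformed:
        corpus.provenance["parse"]["malformed_lines"] = n_malformed
    return corpus


def deduplicate(corpus: Corpus) -> Corpus:
    """Keep the first occurrence of each PMID, drop later ones."""
    seen: set[str] = set()
    kept: list[MedlineRecord] = []
    for record in corpus.records:
        if record.pmid not in seen:
            seen.add(record.pmid)
            kept.append(record)
    out = Corpus(records=kept, provenance=dict(corpus.provenance))
    out.log_step("deduplicate", len(corpus.records), len(kept))
    return out


def _wrap_field(tag: str, value: str) -> list[str]:
    head = f"{tag:<4}- "
    return [head + value]


def write_corpus(corpus: Corpus, stream) -> None:
    """Emit MEDLINE tagged format parseable by :func:`parse_medline`.

    Records with ``raw_fields`` are written from them verbatim (full
    round-trip); otherwise the canonical fields are serialized.
    """
    for i, record in enumerate(corpus.records):
        if i:
            stream.write("\n")
        if record.raw_fields:
            for tag, values in record.raw_fields.items():
                for value in values:
                    for line in _wrap_field(tag, value):
                        stream.write(line + "\n")
            continue
        stream.write(f"PMID- {record.pmid}\n")
        if record.title:
            stream.write(f"TI  - {record.title}\n")
        if record.abstract:
            stream.write(f"AB  - {record.abstract}\n")
        if record.year is not None:
            stream.write(f"DP  - {record.year}\n")
        for entity in record.mesh:
            stream.write(f"MH  - {entity.label}\n")
        if record.country != "Unknown":
            stream.write(f"AD  - {record.country}.\n")


def corpus_to_jsonl(corpus: Corpus, stream) -> None:
    """Serialize one record per line (structured intermediate storage)."""
    import json

    for r in corpus.records:
        stream.write(
            json.dumps(
                {
                    "pmid": r.pmid,
                    "title": r.title,
                    "abstract": r.abstract,
                    "mesh": [e.label for e in r.mesh],
                    "year": r.year,
                    "country": r.country,
                },
                ensure_ascii=False,
            )
            + "\n"
        )


def corpus_from_jsonl(stream) -> Corpus:
    import json

    corpus = Corpus()
    for line in stream:
        if not line.strip():
            continue
        obj = json.loads(line)
        corpus.records.append(
            MedlineRecord(
                pmid=obj["pmid"],
                title=obj.get("title", ""),
                abstract=obj.get("abstract", ""),
                mesh=tuple(MeshEntity.from_label(x) for x in obj.get("mesh", [])),
                year=obj.get("year"),
                country=obj.get("country", "Unknown"),
            )
        )
    corpus.log_step("load_jsonl", len(corpus.records), len(corpus.records))
    return corpus
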
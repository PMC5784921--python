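"""Seeded generator of MEDLINE-format corpora with known ground truth.

The generator emulates the statistical structure the analysis assumes of a
real literature corpus: a thematic block structure (articles draw most of
their MeSH terms from one stratum of the WHO social-determinants framework,
which induces clustering in the co-occurrence network), a handful of hub
terms present in a large fraction of records (the demographic check-tags
Female / Male / Middle Aged … that dominate the published degree rankings),
skewed country output, linear growth of publication counts over the study
window, and an eligibility mix (records with/without cardiovascular
inclusion terms, with excluded diseases, or with risk-factor-only content).

Every random draw is recorded in a :class:`GroundTruth` bundle, so each
pipeline stage can be checked exactly: eligibility labels against the
filter, year × country tallies against the trend matrix, and per-article
pair counts against the network's total edge weight.  A single
``random.Random(seed)`` stream with a fixed draw order makes output
byte-identical across runs and platforms.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

#: Thematic term blocks, one per WHO-framework stratum plus classic risk
#: factors.  Terms deliberately mirror the packaged default codebook.
DEFAULT_BLOCKS: dict[str, tuple[str, ...]] = {
    "structural-position": (
        "Socioeconomic Factors",
        "Social Class",
        "Poverty",
        "Education",
        "Income",
        "Occupations",
        "Employment",
        "Health Status Disparities",
        "Residence Characteristics",
        "Ethnic Groups",
        "Sex Factors",
    ),
    "structural-context": (
        "Social Determinants of Health",
        "Health Policy",
        "Public Policy",
        "Public Health",
        "Politics",
        "Culture",
        "Government",
        "World Health Organization",
        "Global Health",
        "Environment",
    ),
    "health-system": (
        "Health Promotion",
        "Health Services Accessibility",
        "Health Services Needs and Demand",
        "Delivery of Health Care",
        "Insurance, Health",
        "Health Services, Indigenous",
    ),
    "intermediary-other": (
        "Life Style",
        "Aging",
        "Health Status",
        "Child Development",
        "Food Supply",
        "Housing",
        "Social Support",
        "Social Environment",
    ),
    "risk-factors": (
        "Obesity",
        "Smoking",
        "Physical Inactivity",
        "Diabetes Mellitus",
        "Stress",
        "Metabolic Syndrome",
        "Hypertension",
        "Cholesterol",
    ),
}

DEFAULT_BLOCK_WEIGHTS = {
    "structural-position": 0.25,
    "structural-context": 0.25,
    "health-system": 0.15,
    "intermediary-other": 0.20,
    "risk-factors": 0.15,
}

#: Demographic (plus generic Risk Factors) hub terms with their
#: per-record inclusion probabilities, emulating the published hub ranking.
DEFAULT_HUBS: tuple[tuple[str, float], ...] = (
    ("Female", 0.55),
    ("Male", 0.50),
    ("Middle Aged", 0.45),
    ("Risk Factors", 0.40),
    ("Adult", 0.35),
    ("Aged", 0.30),
)

DEFAULT_INCLUSION_TERMS = (
    "Acute Coronary Syndrome",
    "Myocardial Infarction",
    "Heart Diseases",
    "Angina Pectoris",
)

DEFAULT_EXCLUSION_TERMS = (
    "Rheumatic Fever",
    "Lung Diseases",
    "Lupus Erythematosus",
    "Neoplasms",
    "Pneumonia",
    "Dementia",
    "Parkinson Disease",
)

DEFAULT_COUNTRY_WEIGHTS = {
    "United States": 0.24,
    "United Kingdom": 0.20,
    "Canada": 0.12,
    "Australia": 0.09,
    "Sweden": 0.06,
    "Netherlands": 0.05,
    "Germany": 0.05,
    "Spain": 0.04,
    "Brazil": 0.04,
    "China": 0.03,
    "Norway": 0.03,
    "New Zealand": 0.03,
    "Mexico": 0.02,
}

#: Surface forms used to render affiliations (exercises gazetteer synonyms).
_COUNTRY_SURFACE = {
    "United States": ("USA", "United States", "US"),
    "United Kingdom": ("UK", "United Kingdom", "England"),
    "Netherlands": ("The Netherlands", "Netherlands"),
    "China": ("China", "PR China"),
}

_QUALIFIERS = ("epidemiology", "economics", "trends", "statistics & numerical data")

_CITIES = (
    "Springfield",
    "Riverton",
    "Lakeside",
    "Hillcrest",
    "Fairview",
    "Brookfield",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic corpus.

    ``terms_per_record`` is 2 + Poisson(``extra_terms_mean``) thematic-block
    terms per record (minimum two, so almost every record contributes
    co-occurrence pairs); hub, inclusion, exclusion and always-on terms are
    added on top of that.
    """

    n_records: int = 1000
    blocks: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_BLOCKS)
    )
    block_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BLOCK_WEIGHTS)
    )
    hub_terms: tuple[tuple[str, float], ...] = DEFAULT_HUBS
    min_terms: int = 2
    extra_terms_mean: float = 4.0
    major_topic_prob: float = 0.20
    qualifier_prob: float = 0.30
    year_range: tuple[int, int] = (1980, 2015)
    year_weights: tuple[float, ...] | None = None  # None → linear growth
    country_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COUNTRY_WEIGHTS)
    )
    unknown_affiliation_prob: float = 0.05
    undated_prob: float = 0.02
    inclusion_frac: float = 0.30
    exclusion_frac: float = 0.10
    inclusion_terms: tuple[str, ...] = DEFAULT_INCLUSION_TERMS
    exclusion_terms: tuple[str, ...] = DEFAULT_EXCLUSION_TERMS
    always_terms: tuple[str, ...] = ("Humans",)
    risk_block: str = "risk-factors"
    demographics: tuple[str, ...] = (
        "Female",
        "Male",
        "Middle Aged",
        "Adult",
        "Aged",
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.major_topic_prob,
            self.qualifier_prob,
            self.inclusion_frac,
            self.exclusion_frac,
            self.unknown_affiliation_prob,
            self.undated_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        for _, p in self.hub_terms:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"hub probability out of [0,1]: {p}")
        if self.n_records < 0:
            raise ValueError("n_records must be non-negative")
        if self.min_terms < 2:
            raise ValueError("min_terms must be at least 2")
        if set(self.block_weights) != set(self.blocks):
            raise ValueError("block_weights keys must match blocks")
        if any(w < 0 for w in self.block_weights.values()) or not sum(
            self.block_weights.values()
        ) > 0:
            raise ValueError("block weights must be non-negative with positive sum")
        if any(w < 0 for w in self.country_weights.values()):
            raise ValueError("country weights must be non-negative")


@dataclass
class RecordTruth:
    """Every draw made for one record."""

    pmid: str
    year: int | None
    country: str  # canonical, "Unknown" when no affiliation country
    block: str
    entities: tuple[tuple[str, bool], ...]  # (descriptor, major_topic)
    has_inclusion: bool
    has_exclusion: bool
    eligible: bool


@dataclass
class GroundTruth:
    """Planted truth for a generated corpus, recomputable per stage."""

    records: list[RecordTruth] = field(default_factory=list)

    def eligibility(self) -> dict[str, bool]:
        return {r.pmid: r.eligible for r in self.records}

    def year_country_tally(
        self, year_range: tuple[int, int], eligible_only: bool = True
    ) -> Counter:
        """(year, country) tallies under the trend-matrix rules."""
        start, end = year_range
        tally: Counter = Counter()
        for r in self.records:
            if eligible_only and not r.eligible:
                continue
            if r.year is None or not (start <= r.year <= end):
                continue
            if r.country == "Unknown":
                continue
            tally[(r.year, r.country)] += 1
        return tally

    def pair_weight_total(self, stoplist: frozenset[str] = frozenset({"humans"})) -> int:
        """Σ_a C(m_a, 2) over eligible records, m_a = retained entities."""
        total = 0
        for r in self.records:
            if not r.eligible:
                continue
            m = sum(1 for d, _ in r.entities if d.casefold() not in stoplist)
            total += m * (m - 1) // 2
        return total

    def pair_tally(
        self, stoplist: frozenset[str] = frozenset({"humans"})
    ) -> Counter:
        """Per-pair co-occurrence counts over eligible records."""
        tally: Counter = Counter()
        for r in self.records:
            if not r.eligible:
                continue
            kept = sorted(e for e in r.entities if e[0].casefold() not in stoplist)
            for a, b in combinations(kept, 2):
                tally[(a, b)] += 1
        return tally

    def term_frequencies(self) -> Counter:
        """How many records carry each descriptor (major flag ignored)."""
        freq: Counter = Counter()
        for r in self.records:
            for d, _ in r.entities:
                freq[d] += 1
        return freq

    def to_csv(self, stream) -> None:
        stream.write("pmid,year,country,block,eligible,entities\n")
        for r in self.records:
            ents = ";".join(("*" if m else "") + d for d, m in r.entities)
            year = "" if r.year is None else r.year
            stream.write(
                f'{r.pmid},{year},{r.country},{r.block},{int(r.eligible)},"{ents}"\n'
            )


def _poisson(rng: random.Random, lam: float) -> int:
    # Knuth's method; lam is small (a handful of terms per record).
    limit = pow(2.718281828459045, -lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= limit:
            return k
        k += 1


def _weighted_choice(rng: random.Random, weights: dict[str, float]) -> str:
    keys = list(weights)
    return rng.choices(keys, weights=[weights[k] for k in keys], k=1)[0]


def _render_mh(rng: random.Random, descriptor: str, major: bool, qualifier_prob: float) -> str:
    if rng.random() < qualifier_prob:
        qualifier = rng.choice(_QUALIFIERS)
        if major and rng.random() < 0.5:
            return f"{descriptor}/*{qualifier}"  # star carried by the qualifier
        return f"{'*' if major else ''}{descriptor}/{qualifier}"
    return f"{'*' if major else ''}{descriptor}"


def generate_corpus(config: GeneratorConfig) -> tuple[str, GroundTruth]:
    """Emit a MEDLINE plain-text corpus and its ground truth.

    Draw order per record (fixed for reproducibility): year, country and
    surface form, thematic block, block term count and sample, hub draws,
    inclusion draw, exclusion draw, per-entity major-topic flags, MH line
    rendering.  Identical configs and seeds yield byte-identical text.
    """
    rng = random.Random(config.seed)
    start, end = config.year_range
    years = list(range(start, end + 1))
    if config.year_weights is None:
        year_weights = [float(i + 1) for i in range(len(years))]  # linear growth
    else:
        if len(config.year_weights) != len(years):
            raise ValueError("year_weights length must match year range")
        year_weights = list(config.year_weights)

    risk_set = {t.casefold() for t in config.blocks.get(config.risk_block, ())}
    demo_set = {t.casefold() for t in config.demographics}
    incl_set = {t.casefold() for t in config.inclusion_terms}
    stop_set = {t.casefold() for t in config.always_terms}

    lines: list[str] = []
    truth = GroundTruth()
    for i in range(config.n_records):
        pmid = str(9000001 + i)
        if rng.random() < config.undated_prob:
            year = None
        else:
            year = rng.choices(years, weights=year_weights, k=1)[0]
        if rng.random() < config.unknown_affiliation_prob:
            country, surface = "Unknown", None
        else:
            country = _weighted_choice(rng, config.country_weights)
            surface = rng.choice(_COUNTRY_SURFACE.get(country, (country,)))
        block = _weighted_choice(rng, config.block_weights)
        pool = list(config.blocks[block])
        n_terms = min(
            config.min_terms + _poisson(rng, config.extra_terms_mean), len(pool)
        )
        descriptors = rng.sample(pool, n_terms)
        for hub, prob in config.hub_terms:
            if rng.random() < prob:
                descriptors.append(hub)
        has_inclusion = rng.random() < config.inclusion_frac
        if has_inclusion:
            descriptors.append(rng.choice(list(config.inclusion_terms)))
        has_exclusion = rng.random() < config.exclusion_frac
        if has_exclusion:
            descriptors.append(rng.choice(list(config.exclusion_terms)))
        descriptors.extend(config.always_terms)

        entities = tuple(
            (d, rng.random() < config.major_topic_prob) for d in descriptors
        )

        # Independent eligibility bookkeeping from the planted draws: the
        # record is risk-factor-only when its substantive remainder is
        # non-empty and lies entirely within the risk-factor vocabulary.
        remainder = {
            d.casefold()
            for d, _ in entities
            if d.casefold() not in demo_set | incl_set | stop_set
        }
        risk_only = bool(remainder) and remainder <= risk_set
        eligible = has_inclusion and not has_exclusion and not risk_only

        truth.records.append(
            RecordTruth(
                pmid=pmid,
                year=year,
                country=country,
                block=block,
                entities=entities,
                has_inclusion=has_inclusion,
                has_exclusion=has_exclusion,
                eligible=eligible,
            )
        )

        if i:
            lines.append("")
        lines.append(f"PMID- {pmid}")
        lines.append(f"TI  - Synthetic study {i + 1}: {block} and cardiovascular outcomes.")
        lines.append(
            "AB  - Synthetic abstract describing associations between "
            f"{block} determinants and cardiovascular disease."
        )
        if year is None:
            lines.append("DP  - n.d.")
        else:
            lines.append(f"DP  - {year} {rng.choice(('Jan', 'Apr', 'Jul', 'Oct'))}")
        for descriptor, major in entities:
            lines.append(
                f"MH  - {_render_mh(rng, descriptor, major, config.qualifier_prob)}"
            )
        city = rng.choice(_CITIES)
        if surface is None:
            lines.append(f"AD  - Department of Public Health, {city} Institute.")
        else:
            lines.append(
                f"AD  - Department of Epidemiology, {city} University, {surface}."
            )

    text = "\n".join(lines) + ("\n" if lines else "")
    return text, truth


def expected_properties(config: GeneratorConfig) -> dict:
    """Closed-form expectations under the generator's draw model.

    Returns expected per-hub record frequencies, expected per-year counts
    (over dated records) and the expected per-record pair count E[C(m,2)]
    over *all* records, where m (the number of distinct non-stop-listed
    entities) is a sum of independent components: the truncated block draw,
    the hub Bernoullis and the inclusion/exclusion Bernoullis.  The block
    count truncation (a block has finitely many terms) is handled by exact
    enumeration of the Poisson tail.
    """
    import math

    start, end = config.year_range
    years = list(range(start, end + 1))
    if config.year_weights is None:
        weights = [float(i + 1) for i in range(len(years))]
    else:
        weights = list(config.year_weights)
    w_sum = sum(weights)
    dated = config.n_records * (1.0 - config.undated_prob)
    expected_year_counts = {
        y: dated * w / w_sum for y, w in zip(years, weights)
    }

    hub_freq = {hub: config.n_records * p for hub, p in config.hub_terms}

    # Block-term count: K = min(min_terms + Poisson(lam), |block pool|),
    # mixed over blocks.  Enumerate the Poisson pmf up to a negligible tail.
    lam = config.extra_terms_mean
    pmf = []
    k, cum = 0, 0.0
    while cum < 1.0 - 1e-12 and k < 400:
        p = math.exp(-lam) * lam**k / math.factorial(k)
        pmf.append(p)
        cum += p
        k += 1
    bw_sum = sum(config.block_weights.values())
    e_k = e_k2 = 0.0
    for block, weight in config.block_weights.items():
        cap = len(config.blocks[block])
        for j, p in enumerate(pmf):
            kk = min(config.min_terms + j, cap)
            e_k += weight / bw_sum * p * kk
            e_k2 += weight / bw_sum * p * kk * kk
    var_k = e_k2 - e_k**2

    mean = e_k + len(config.always_terms)
    var = var_k
    for _, p in config.hub_terms:
        mean += p
        var += p * (1 - p)
    for p in (config.inclusion_frac, config.exclusion_frac):
        mean += p
        var += p * (1 - p)
    e_m2 = var + mean**2
    expected_pairs_per_record = 0.5 * (e_m2 - mean)

    return {
        "expected_hub_frequencies": hub_freq,
        "expected_year_counts": expected_year_counts,
        "expected_terms_per_record": mean,
        "expected_pairs_per_record": expected_pairs_per_record,
        "expected_total_pairs": config.n_records * expected_pairs_per_record,
    }
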
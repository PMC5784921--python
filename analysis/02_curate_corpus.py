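"""Parse, deduplicate and screen the corpus with the default codebook.

Reads results/analysis/corpus.medline, applies the MeSH-level
inclusion/exclusion rules (CVD term required; other-disease and
risk-factor-only records dropped) and writes the curated corpus plus the
per-rule filter audit.
"""

from pathlib import Path

from litmesh.codebook import apply_inclusion_exclusion, load_codebook
from litmesh.gazetteer import load_gazetteer
from litmesh.medline import deduplicate, parse_medline, write_corpus

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main() -> None:
    gazetteer = load_gazetteer()
    codebook = load_codebook(None, gazetteer)
    with open(OUTDIR / "corpus.medline", encoding="utf-8") as fh:
        corpus = parse_medline(fh, gazetteer)
    corpus = deduplicate(corpus)
    filtered, report = apply_inclusion_exclusion(corpus, codebook)

    with open(OUTDIR / "corpus_curated.medline", "w", encoding="utf-8") as fh:
        write_corpus(filtered, fh)
    report.to_frame().to_csv(OUTDIR / "filter_report.csv", index=False)

    print(f"retrieved {report.retrieved} records after deduplication")
    for rule, dropped in report.per_rule.items():
        print(f"  dropped by {rule}: {dropped}")
    print(f"assessed (curated corpus): {report.assessed}")
    print(f"wrote {OUTDIR / 'corpus_curated.medline'} and filter_report.csv")


if __name__ == "__main__":
    main()
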
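"""Publication-trend aggregation: year × country count matrices.

Rows are publication years (ascending, those observed within the configured
window), columns are the canonical countries of the first author affiliation
ordered by descending total output.  Records without a resolvable year or
country, or dated outside the window, are excluded from the matrix but
tallied so the bookkeeping identity

    matrix total + unknown-country + undated + out-of-range = corpus size

always holds.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .medline import Corpus

#: The study window: the literature search spans 1980 through 2016.
DEFAULT_YEAR_RANGE = (1980, 2016)


@dataclass
class TrendMatrix:
    """Year × country publication counts plus exclusion bookkeeping."""

    counts: pd.DataFrame  # index: years ascending; columns: countries
    unknown_country: int = 0
    undated: int = 0
    out_of_range: int = 0

    @property
    def years(self) -> list[int]:
        return list(self.counts.index)

    @property
    def countries(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def year_marginals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def country_marginals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def to_csv(self, path) -> None:
        self.counts.to_csv(path, index_label="year")


def year_country_matrix(
    corpus: Corpus, year_range: tuple[int, int] = DEFAULT_YEAR_RANGE
) -> TrendMatrix:
    """Count records per (year, country) cell within the window.

    Countries are ordered by descending total (alphabetical tie-break),
    years ascending.
    """
    start, end = year_range
    if start > end:
        raise ValueError(f"invalid year range {year_range}")
    cells: Counter[tuple[int, str]] = Counter()
    unknown = undated = out_of_range = 0
    for record in corpus.records:
        if record.year is None:
            undated += 1
        elif not (start <= record.year <= end):
            out_of_range += 1
        elif record.country == "Unknown":
            unknown += 1
        else:
            cells[(record.year, record.country)] += 1

    years = sorted({y for y, _ in cells})
    totals: Counter[str] = Counter()
    for (_, c), n in cells.items():
        totals[c] += n
    countries = sorted(totals, key=lambda c: (-totals[c], c))
    counts = pd.DataFrame(0, index=years, columns=countries, dtype=int)
    for (y, c), n in cells.items():
        counts.loc[y, c] = n
    return TrendMatrix(
        counts=counts,
        unknown_country=unknown,
        undated=undated,
        out_of_range=out_of_range,
    )


def yearly_counts(corpus: Corpus) -> tuple[dict[int, int], int]:
    """Per-year record counts over all dated records; returns (counts, undated).

    Unlike the matrix, records with an unresolved country still count here,
    so each year's value equals the matrix row marginal plus the
    unknown-country records of that year.
    """
    counts: Counter[int] = Counter()
    undated = 0
    for record in corpus.records:
        if record.year is None:
            undated += 1
        else:
            counts[record.year] += 1
    return dict(sorted(counts.items())), undated


@dataclass
class _HeatmapStyle:
    cmap: str = "hot"
    figsize: tuple[float, float] = (10.0, 8.0)


def plot_heatmap(matrix: TrendMatrix, path, style: _HeatmapStyle = _HeatmapStyle()) -> None:
    """Optional convenience rendering; the CSV matrix is the contract."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=style.figsize)
    im = ax.imshow(matrix.counts.to_numpy(), aspect="auto", cmap=style.cmap)
    ax.set_xticks(range(len(matrix.countries)))
    ax.set_xticklabels(matrix.countries, rotation=90, fontsize=6)
    ax.set_yticks(range(len(matrix.years)))
    ax.set_yticklabels(matrix.years, fontsize=6)
    fig.colorbar(im, ax=ax, label="publications")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
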
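"""Country gazetteer: surface forms in affiliation strings → canonical names."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml


def load_gazetteer(path: str | None = None) -> dict[str, str]:
    """Load a gazetteer mapping lower-cased surface forms to canonical names.

    The YAML maps each canonical country name to a list of synonyms; the
    canonical name itself always resolves.
    """
    if path is None:
        return dict(_default_gazetteer())
    with open(path, encoding="utf-8") as fh:
        return _build(yaml.safe_load(fh))


@lru_cache(maxsize=1)
def _default_gazetteer() -> dict[str, str]:
    with resources.files("litmesh.data").joinpath("gazetteer.yaml").open(
        encoding="utf-8"
    ) as fh:
        return _build(yaml.safe_load(fh))


def _build(raw: dict[str, list[str] | None]) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for canonical, synonyms in raw.items():
        mapping[canonical.lower()] = canonical
        for form in synonyms or []:
            mapping[str(form).lower()] = canonical
    return mapping


def country_names(gazetteer: dict[str, str] | None = None) -> set[str]:
    """Canonical country names, e.g. for stop-listing country MeSH terms."""
    gaz = gazetteer if gazetteer is not None else _default_gazetteer()
    return set(gaz.values())
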
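"""Stimulus lexicon: category-tagged identifiers standing in for content.

Drug-related words and pictures are represented by opaque tokens with a
category label; no image assets or word lists are consumed. A synthetic
placeholder lexicon ships with the package (``data/default_lexicon.csv``)
so every task can run out of the box; study deployments supply their own
CSV with the same two columns.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .session_core import ConfigurationError

CATEGORIES = ("meth_word", "neutral_word", "meth_picture", "neutral_picture")


@dataclass(frozen=True)
class Lexicon:
    """Token pools keyed by stimulus category."""

    tokens: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def pool(self, category: str) -> tuple[str, ...]:
        if category not in self.tokens or not self.tokens[category]:
            raise ConfigurationError(f"lexicon has no tokens for category {category!r}")
        return self.tokens[category]

    def sample(self, category: str, rng) -> str:
        pool = self.pool(category)
        return pool[int(rng.integers(len(pool)))]


def _from_rows(rows) -> Lexicon:
    tokens: dict[str, list[str]] = {c: [] for c in CATEGORIES}
    for row in rows:
        token, category = row["token_id"].strip(), row["category"].strip()
        if category not in CATEGORIES:
            raise ConfigurationError(f"unknown lexicon category {category!r}")
        tokens[category].append(token)
    return Lexicon({c: tuple(v) for c, v in tokens.items()})


def load_lexicon(path: str | Path) -> Lexicon:
    """Load a lexicon CSV with columns ``token_id,category``."""
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"token_id", "category"} <= set(reader.fieldnames):
            raise ConfigurationError("lexicon CSV must have columns token_id,category")
        return _from_rows(reader)


def default_lexicon() -> Lexicon:
    """The synthetic placeholder lexicon bundled with the package."""
    ref = resources.files("ccat.data").joinpath("default_lexicon.csv")
    with ref.open(newline="", encoding="utf-8") as fh:
        return _from_rows(csv.DictReader(fh))
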
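"""Category lexicon: LIWC-dic-style parsing, tokenisation and hit counting.

A lexicon is a set of named word categories, each holding lowercase
patterns that are either exact words or prefix wildcards (trailing
``*``), plus an acyclic parent->children hierarchy (e.g. affective
processes ⊃ negative emotions ⊃ anger).  Tokens may hit several
categories at once, and a hit in a child also counts for every ancestor.

The dic dialect has two ``%``-delimited sections: a category id/name map,
then one line per word listing the category ids it belongs to::

    %
    1   posemo
    2   anger
    %
    happy   1
    angr*   2
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CategoryLexicon",
    "parse_lexicon",
    "tokenize",
    "count_hits",
    "toy_lexicon",
    "DEFAULT_HIERARCHY",
]

# Parent -> children links for the category names used by the shipped toy
# lexicon (LIWC-2015-style naming).  Any dic file reusing these names
# inherits the hierarchy; a custom mapping can be passed instead.
DEFAULT_HIERARCHY: dict[str, tuple[str, ...]] = {
    "ppron": ("i", "we", "you", "shehe", "they"),
    "affect": ("posemo", "negemo"),
    "negemo": ("anger", "sad", "anx"),
    "cogproc": ("insight", "cause"),
    "percept": ("see", "hear", "feel"),
    "bio": ("body", "health"),
    "drives": ("achieve", "power"),
    "relativ": ("motion", "space", "time"),
    "pconcern": ("work", "death"),
}

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:'[a-z0-9]+)*")


@dataclass(frozen=True)
class CategoryLexicon:
    """Ordered categories, per-category pattern sets, and a hierarchy."""

    categories: tuple[str, ...]
    patterns: Mapping[str, frozenset[str]]
    hierarchy: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cat in self.categories:
            pats = self.patterns.get(cat, frozenset())
            if any(p == "" or p == "*" for p in pats):
                raise ValueError(f"category {cat!r} has an empty pattern")
        self._check_acyclic()
        # matcher tables: exact word -> categories; prefix list (no '*')
        exact: dict[str, set[str]] = {}
        prefixes: list[tuple[str, str]] = []
        for cat, pats in self.patterns.items():
            for p in pats:
                if p.endswith("*"):
                    prefixes.append((p[:-1], cat))
                else:
                    exact.setdefault(p, set()).add(cat)
        object.__setattr__(self, "_exact", exact)
        object.__setattr__(self, "_prefixes", tuple(prefixes))

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(node: str) -> None:
            if state.get(node) == 1:
                raise ValueError(f"hierarchy cycle through {node!r}")
            if state.get(node) == 2:
                return
            state[node] = 1
            for child in self.hierarchy.get(node, ()):
                visit(child)
            state[node] = 2

        for parent in self.hierarchy:
            visit(parent)

    def ancestors(self, category: str) -> set[str]:
        """All (transitive) parents of *category* within the hierarchy."""
        parents = {
            p for p, children in self.hierarchy.items() if category in children
        }
        out = set(parents)
        for p in parents:
            out |= self.ancestors(p)
        return out

    def match(self, token: str) -> set[str]:
        """Categories whose pattern set matches *token* (no hierarchy)."""
        cats = set(self._exact.get(token, ()))
        for prefix, cat in self._prefixes:
            if token.startswith(prefix):
                cats.add(cat)
        return cats


def parse_lexicon(
    source: str | Path,
    hierarchy: Mapping[str, tuple[str, ...]] | None = None,
) -> CategoryLexicon:
    """Parse a dic-dialect lexicon from a path or literal text.

    Unknown category ids on a word line raise with the line number;
    duplicate word-category pairs collapse.  ``hierarchy`` defaults to
    :data:`DEFAULT_HIERARCHY` restricted to the parsed category names.
    """
    if isinstance(source, Path) or (
        "\n" not in str(source) and Path(source).exists()
    ):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = str(source)
    lines = text.splitlines()
    # locate the two % delimiters
    marks = [i for i, ln in enumerate(lines) if ln.strip() == "%"]
    if len(marks) < 2:
        raise ValueError("dic file must contain two %-delimited sections")
    id_map: dict[str, str] = {}
    order: list[str] = []
    for i in range(marks[0] + 1, marks[1]):
        ln = lines[i].strip()
        if not ln:
            continue
        cid, name = ln.split(None, 1)
        id_map[cid] = name.strip()
        order.append(name.strip())
    patterns: dict[str, set[str]] = {name: set() for name in order}
    for i in range(marks[1] + 1, len(lines)):
        ln = lines[i].strip()
        if not ln:
            continue
        parts = ln.split()
        word, ids = parts[0].lower(), parts[1:]
        for cid in ids:
            if cid not in id_map:
                raise ValueError(
                    f"line {i + 1}: word {word!r} references unknown category id {cid}"
                )
            patterns[id_map[cid]].add(word)
    empty = [c for c, p in patterns.items() if not p]
    hier = dict(hierarchy) if hierarchy is not None else {
        p: tuple(c for c in kids if c in order)
        for p, kids in DEFAULT_HIERARCHY.items()
        if p in order
    }
    # parents may legitimately hold no direct patterns of their own
    for c in empty:
        if c not in hier:
            raise ValueError(f"category {c!r} has no patterns and no children")
    return CategoryLexicon(
        categories=tuple(order),
        patterns={c: frozenset(p) for c, p in patterns.items()},
        hierarchy=hier,
    )


def tokenize(text: str) -> list[str]:
    """Lowercase word tokens: split on non-alphanumeric runs, keeping
    apostrophes inside words ("don't" is one token)."""
    return _TOKEN_RE.findall(text.lower())


def count_hits(tokens: Iterable[str], lexicon: CategoryLexicon) -> dict[str, int]:
    """Per-category hit counts over a token stream.

    Each token increments every matching category and, once per token,
    every ancestor of a matching category (set semantics: a token listed
    under both a child and its parent still counts once for the parent).
    """
    counts = dict.fromkeys(lexicon.categories, 0)
    for tok in tokens:
        cats = lexicon.match(tok)
        if not cats:
            continue
        full = set(cats)
        for c in cats:
            full |= lexicon.ancestors(c)
        for c in full:
            if c in counts:
                counts[c] += 1
    return counts


def toy_lexicon() -> CategoryLexicon:
    """The shipped ~120-word demonstration lexicon (see data/toy.dic)."""
    from importlib.resources import files

    return parse_lexicon(files("trajlens").joinpath("data/toy.dic").read_text())
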
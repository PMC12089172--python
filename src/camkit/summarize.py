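"""Computer-assisted summarization of concept texts.

Participants write free text, so the same idea appears as spelling variants
("dreams"/"dreasm"), synonyms ("war"/"conflict") or semantically close words.
Before quantitative analysis these raw texts are grouped under researcher-named
superordinate categories.  This module generates grouping *suggestions* by
four routes -- optimal string alignment distance, regular-expression search,
synonym-dictionary overlap, and word-vector cosine similarity -- and applies a
finished :class:`SummaryMap` to a CAM set, optionally splitting categories by
valence sign ("Cost_positive" vs "Cost_negative").

The final naming of categories is the researcher's act; nothing here invents
category labels.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import AMBIVALENT, CAM, CAMSet, Concept


def normalize_text(text: str) -> str:
    """Case-fold, trim, and collapse internal whitespace.

    All matching and mapping operate on this normal form, so that
    "Heat pump " and "heat  pump" count as the same unique concept.
    """
    return " ".join(text.split()).casefold()


# ---------------------------------------------------------------------------
# optimal string alignment distance


def osa_distance(s: str, t: str) -> int:
    """Optimal string alignment (restricted Damerau-Levenshtein) distance.

    Minimum number of insertions, deletions, substitutions and adjacent
    transpositions turning ``s`` into ``t``, with the restriction that no
    substring is edited twice.  E.g. ``osa_distance("dreams", "dreasm") == 1``
    (one adjacent transposition).  Symmetric; 0 iff the strings are equal.
    Unlike the unrestricted Damerau-Levenshtein metric, OSA can violate the
    triangle inequality (e.g. the "ca"/"abc" family).
    """
    n, m = len(s), len(t)
    if n == 0 or m == 0:
        return n or m
    prev2: list[int] = []
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cost = 0 if s[i - 1] == t[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if i > 1 and j > 1 and s[i - 1] == t[j - 2] and s[i - 2] == t[j - 1]:
                cur[j] = min(cur[j], prev2[j - 2] + 1)
        prev2, prev = prev, cur
    return prev[m]


# ---------------------------------------------------------------------------
# suggestion groups


@dataclass(frozen=True)
class SuggestionGroup:
    """A set of raw texts suggested for summarization under one category.

    ``source`` names the route that produced it (distance, regex, synonym,
    embedding); ``score`` is the route's own scale (a maximum distance, or a
    minimum pairwise similarity).
    """

    members: tuple[str, ...]
    source: str
    score: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(sorted(self.members)))
        if self.source != "regex" and len(self.members) < 2:
            raise ValueError(f"{self.source} group needs >= 2 members")

    @property
    def representative(self) -> str:
        return self.members[0]


def _components(nodes: Sequence[str], linked) -> list[set[str]]:
    """Connected components by union-find; ``linked(a, b)`` decides edges."""
    parent = {x: x for x in nodes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    items = list(nodes)
    for i, a in enumerate(items):
        for b in items[i + 1 :]:
            if linked(a, b):
                parent[find(a)] = find(b)
    comps: dict[str, set[str]] = {}
    for x in items:
        comps.setdefault(find(x), set()).add(x)
    return list(comps.values())


def _sorted_groups(comps: Iterable[set[str]], source: str, score_of) -> list[SuggestionGroup]:
    groups = [
        SuggestionGroup(members=tuple(c), source=source, score=score_of(c))
        for c in comps
        if len(c) >= 2
    ]
    groups.sort(key=lambda g: (-len(g.members), g.representative))
    return groups


def suggest_by_distance(texts: Iterable[str], max_dist: int = 1) -> list[SuggestionGroup]:
    """Group texts whose pairwise OSA distance is at most ``max_dist``.

    Texts are normalized first; groups are the connected components of the
    "distance <= max_dist" graph (single-linkage closure), sorted by size
    descending then by lexicographic representative.  The group score is the
    largest linked pairwise distance within the group.
    """
    if max_dist < 1:
        raise ValueError("max_dist must be >= 1")
    uniq = sorted({normalize_text(t) for t in texts})
    comps = _components(uniq, lambda a, b: osa_distance(a, b) <= max_dist)

    def score(c: set[str]) -> float:
        ds = [osa_distance(a, b) for a in c for b in c if a < b]
        return float(max(d for d in ds if d <= max_dist))

    return _sorted_groups(comps, "distance", score)


# ---------------------------------------------------------------------------
# regular-expression search

# POSIX character classes -> Python re equivalents.  The analysis-tool
# tradition writes patterns like "[[:digit:]]"; host regex engines do not.
_POSIX_CLASSES = {
    "[:digit:]": r"0-9",
    "[:alpha:]": r"a-zA-Z",
    "[:alnum:]": r"a-zA-Z0-9",
    "[:space:]": r" \t\n\r\f\v",
    "[:upper:]": r"A-Z",
    "[:lower:]": r"a-z",
    "[:punct:]": r"!-/:-@\[-`{-~",
}


def translate_posix(pattern: str) -> str:
    """Rewrite POSIX character classes into the host dialect.

    ``[[:digit:]]`` becomes ``[0-9]``; classes may be combined inside one
    bracket expression (``[[:digit:][:alpha:]]``).
    """
    out = pattern
    for posix, py in _POSIX_CLASSES.items():
        out = out.replace(posix, py)
    return out


class PatternError(ValueError):
    """Invalid regular expression, carrying the error position when known."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message if position is None else f"{message} (at position {position})")
        self.position = position


def search_terms(
    texts: Iterable[str], pattern: str, *, case_sensitive: bool = False
) -> list[str]:
    """All texts containing at least one match of ``pattern``.

    POSIX classes are translated before compilation; matching is
    case-insensitive unless ``case_sensitive`` is set.  Texts are returned in
    sorted order of their normal form.
    """
    try:
        rx = re.compile(translate_posix(pattern), 0 if case_sensitive else re.IGNORECASE)
    except re.error as exc:
        raise PatternError(str(exc), getattr(exc, "pos", None)) from exc
    uniq = sorted({normalize_text(t): t for t in texts}.items())
    return [norm for norm, _ in uniq if rx.search(norm)]


# ---------------------------------------------------------------------------
# synonym dictionary


def load_synonym_dictionary(raw: str | Mapping) -> dict[str, set[str]]:
    """Load a word -> synonyms mapping (JSON text or dict) and symmetrize it."""
    doc = json.loads(raw) if isinstance(raw, str) else raw
    out: dict[str, set[str]] = {}
    for word, syns in doc.items():
        w = normalize_text(word)
        out.setdefault(w, set()).update(normalize_text(s) for s in syns)
    for w, syns in list(out.items()):
        for s in syns:
            out.setdefault(s, set()).add(w)
    return out


def synonym_groups(
    texts: Iterable[str], dictionary: Mapping[str, set[str]]
) -> list[SuggestionGroup]:
    """Group single-word texts whose synonym sets overlap.

    Each word's synonym set implicitly includes the word itself; texts absent
    from the dictionary have empty synonym sets and are never grouped.
    Multi-word texts never participate (synonym lookup is word-level).
    """
    uniq = sorted({normalize_text(t) for t in texts})
    single = [t for t in uniq if len(t.split()) == 1]
    syn = {t: set(dictionary.get(t, set())) | {t} for t in single}
    comps = _components(single, lambda a, b: bool(syn[a] & syn[b]))
    return _sorted_groups(comps, "synonym", lambda c: float(len(c)))


# ---------------------------------------------------------------------------
# embedding similarity


def cosine_similarity(u, v) -> float:
    """Cosine of the angle between two vectors: dot(u, v)/(|u||v|), in [-1, 1].

    -1 means opposite vectors, +1 proportional vectors.  Raises on a zero
    vector, where the similarity is undefined.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def load_vector_table(path_or_df) -> dict[str, np.ndarray]:
    """Read a vector table CSV (columns: text, v1..vd) into a provider dict."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    cols = [c for c in df.columns if c != "text"]
    return {
        normalize_text(str(r["text"])): np.asarray([r[c] for c in cols], dtype=float)
        for _, r in df.iterrows()
    }


def embedding_suggestions(
    texts: Iterable[str],
    vectors: Mapping[str, Sequence[float]],
    threshold: float,
) -> tuple[list[SuggestionGroup], list[str]]:
    """Group texts whose word-vector cosine similarity reaches ``threshold``.

    Returns ``(groups, missing)`` where ``missing`` lists texts with no vector
    (skipped, reported rather than silently dropped).  Each group's score is
    its minimum pairwise similarity.
    """
    if not (-1.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (-1, 1]")
    uniq = sorted({normalize_text(t) for t in texts})
    have = [t for t in uniq if t in vectors]
    missing = [t for t in uniq if t not in vectors]
    sims = {
        (a, b): cosine_similarity(vectors[a], vectors[b])
        for i, a in enumerate(have)
        for b in have[i + 1 :]
    }
    comps = _components(have, lambda a, b: sims[(min(a, b), max(a, b))] >= threshold)

    def score(c: set[str]) -> float:
        return min(sims[(a, b)] for a in c for b in c if a < b)

    return _sorted_groups(comps, "embedding", score), missing


def suggestions_table(groups: Sequence[SuggestionGroup]) -> pd.DataFrame:
    """Long-format suggestion report (group_id, member, source, score)."""
    rows = [
        {"group_id": gid, "member": m, "source": g.source, "score": g.score}
        for gid, g in enumerate(groups)
        for m in g.members
    ]
    return pd.DataFrame(rows, columns=["group_id", "member", "source", "score"])


# ---------------------------------------------------------------------------
# summary map application


@dataclass(frozen=True)
class SummaryMap:
    """Mapping from raw concept text (normal form) to superordinate category.

    With ``split_by_valence`` the category label is suffixed by the concept's
    valence class on application, so that e.g. positive and negative "Cost"
    concepts stay distinguishable.
    """

    entries: Mapping[str, str] = field(default_factory=dict)
    split_by_valence: bool = False

    def __post_init__(self) -> None:
        norm = {}
        for raw, cat in self.entries.items():
            if not str(cat).strip():
                raise ValueError(f"empty category label for {raw!r}")
            norm[normalize_text(raw)] = str(cat)
        object.__setattr__(self, "entries", dict(sorted(norm.items())))

    def category_for(self, text: str) -> str | None:
        return self.entries.get(normalize_text(text))

    @classmethod
    def from_csv(cls, path, split_by_valence: bool = False) -> "SummaryMap":
        df = pd.read_csv(path)
        return cls(
            entries=dict(zip(df["raw_text"].astype(str), df["category"].astype(str))),
            split_by_valence=split_by_valence,
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            [{"raw_text": k, "category": v} for k, v in self.entries.items()]
        ).to_csv(path, index=False)


def valence_class(valence: int | str) -> str:
    if valence == AMBIVALENT:
        return "ambivalent"
    return "positive" if valence > 0 else "negative" if valence < 0 else "neutral"


def summarized_text(concept: Concept, smap: SummaryMap) -> str:
    """The label a concept carries after applying ``smap`` (without mutating)."""
    cat = smap.category_for(concept.text)
    if cat is None:
        return concept.text
    if smap.split_by_valence:
        return f"{cat}_{valence_class(concept.valence)}"
    return cat


def apply_summary(cams: CAMSet, smap: SummaryMap) -> CAMSet:
    """Replace mapped concept texts by their category labels across a CAM set.

    Pure: returns a new CAMSet.  The original text is preserved in each
    concept's ``raw_text`` field (kept from the first application, so applying
    a map twice is a no-op on already-mapped concepts).  Valences, connectors
    and graph structure are never touched.
    """
    new_cams = []
    for cam in cams:
        new_concepts = []
        for c in cam.concepts:
            lookup = c.raw_text if c.raw_text is not None else c.text
            cat = smap.category_for(lookup)
            if cat is None:
                new_concepts.append(c)
            else:
                label = (
                    f"{cat}_{valence_class(c.valence)}" if smap.split_by_valence else cat
                )
                new_concepts.append(replace(c, text=label, raw_text=lookup))
        new_cams.append(cam.with_concepts(new_concepts))
    return CAMSet(cams=new_cams, provenance=list(cams.provenance))


def unsummarized_overview(cams: CAMSet, smap: SummaryMap) -> pd.DataFrame:
    """Unique concept texts not yet covered by the map, with frequencies.

    Sorted by frequency descending, then lexicographically -- the worklist of
    what remains to be categorized.
    """
    counts: dict[str, int] = {}
    for _, c in cams.all_concepts():
        lookup = c.raw_text if c.raw_text is not None else c.text
        norm = normalize_text(lookup)
        if smap.category_for(norm) is None:
            counts[norm] = counts.get(norm, 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["raw_text", "frequency"])
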
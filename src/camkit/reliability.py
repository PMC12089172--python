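"""Inter-rater reliability for the summarization step.

Several raters independently sort the same sampled concepts into
superordinate categories, each using their *own* category names.  What should
be reliable is the partition -- whether raters group the same concepts
together -- not the invented labels.  Category labels are therefore aligned
onto a shared index space before any coefficient is computed, in two variants:

``exact_overlap``
    greedy one-to-one matching of categories in descending order of overlap
    count (ties broken lexicographically on the label pair);
``max_overlap``
    the one-to-one assignment maximizing total overlapping items, solved
    exactly as a linear assignment problem.

On aligned codings, pairwise Cohen's kappa, and Fleiss' kappa with its
category-wise decomposition, are computed from first principles.  Note that
overlap-based alignment is positively biased under the null (it picks the
luckiest matching), so null-model calibration should use a shared label space
directly -- see :func:`cohen_kappa_from_labels` and docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .model import CAMSet
from .summarize import normalize_text


@dataclass(frozen=True)
class RaterCoding:
    """One rater's assignment of concepts to their own category vocabulary."""

    rater_id: str
    assignments: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "assignments",
            {normalize_text(k): str(v) for k, v in self.assignments.items()},
        )

    @property
    def items(self) -> frozenset[str]:
        return frozenset(self.assignments)

    @classmethod
    def from_csv(cls, path, rater_id: str | None = None) -> "RaterCoding":
        df = pd.read_csv(path)
        rid = rater_id if rater_id is not None else str(path)
        return cls(rid, dict(zip(df["concept"].astype(str), df["category"].astype(str))))


@dataclass(frozen=True)
class AlignedCoding:
    """Raters' codings mapped onto a shared category index space.

    ``codes[r][i]`` is rater ``r``'s category index for item ``i`` of
    ``items``.  Indices are comparable across raters after alignment.
    """

    items: tuple[str, ...]
    rater_ids: tuple[str, ...]
    codes: tuple[tuple[int, ...], ...]
    alignment_mode: str
    n_categories: int = field(default=0)

    def __post_init__(self) -> None:
        if self.n_categories == 0:
            object.__setattr__(
                self, "n_categories", 1 + max(max(row) for row in self.codes)
            )

    def pair(self, a: str | int, b: str | int) -> tuple[tuple[int, ...], tuple[int, ...]]:
        ia = a if isinstance(a, int) else self.rater_ids.index(a)
        ib = b if isinstance(b, int) else self.rater_ids.index(b)
        return self.codes[ia], self.codes[ib]


def sample_training_concepts(
    cams: CAMSet, proportion: float, seed: int
) -> list[str]:
    """Random training sample of unique concept texts for rater calibration.

    Draws ``ceil(proportion * n_unique)`` texts without replacement,
    reproducibly from ``seed``.  A typical choice is 10% of all unique drawn
    concepts.
    """
    if not 0 < proportion <= 1:
        raise ValueError("proportion must be in (0, 1]")
    uniq = sorted({normalize_text(c.text) for _, c in cams.all_concepts()})
    if not uniq:
        raise ValueError("empty CAM set: no concepts to sample")
    k = math.ceil(proportion * len(uniq))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(uniq), size=k, replace=False)
    return [uniq[i] for i in sorted(idx)]


# ---------------------------------------------------------------------------
# category alignment


def _category_order(coding: RaterCoding, items: Sequence[str]) -> list[str]:
    """Categories ordered by their member-item fingerprint.

    A category *is* the set of items it contains; ordering on that set (not
    on the rater's invented name) keeps every downstream tie-break invariant
    under category renaming, which is the whole point of partition-based
    reliability.
    """
    members: dict[str, list[str]] = {}
    for it in items:
        members.setdefault(coding.assignments[it], []).append(it)
    return sorted(members, key=lambda c: sorted(members[c]))


def _overlap_matrix(
    ref: RaterCoding, other: RaterCoding, items: Sequence[str]
) -> tuple[list[str], list[str], np.ndarray]:
    ref_cats = _category_order(ref, items)
    oth_cats = _category_order(other, items)
    mat = np.zeros((len(ref_cats), len(oth_cats)), dtype=int)
    ri = {c: k for k, c in enumerate(ref_cats)}
    oi = {c: k for k, c in enumerate(oth_cats)}
    for it in items:
        mat[ri[ref.assignments[it]], oi[other.assignments[it]]] += 1
    return ref_cats, oth_cats, mat


def _match_categories(
    ref: RaterCoding, other: RaterCoding, items: Sequence[str], mode: str
) -> dict[str, str]:
    """One-to-one map other-category -> ref-category (unmatched keep None)."""
    ref_cats, oth_cats, mat = _overlap_matrix(ref, other, items)
    mapping: dict[str, str] = {}
    if mode == "exact_overlap":
        # greedy in descending overlap; ties broken by the fingerprint order
        # of the category pair (positions in ref_cats/oth_cats), so the
        # result does not depend on the raters' invented names
        cells = [
            (int(mat[i, j]), i, j)
            for i in range(len(ref_cats))
            for j in range(len(oth_cats))
            if mat[i, j] > 0
        ]
        cells.sort(key=lambda t: (-t[0], t[1], t[2]))
        used_ref: set[int] = set()
        for _, i, j in cells:
            if oth_cats[j] in mapping or i in used_ref:
                continue
            mapping[oth_cats[j]] = ref_cats[i]
            used_ref.add(i)
    elif mode == "max_overlap":
        rows, cols = linear_sum_assignment(-mat)
        for i, j in zip(rows, cols):
            if mat[i, j] > 0:
                mapping[oth_cats[j]] = ref_cats[i]
    else:
        raise ValueError(f"unknown alignment mode {mode!r}")
    return mapping


def align_categories(
    codings: Sequence[RaterCoding], mode: str = "max_overlap"
) -> AlignedCoding:
    """Align raters' category vocabularies onto a shared index space.

    The rater with the most categories anchors the shared space (ties broken
    by rater id); every other rater's categories are matched one-to-one onto
    it by the chosen overlap rule, and categories left unmatched get fresh
    indices.  ``mode="identity"`` skips matching and indexes the raw labels
    as-is, for codings already expressed in one vocabulary.

    Raises on fewer than two raters or item-set mismatch (the symmetric
    difference is listed).
    """
    if len(codings) < 2:
        raise ValueError("need at least 2 raters")
    items0 = codings[0].items
    for c in codings[1:]:
        if c.items != items0:
            diff = sorted(items0 ^ c.items)
            raise ValueError(
                f"item sets differ between raters {codings[0].rater_id!r} and "
                f"{c.rater_id!r}: {diff}"
            )
    items = tuple(sorted(items0))

    index: dict[str, int] = {}

    def idx(label: str) -> int:
        if label not in index:
            index[label] = len(index)
        return index[label]

    if mode == "identity":
        codes = tuple(
            tuple(idx(c.assignments[it]) for it in items) for c in codings
        )
        return AlignedCoding(items, tuple(c.rater_id for c in codings), codes, mode)

    order = sorted(
        range(len(codings)),
        key=lambda i: (-len(set(codings[i].assignments.values())), codings[i].rater_id),
    )
    ref = codings[order[0]]
    rows: dict[int, tuple[int, ...]] = {
        order[0]: tuple(idx(ref.assignments[it]) for it in items)
    }
    for i in order[1:]:
        other = codings[i]
        mapping = _match_categories(ref, other, items, mode)
        row = []
        for it in items:
            oc = other.assignments[it]
            label = mapping.get(oc, f"\x00{other.rater_id}\x00{oc}")  # fresh
            row.append(idx(label))
        rows[i] = tuple(row)
    codes = tuple(rows[i] for i in range(len(codings)))
    return AlignedCoding(items, tuple(c.rater_id for c in codings), codes, mode)


def total_overlap(aligned: AlignedCoding) -> int:
    """Total pairwise agreements after alignment (the matching objective)."""
    n = len(aligned.rater_ids)
    return sum(
        int(x == y)
        for a in range(n)
        for b in range(a + 1, n)
        for x, y in zip(aligned.codes[a], aligned.codes[b])
    )


# ---------------------------------------------------------------------------
# kappa coefficients


def cohen_kappa_from_labels(r1: Sequence, r2: Sequence) -> float:
    """Cohen's kappa for two raters in a shared label space.

    kappa = (p_o - p_e)/(1 - p_e) with p_o the observed agreement proportion
    and p_e the chance agreement from the two raters' marginals.  In the
    degenerate case p_e = 1 (a single shared category), returns 1 for perfect
    agreement and 0 otherwise, avoiding 0/0.
    """
    if len(r1) != len(r2):
        raise ValueError("label sequences differ in length")
    n = len(r1)
    if n < 2:
        raise ValueError("need at least 2 items")
    p_o = sum(a == b for a, b in zip(r1, r2)) / n
    cats = set(r1) | set(r2)
    p_e = sum(
        (sum(a == c for a in r1) / n) * (sum(b == c for b in r2) / n) for c in cats
    )
    if p_e >= 1.0 - 1e-15:
        return 1.0 if p_o >= 1.0 - 1e-15 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def cohen_kappa(aligned: AlignedCoding, rater_pair: tuple[str | int, str | int]) -> float:
    """Pairwise Cohen's kappa on an aligned coding."""
    r1, r2 = aligned.pair(*rater_pair)
    return cohen_kappa_from_labels(r1, r2)


def _rating_counts(aligned: AlignedCoding) -> np.ndarray:
    """Item x category matrix of rater counts (n_ij)."""
    n_items = len(aligned.items)
    counts = np.zeros((n_items, aligned.n_categories), dtype=int)
    for row in aligned.codes:
        for i, c in enumerate(row):
            counts[i, c] += 1
    return counts


def fleiss_kappa(aligned: AlignedCoding) -> tuple[float, dict[int, float]]:
    """Fleiss' kappa plus the category-wise kappa decomposition.

    With N items, n raters and n_ij raters assigning item i to category j:

        P_i   = (sum_j n_ij^2 - n) / (n (n - 1))
        P-bar = mean_i P_i
        p_j   = sum_i n_ij / (N n)
        P-bar_e = sum_j p_j^2
        kappa = (P-bar - P-bar_e) / (1 - P-bar_e)

    Category-wise: kappa_j = 1 - [sum_i n_ij (n - n_ij)] /
    [N n (n-1) p_j (1 - p_j)], reported only for categories actually used
    with 0 < p_j < 1.  Returns ``(overall, {category_index: kappa_j})``.
    """
    counts = _rating_counts(aligned)
    N, _ = counts.shape
    n = len(aligned.rater_ids)
    if n < 2:
        raise ValueError("need at least 2 raters")
    if not np.all(counts.sum(axis=1) == n):
        raise ValueError("every rater must code every item")
    p_j = counts.sum(axis=0) / (N * n)
    P_i = (np.square(counts).sum(axis=1) - n) / (n * (n - 1))
    P_bar = float(P_i.mean())
    P_e = float(np.square(p_j).sum())
    if P_e >= 1.0 - 1e-15:
        overall = 1.0 if P_bar >= 1.0 - 1e-15 else 0.0
    else:
        overall = (P_bar - P_e) / (1.0 - P_e)
    per_cat: dict[int, float] = {}
    for j in range(counts.shape[1]):
        pj = float(p_j[j])
        if pj <= 0.0 or pj >= 1.0:
            continue
        num = float((counts[:, j] * (n - counts[:, j])).sum())
        per_cat[j] = 1.0 - num / (N * n * (n - 1) * pj * (1.0 - pj))
    return overall, per_cat


def fleiss_kappa_from_counts(counts: np.ndarray) -> float:
    """Fleiss' kappa directly from an item x category count table."""
    counts = np.asarray(counts, dtype=float)
    N = counts.shape[0]
    n = int(counts.sum(axis=1)[0])
    p_j = counts.sum(axis=0) / (N * n)
    P_bar = float(((np.square(counts).sum(axis=1) - n) / (n * (n - 1))).mean())
    P_e = float(np.square(p_j).sum())
    if P_e >= 1.0 - 1e-15:
        return 1.0 if P_bar >= 1.0 - 1e-15 else 0.0
    return (P_bar - P_e) / (1.0 - P_e)


# ---------------------------------------------------------------------------
# report


def reliability_report(codings: Sequence[RaterCoding]) -> pd.DataFrame:
    """Full reliability table for a set of rater codings.

    Rows: every rater pair under both alignment variants (Cohen's kappa), the
    overall Fleiss' kappa, and one category-wise kappa per shared category --
    C(R,2) x 2 + 1 + #categories rows.  A per-category member summary for
    rater training is available via :func:`category_members`.
    """
    rows: list[dict] = []
    n = len(codings)
    for mode in ("exact_overlap", "max_overlap"):
        aligned = align_categories(codings, mode=mode)
        for a in range(n):
            for b in range(a + 1, n):
                rows.append(
                    {
                        "coefficient": "cohen_kappa",
                        "alignment": mode,
                        "rater_a": codings[a].rater_id,
                        "rater_b": codings[b].rater_id,
                        "category": "",
                        "value": cohen_kappa(aligned, (a, b)),
                    }
                )
    aligned = align_categories(codings, mode="max_overlap")
    overall, per_cat = fleiss_kappa(aligned)
    rows.append(
        {
            "coefficient": "fleiss_kappa",
            "alignment": "max_overlap",
            "rater_a": "",
            "rater_b": "",
            "category": "",
            "value": overall,
        }
    )
    for j, kj in sorted(per_cat.items()):
        rows.append(
            {
                "coefficient": "category_kappa",
                "alignment": "max_overlap",
                "rater_a": "",
                "rater_b": "",
                "category": str(j),
                "value": kj,
            }
        )
    return pd.DataFrame(
        rows, columns=["coefficient", "alignment", "rater_a", "rater_b", "category", "value"]
    )


def category_members(coding: RaterCoding) -> pd.DataFrame:
    """Per-category member lists for one rater (training material)."""
    rows = []
    by_cat: dict[str, list[str]] = {}
    for item, cat in sorted(coding.assignments.items()):
        by_cat.setdefault(cat, []).append(item)
    for cat, members in sorted(by_cat.items()):
        rows.append(
            {
                "rater_id": coding.rater_id,
                "category": cat,
                "n_members": len(members),
                "members": "; ".join(members),
            }
        )
    return pd.DataFrame(rows, columns=["rater_id", "category", "n_members", "members"])
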
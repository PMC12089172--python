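"""Concept co-occurrence across CAMs and valence-profile clustering.

Whether two (summarized) concepts are drawn together disproportionately often
is measured per concept pair with a 2x2 contingency table of per-CAM presence
and the phi coefficient

    phi = (ad - bc) / sqrt[(a+b)(c+d)(a+c)(b+d)],

where a = CAMs containing both, b/c = one only, d = neither.  Presence is
binary per CAM (a participant counts once however many instances they drew).
Significance comes from the 1-df Pearson chi-square, chi2 = N * phi^2;
Fisher's exact test is reported alongside whenever an expected cell is small.

Separately, CAMs are clustered on their valence profiles: the CAM x concept
matrix of per-CAM mean valences is z-transformed column-wise and clustered
hierarchically with Euclidean distance and Ward's method, to find groups of
participants who rate the same concepts differently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .model import CAMSet
from .indicators import numeric_valence
from .summarize import normalize_text


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 per-CAM presence table for a concept pair."""

    a: int  # both present
    b: int  # first only
    c: int  # second only
    d: int  # neither
    label_a: str = ""
    label_b: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def presence_sets(cams: CAMSet) -> dict[str, set[str]]:
    """Per-label sets of CAM ids containing the label (binary presence)."""
    out: dict[str, set[str]] = {}
    for cam in cams:
        for c in cam.concepts:
            out.setdefault(normalize_text(c.text), set()).add(cam.cam_id)
    return out


def build_contingency(cams: CAMSet, concept_a: str, concept_b: str) -> ContingencyTable:
    """Presence contingency table for two summarized concept labels."""
    pres = presence_sets(cams)
    la, lb = normalize_text(concept_a), normalize_text(concept_b)
    for lab in (la, lb):
        if lab not in pres:
            raise KeyError(f"concept {lab!r} not drawn in any CAM")
    sa, sb = pres[la], pres[lb]
    n = len(cams)
    a = len(sa & sb)
    b = len(sa - sb)
    c = len(sb - sa)
    return ContingencyTable(a=a, b=b, c=c, d=n - a - b - c, label_a=la, label_b=lb)


@dataclass(frozen=True)
class PhiResult:
    phi: float
    chi2: float
    p: float
    small_cells: bool
    fisher_p: float | None = None


def phi(t: ContingencyTable) -> PhiResult:
    """Phi coefficient with its chi-square p-value.

    Requires all four marginals positive (otherwise phi is undefined).
    chi2 = N * phi^2 with 1 df, no continuity correction, so the identity
    phi = sign(ad - bc) * sqrt(chi2 / N) holds exactly.  When any expected
    cell is below 5 the result is flagged and Fisher's exact p is attached.
    """
    m1, m2, m3, m4 = t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d
    if min(m1, m2, m3, m4) == 0:
        raise ValueError(
            f"phi undefined: zero marginal in table ({t.a}, {t.b}, {t.c}, {t.d})"
        )
    num = t.a * t.d - t.b * t.c
    val = num / math.sqrt(m1 * m2 * m3 * m4)
    chi2 = t.n * val * val
    p = float(stats.chi2.sf(chi2, df=1))
    expected = np.outer([m1, m2], [m3, m4]) / t.n
    small = bool((expected < 5).any())
    fisher_p = None
    if small:
        _, fisher_p = stats.fisher_exact(t.as_array())
        fisher_p = float(fisher_p)
    return PhiResult(phi=float(val), chi2=float(chi2), p=p, small_cells=small, fisher_p=fisher_p)


def cooccurrence_matrix(cams: CAMSet, min_n: int = 1) -> pd.DataFrame:
    """All pairwise phi coefficients in long format.

    Concepts drawn in fewer than ``min_n`` CAMs are excluded.  Columns:
    concept_a, concept_b, a, b, c, d, phi, p, p_adj (Benjamini-Hochberg over
    the defined pairs; opt-in reading -- raw p is the primary column),
    small_cells, fisher_p.  Pairs with a zero marginal carry NaN phi.
    Symmetric by construction; each unordered pair appears once.
    """
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    pres = presence_sets(cams)
    labels = sorted(lab for lab, s in pres.items() if len(s) >= min_n)
    n = len(cams)
    rows = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            sa, sb = pres[la], pres[lb]
            a = len(sa & sb)
            b = len(sa - sb)
            c = len(sb - sa)
            t = ContingencyTable(a, b, c, n - a - b - c, la, lb)
            try:
                r = phi(t)
                rows.append(
                    {
                        "concept_a": la, "concept_b": lb,
                        "a": a, "b": b, "c": c, "d": t.d,
                        "phi": r.phi, "p": r.p,
                        "small_cells": r.small_cells, "fisher_p": r.fisher_p,
                    }
                )
            except ValueError:
                rows.append(
                    {
                        "concept_a": la, "concept_b": lb,
                        "a": a, "b": b, "c": c, "d": t.d,
                        "phi": float("nan"), "p": float("nan"),
                        "small_cells": True, "fisher_p": None,
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=["concept_a", "concept_b", "a", "b", "c", "d", "phi", "p",
                 "small_cells", "fisher_p"],
    )
    # Benjamini-Hochberg over defined p-values (documented as opt-in)
    df["p_adj"] = float("nan")
    defined = df["p"].notna()
    if defined.any():
        pvals = df.loc[defined, "p"].to_numpy()
        order = np.argsort(pvals)
        m = len(pvals)
        adj = np.empty(m)
        prev = 1.0
        for rank in range(m - 1, -1, -1):
            idx = order[rank]
            prev = min(prev, pvals[idx] * m / (rank + 1))
            adj[idx] = prev
        df.loc[defined, "p_adj"] = adj
    return df


def phi_matrix(long: pd.DataFrame) -> pd.DataFrame:
    """Square symmetric phi matrix (unit diagonal) from the long format."""
    labels = sorted(set(long["concept_a"]) | set(long["concept_b"]))
    mat = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for r in long.itertuples():
        mat.loc[r.concept_a, r.concept_b] = r.phi
        mat.loc[r.concept_b, r.concept_a] = r.phi
    return mat


# ---------------------------------------------------------------------------
# valence-profile clustering


@dataclass
class ValenceClustering:
    """Result of hierarchical clustering of CAMs on valence profiles."""

    features: pd.DataFrame          # CAM x concept z-scores (imputed)
    imputed: pd.DataFrame           # boolean mask of grand-mean-imputed cells
    linkage_matrix: np.ndarray      # scipy linkage (Ward)
    labels: pd.Series | None = None # flat k-cut labels, if requested
    profile: pd.DataFrame | None = None  # mean z per concept per cluster
    transpose: bool = field(default=False)


def valence_clusters(
    cams: CAMSet,
    k: int | None = None,
    min_count: int = 2,
    transpose: bool = False,
) -> ValenceClustering:
    """Ward clustering of CAMs over z-scored concept mean valences.

    Eligible concepts are those drawn at least ``min_count`` times in total.
    The feature matrix holds each CAM's mean valence per eligible concept
    (mean over that CAM's instances); columns are z-transformed, and cells
    for concepts absent from a CAM are imputed at the grand mean (0 after the
    z-transform) and flagged.  With ``transpose`` the concepts, not the CAMs,
    are the clustered objects.  The cluster ``profile`` (average z-score per
    concept within each flat cluster) supports interpretation of a k-cut.
    """
    if len(cams) < 2:
        raise ValueError("need at least 2 CAMs")
    totals: dict[str, int] = {}
    for _, c in cams.all_concepts():
        t = normalize_text(c.text)
        totals[t] = totals.get(t, 0) + 1
    eligible = sorted(t for t, n in totals.items() if n >= min_count)
    if len(eligible) < 2:
        raise ValueError(
            f"need >= 2 concepts drawn at least {min_count} times; got {len(eligible)}"
        )
    raw = pd.DataFrame(index=cams.cam_ids, columns=eligible, dtype=float)
    for cam in cams:
        by_text: dict[str, list[float]] = {}
        for c in cam.concepts:
            t = normalize_text(c.text)
            if t in totals and totals[t] >= min_count:
                by_text.setdefault(t, []).append(numeric_valence(c))
        for t, vals in by_text.items():
            raw.loc[cam.cam_id, t] = float(np.mean(vals))
    # column-wise z-transform on observed cells, then grand-mean imputation
    z = raw.copy()
    for col in z.columns:
        obs = z[col].dropna()
        sd = obs.std(ddof=1)
        if len(obs) < 2 or sd == 0 or np.isnan(sd):
            z[col] = (z[col] - obs.mean()) if len(obs) else z[col]
            z[col] = z[col].fillna(0.0) * 0.0
        else:
            z[col] = (z[col] - obs.mean()) / sd
    imputed = raw.isna()
    z = z.fillna(0.0)
    mat = z.T if transpose else z
    lm = linkage(mat.to_numpy(), method="ward", metric="euclidean")
    result = ValenceClustering(
        features=z, imputed=imputed, linkage_matrix=lm, transpose=transpose
    )
    if k is not None:
        flat = fcluster(lm, t=k, criterion="maxclust")
        result.labels = pd.Series(flat, index=mat.index, name="cluster")
        if not transpose:
            prof = z.groupby(result.labels).mean()
            prof.index.name = "cluster"
            result.profile = prof
    return result


def dendrogram_newick(lm: np.ndarray, leaf_names: list[str]) -> str:
    """Nested-parenthesis (Newick-style) text export of a linkage tree."""
    n = len(leaf_names)
    nodes: dict[int, str] = {i: leaf_names[i] for i in range(n)}
    for i, (a, b, height, _) in enumerate(lm):
        nodes[n + i] = f"({nodes[int(a)]},{nodes[int(b)]}):{height:.6g}"
    return nodes[n + len(lm) - 1] + ";"
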
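"""Network indicators on macro, micro, and mezzo levels, plus the six
neighborhood-valence variants.

All distance and degree computations run on the undirected simple-graph
projection of a CAM; the directed structure is kept in the data model but
in-/out-degree are not distinguished.  Ambivalent concepts enter mean-valence
computations as 0 by default (``as_zero`` policy) or can be excluded; in
class-share percentages they always count as their own class.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .model import AMBIVALENT, CAM, CAMSet, Concept

#: Marker returned for values with no defined answer on this CAM (e.g. the
#: density of a single-node graph, or the mean over an empty neighborhood).
UNDEFINED = float("nan")


@dataclass(frozen=True)
class IndicatorRow:
    cam_id: str
    indicator: str
    level: str  # macro | micro | mezzo
    focus: str  # concept id, community id, or "" for macro
    value: float


class _Excluded:
    def __repr__(self) -> str:  # pragma: no cover
        return "EXCLUDED"


EXCLUDED = _Excluded()


def numeric_valence(c: Concept, ambivalent_policy: str = "as_zero"):
    """Numeric reading of a concept's valence.

    Integer valences pass through; the ambivalent state maps to 0 under
    ``as_zero`` or to the :data:`EXCLUDED` marker under ``exclude``.
    """
    if c.valence != AMBIVALENT:
        return float(c.valence)
    if ambivalent_policy == "as_zero":
        return 0.0
    if ambivalent_policy == "exclude":
        return EXCLUDED
    raise ValueError(f"unknown ambivalent policy {ambivalent_policy!r}")


def _mean_valence(concepts: Iterable[Concept], policy: str = "as_zero") -> float:
    vals = [numeric_valence(c, policy) for c in concepts]
    vals = [v for v in vals if v is not EXCLUDED]
    return float(np.mean(vals)) if vals else UNDEFINED


def central_concept(cam: CAM, explicit_id: str | None = None) -> Concept:
    """The designated central concept: explicit id > predefined flag >
    maximum degree, with lexicographic id tie-breaking throughout."""
    if explicit_id is not None:
        return cam.concept(explicit_id)
    predefined = sorted((c for c in cam.concepts if c.predefined), key=lambda c: c.id)
    g = cam.graph()
    if predefined:
        return max(predefined, key=lambda c: (g.degree(c.id), ), default=predefined[0]) \
            if len(predefined) > 1 else predefined[0]
    return max(sorted(cam.concepts, key=lambda c: c.id), key=lambda c: g.degree(c.id))


def macro_indicators(cam: CAM, central_id: str | None = None) -> list[IndicatorRow]:
    """Whole-CAM indicators.

    mean_valence, central_node_valence, density (on the undirected simple
    projection), diameter (longest shortest path on the largest connected
    component), num_nodes, num_links, and the valence-class shares
    pct_positive / pct_negative / pct_neutral / pct_ambivalent.  Density is
    undefined-flagged for a single-node CAM; an empty CAM is an error.
    """
    if cam.n_concepts == 0:
        raise ValueError(f"CAM {cam.cam_id!r} has no concepts")
    g = cam.graph()
    n, m = g.number_of_nodes(), g.number_of_edges()
    density = UNDEFINED if n < 2 else m / (n * (n - 1) / 2)
    if n == 1:
        diameter = 0.0
    else:
        giant = g.subgraph(max(nx.connected_components(g), key=lambda s: (len(s), sorted(s))))
        diameter = float(nx.diameter(giant)) if giant.number_of_nodes() > 1 else 0.0
    classes = {"positive": 0, "negative": 0, "neutral": 0, "ambivalent": 0}
    for c in cam.concepts:
        if c.valence == AMBIVALENT:
            classes["ambivalent"] += 1
        elif c.valence > 0:
            classes["positive"] += 1
        elif c.valence < 0:
            classes["negative"] += 1
        else:
            classes["neutral"] += 1
    central = central_concept(cam, central_id)
    values = {
        "mean_valence": _mean_valence(cam.concepts),
        "central_node_valence": numeric_valence(central),
        "density": density,
        "diameter": diameter,
        "num_nodes": float(n),
        "num_links": float(m),
        "pct_positive": classes["positive"] / n,
        "pct_negative": classes["negative"] / n,
        "pct_neutral": classes["neutral"] / n,
        "pct_ambivalent": classes["ambivalent"] / n,
    }
    return [IndicatorRow(cam.cam_id, k, "macro", "", v) for k, v in values.items()]


def micro_indicators(cam: CAM, focus: Sequence[str]) -> list[IndicatorRow]:
    """Per-concept indicators: degree, betweenness centrality, closeness
    centrality (within the concept's component), and own valence."""
    g = cam.graph()
    for cid in focus:
        if cid not in g:
            raise KeyError(f"concept {cid!r} not in CAM {cam.cam_id!r}")
    betweenness = nx.betweenness_centrality(g, normalized=False)
    rows = []
    for cid in focus:
        comp = nx.node_connected_component(g, cid)
        closeness = nx.closeness_centrality(g.subgraph(comp), u=cid)
        for name, value in (
            ("degree", float(g.degree(cid))),
            ("betweenness", float(betweenness[cid])),
            ("closeness", float(closeness)),
            ("valence", numeric_valence(cam.concept(cid))),
        ):
            rows.append(IndicatorRow(cam.cam_id, name, "micro", cid, value))
    return rows


def communities(cam: CAM) -> list[frozenset[str]]:
    """Community partition by greedy modularity maximization, deterministic
    ordering (communities sorted by smallest member id)."""
    g = cam.graph()
    if g.number_of_edges() == 0:
        comms = [frozenset({n}) for n in g.nodes]
    else:
        comms = [frozenset(c) for c in nx.community.greedy_modularity_communities(g)]
    return sorted(comms, key=lambda c: min(c))


def mezzo_indicators(cam: CAM) -> list[IndicatorRow]:
    """Community-level indicators: per community size, mean valence and
    internal density, plus the number of connected components of the CAM."""
    if cam.n_concepts < 2:
        raise ValueError("mezzo indicators need at least 2 concepts")
    g = cam.graph()
    rows = [
        IndicatorRow(
            cam.cam_id, "n_components", "mezzo", "", float(nx.number_connected_components(g))
        )
    ]
    for k, comm in enumerate(communities(cam)):
        sub = g.subgraph(comm)
        nn = sub.number_of_nodes()
        dens = UNDEFINED if nn < 2 else sub.number_of_edges() / (nn * (nn - 1) / 2)
        members = [cam.concept(cid) for cid in comm]
        cid = f"community_{k}"
        rows.append(IndicatorRow(cam.cam_id, "community_size", "mezzo", cid, float(nn)))
        rows.append(IndicatorRow(cam.cam_id, "community_mean_valence", "mezzo", cid, _mean_valence(members)))
        rows.append(IndicatorRow(cam.cam_id, "community_density", "mezzo", cid, dens))
    return rows


# ---------------------------------------------------------------------------
# neighborhood valence (six variants)


def _removed_graph(
    cam: CAM,
    removed_edges: Iterable[tuple[str, str]] | None,
    removed_nodes: Iterable[str] | None,
) -> nx.Graph:
    g = cam.graph()
    for node in removed_nodes or ():
        if node in g:
            g.remove_node(node)
    for a, b in removed_edges or ():
        if g.has_edge(a, b):
            g.remove_edge(a, b)
    return g


def neighborhood_valence(
    cam: CAM,
    focus: str,
    variant: int,
    removed_edges: Iterable[tuple[str, str]] | None = None,
    removed_nodes: Iterable[str] | None = None,
    ambivalent_policy: str = "as_zero",
) -> float:
    """Mean valence over a focal concept's neighborhood, in six variants.

    With N1 the concepts adjacent to the focus and N2 the concepts within
    graph distance 2 (both excluding the focus itself, both computed after
    the temporary edge/node removals):

    1. plain mean valence over N1
    2. plain mean valence over N2
    3. |strength|-weighted mean over N1 (weight = |strength| of the edge to
       the focus)
    4. weighted mean over N2, weight = product of |strength|/3 along one
       shortest path from the focus (the maximum over shortest paths)
    5. affect-adjusted mean over N1: numerator sums all numeric valences,
       denominator counts only non-neutral, non-ambivalent neighbors
    6. affect-adjusted mean over N2

    Temporary removals let studies with deliberately bridged designs (two
    opposing anchor concepts) measure one side's neighborhood without the
    other side leaking in.  Returns NaN when the neighborhood (or, for 5/6,
    the affect-carrying denominator) is empty.
    """
    if variant not in range(1, 7):
        raise ValueError("variant must be 1..6")
    g = _removed_graph(cam, removed_edges, removed_nodes)
    if focus not in g:
        raise KeyError(f"focus concept {focus!r} absent (removed or unknown)")
    dist = nx.single_source_shortest_path_length(g, focus, cutoff=2)
    n1 = sorted(v for v, d in dist.items() if d == 1)
    n2 = sorted(v for v, d in dist.items() if 1 <= d <= 2)
    hood = n1 if variant in (1, 3, 5) else n2
    if not hood:
        return UNDEFINED
    val = {v: numeric_valence(cam.concept(v), ambivalent_policy) for v in hood}
    if any(val[v] is EXCLUDED for v in hood):
        hood = [v for v in hood if val[v] is not EXCLUDED]
        if not hood:
            return UNDEFINED

    # convex combinations of valences lie in [-3, 3]; clip float drift
    def _bounded(x: float) -> float:
        return float(min(3.0, max(-3.0, x)))

    if variant in (1, 2):
        return _bounded(np.mean([val[v] for v in hood]))
    if variant == 3:
        w = {v: abs(g.edges[focus, v]["strength"]) for v in hood}
        return _bounded(sum(w[v] * val[v] for v in hood) / sum(w.values()))
    if variant == 4:
        w = {}
        for v in hood:
            best = 0.0
            for path in nx.all_shortest_paths(g, focus, v):
                prod = 1.0
                for a, b in itertools.pairwise(path):
                    prod *= abs(g.edges[a, b]["strength"]) / 3.0
                best = max(best, prod)
            w[v] = best
        return _bounded(sum(w[v] * val[v] for v in hood) / sum(w.values()))
    # affect-adjusted (variants 5, 6): only affect-carrying concepts count
    # toward the denominator, the numerator keeps every neighbor's valence
    carriers = [
        v for v in hood
        if cam.concept(v).valence != AMBIVALENT and cam.concept(v).valence != 0
    ]
    if not carriers:
        return UNDEFINED
    return float(sum(val[v] for v in hood) / len(carriers))


# ---------------------------------------------------------------------------
# tabular interface


def indicator_table(rows: Iterable[IndicatorRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [r.__dict__ for r in rows],
        columns=["cam_id", "indicator", "level", "focus", "value"],
    )


def indicators_for_set(
    cams: CAMSet,
    levels: Sequence[str] = ("macro",),
    focus: Sequence[str] = (),
) -> pd.DataFrame:
    """Long-format indicator table over a CAM set."""
    rows: list[IndicatorRow] = []
    for cam in cams:
        if "macro" in levels:
            rows.extend(macro_indicators(cam))
        if "micro" in levels:
            ids = [f for f in focus if any(c.id == f for c in cam.concepts)]
            if ids:
                rows.extend(micro_indicators(cam, ids))
        if "mezzo" in levels and cam.n_concepts >= 2:
            rows.extend(mezzo_indicators(cam))
    return indicator_table(rows)


def summary_statistics(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-indicator mean/SD across CAMs, and the between-indicator Pearson
    correlation matrix with plain two-sided p-values (macro level only).

    The p-values are unadjusted; this is a screening table, not a
    multiple-testing-corrected inference.
    """
    macro = table[table["level"] == "macro"]
    wide = macro.pivot_table(index="cam_id", columns="indicator", values="value")
    summary = pd.DataFrame({"mean": wide.mean(), "sd": wide.std(ddof=1)})
    from scipy import stats

    cols = list(wide.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            sub = wide[[a, b]].dropna()
            if len(sub) < 3 or sub[a].std() == 0 or sub[b].std() == 0:
                r, p = UNDEFINED, UNDEFINED
            else:
                r, p = stats.pearsonr(sub[a], sub[b])
            rows.append({"indicator_a": a, "indicator_b": b, "r": r, "p": p})
    return summary, pd.DataFrame(rows, columns=["indicator_a", "indicator_b", "r", "p"])
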
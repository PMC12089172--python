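"""Cross-CAM aggregation into one canonical graph.

Many participants' CAMs are merged into a single graph whose node and edge
weights are drawing frequencies: a node's weight is the number of CAMs
containing that (canonical) concept label, an edge's weight the number of
CAMs drawing that pair connected.  Aggregation is meant to run *after*
summarization, since labels are matched by exact string equality.

Duplicate labels within one CAM are first made unique by the canonical
renaming rule: "cost" drawn twice becomes "cost_1", "cost_2", suffixes
assigned in descending order of degree (ties by concept id).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd

from .model import CAM, CAMSet
from .indicators import numeric_valence, macro_indicators
from .summarize import normalize_text


def canonicalize_cam(cam: CAM) -> CAM:
    """Rename within-CAM duplicate texts to label_1, label_2, ...

    Suffixes follow descending degree (on the undirected projection), ties
    broken by concept id ascending.  Unique texts are left untouched;
    applying the rule twice is a no-op.
    """
    g = cam.graph()
    by_text: dict[str, list] = {}
    for c in cam.concepts:
        by_text.setdefault(normalize_text(c.text), []).append(c)
    renames: dict[str, str] = {}
    for text, group in by_text.items():
        if len(group) < 2:
            continue
        group.sort(key=lambda c: (-g.degree(c.id), c.id))
        for rank, c in enumerate(group, start=1):
            renames[c.id] = f"{c.text}_{rank}"
    if not renames:
        return cam
    new = [replace(c, text=renames.get(c.id, c.text)) for c in cam.concepts]
    return cam.with_concepts(new)


def select_cams(
    cams: CAMSet,
    mode: str,
    k: int | None = None,
    ids: list[str] | None = None,
    seed: int | None = None,
) -> CAMSet:
    """Choose which CAMs enter the aggregate.

    Modes: ``random_k`` (seeded, without replacement), ``most_positive_k`` /
    ``most_negative_k`` (ranked by macro mean valence, ties by cam_id), and
    ``by_ids``.  Selection preserves the original CAM-set ordering.
    """
    if mode == "by_ids":
        known = set(cams.cam_ids)
        missing = [i for i in (ids or []) if i not in known]
        if missing:
            raise KeyError(f"unknown cam ids: {missing}")
        chosen = set(ids or [])
    elif mode == "random_k":
        if k is None or k > len(cams):
            raise ValueError("random_k needs k <= number of CAMs")
        rng = np.random.default_rng(seed)
        chosen = set(rng.choice(cams.cam_ids, size=k, replace=False).tolist())
    elif mode in ("most_positive_k", "most_negative_k"):
        if k is None or k > len(cams):
            raise ValueError(f"{mode} needs k <= number of CAMs")
        means = {
            cam.cam_id: next(
                r.value for r in macro_indicators(cam) if r.indicator == "mean_valence"
            )
            for cam in cams
        }
        sign = -1.0 if mode == "most_positive_k" else 1.0
        ranked = sorted(cams.cam_ids, key=lambda cid: (sign * means[cid], cid))
        chosen = set(ranked[:k])
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    return CAMSet(
        cams=[c for c in cams if c.cam_id in chosen],
        provenance=list(cams.provenance),
    )


@dataclass
class AggregateGraph:
    """The canonical aggregate: frequency-weighted nodes and edges.

    ``nodes``: label, frequency (CAMs containing the label), mean_valence
    (over contributing concepts).  ``edges``: label_a, label_b, frequency
    (CAMs connecting the pair), mean_strength (auxiliary; the visual weight
    is frequency).
    """

    nodes: pd.DataFrame
    edges: pd.DataFrame
    n_cams: int
    selection: str = ""

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for r in self.nodes.itertuples():
            g.add_node(r.label, frequency=int(r.frequency), mean_valence=float(r.mean_valence))
        for r in self.edges.itertuples():
            g.add_edge(
                r.label_a, r.label_b,
                frequency=int(r.frequency), mean_strength=float(r.mean_strength),
            )
        return g

    def adjacency_matrix(self) -> pd.DataFrame:
        labels = list(self.nodes["label"])
        mat = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
        for r in self.edges.itertuples():
            mat.loc[r.label_a, r.label_b] = int(r.frequency)
            mat.loc[r.label_b, r.label_a] = int(r.frequency)
        return mat

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph(), path)

    def to_dot(self, path) -> None:
        """Minimal DOT export; node size / edge width carry the frequencies."""
        lines = ["graph aggregate {"]
        for r in self.nodes.itertuples():
            lines.append(
                f'  "{r.label}" [frequency={int(r.frequency)}, '
                f'mean_valence={float(r.mean_valence):.3f}];'
            )
        for r in self.edges.itertuples():
            lines.append(
                f'  "{r.label_a}" -- "{r.label_b}" [frequency={int(r.frequency)}];'
            )
        lines.append("}")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")


def aggregate(cams: CAMSet, selection: str = "") -> AggregateGraph:
    """Merge a CAM set into its canonical aggregate graph.

    Every CAM is canonicalized first (duplicate labels suffixed), then node
    frequency counts CAMs containing each label, edge frequency counts CAMs
    connecting each label pair (any sign or direction).  Order-independent:
    permuting the CAM list yields an identical aggregate.
    """
    if len(cams) == 0:
        raise ValueError("cannot aggregate an empty selection")
    node_cams: dict[str, set[str]] = {}
    node_vals: dict[str, list[float]] = {}
    edge_cams: dict[tuple[str, str], set[str]] = {}
    edge_strengths: dict[tuple[str, str], list[float]] = {}
    for cam in cams:
        canon = canonicalize_cam(cam)
        labels = {c.id: normalize_text(c.text) for c in canon.concepts}
        for c in canon.concepts:
            lab = labels[c.id]
            node_cams.setdefault(lab, set()).add(cam.cam_id)
            node_vals.setdefault(lab, []).append(numeric_valence(c))
        seen_pairs: set[tuple[str, str]] = set()
        for e in canon.connectors:
            pair = tuple(sorted((labels[e.source], labels[e.target])))
            if pair in seen_pairs:
                continue
            seen_pairs.add(pair)
            edge_cams.setdefault(pair, set()).add(cam.cam_id)
            edge_strengths.setdefault(pair, []).append(float(e.strength))
    nodes = pd.DataFrame(
        [
            {
                "label": lab,
                "frequency": len(node_cams[lab]),
                "mean_valence": float(np.mean(node_vals[lab])),
            }
            for lab in sorted(node_cams)
        ],
        columns=["label", "frequency", "mean_valence"],
    )
    edges = pd.DataFrame(
        [
            {
                "label_a": a,
                "label_b": b,
                "frequency": len(edge_cams[(a, b)]),
                "mean_strength": float(np.mean(edge_strengths[(a, b)])),
            }
            for a, b in sorted(edge_cams)
        ],
        columns=["label_a", "label_b", "frequency", "mean_strength"],
    )
    return AggregateGraph(nodes=nodes, edges=edges, n_cams=len(cams), selection=selection)
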
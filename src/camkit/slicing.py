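"""Slicing CAMs into sub-CAMs and comparing the resulting components.

Study designs that seed a CAM with two opposing anchor concepts (e.g. "own
car" vs "public transport") produce maps that can be split by deleting the
bridging connector(s) and/or concepts.  The split is validated -- the
component count must match the researcher's expectation, anchors must land in
distinct components -- and each component becomes a standalone CAM that every
other module can re-ingest.  Across participants, the named components are
then compared with a within-subject (paired) t test on mean valence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .model import CAM, CAMSet
from .indicators import macro_indicators
from .summarize import normalize_text


@dataclass(frozen=True)
class SliceSpec:
    """What to delete and what the split should look like.

    Deletion targets are addressed by concept *text* (post-summarization
    normal form), so one spec applies across all participants' CAMs.
    """

    edges_to_delete: frozenset[frozenset[str]] = frozenset()
    nodes_to_delete: frozenset[str] = frozenset()
    expected_components: int = 2
    anchors: tuple[tuple[str, str], ...] = ()  # (component name, anchor text)
    min_component_size: int = 1

    def __post_init__(self) -> None:
        edges = frozenset(
            frozenset(normalize_text(t) for t in pair) for pair in self.edges_to_delete
        )
        nodes = frozenset(normalize_text(t) for t in self.nodes_to_delete)
        anchors = tuple((name, normalize_text(t)) for name, t in self.anchors)
        object.__setattr__(self, "edges_to_delete", edges)
        object.__setattr__(self, "nodes_to_delete", nodes)
        object.__setattr__(self, "anchors", anchors)
        if not edges and not nodes:
            raise ValueError("slice spec must delete at least one edge or node")
        if self.expected_components < 1:
            raise ValueError("expected_components must be positive")
        texts = [t for _, t in anchors]
        if len(set(texts)) != len(texts):
            raise ValueError("anchor texts must be distinct")


@dataclass
class SliceResult:
    components: list[CAM]
    verdict: str                       # "PASS" | "FAIL"
    reasons: list[str] = field(default_factory=list)
    component_names: dict[str, str] = field(default_factory=dict)  # cam_id -> anchor name


def _resolve_text(cam: CAM, text: str) -> str:
    """Concept id for a (normalized) text; duplicates or misses are errors."""
    hits = [c.id for c in cam.concepts if normalize_text(c.text) == text]
    if not hits:
        candidates = sorted({normalize_text(c.text) for c in cam.concepts})
        raise KeyError(f"no concept with text {text!r}; candidates: {candidates}")
    if len(hits) > 1:
        raise KeyError(
            f"text {text!r} is ambiguous in CAM {cam.cam_id!r} "
            "(canonicalize duplicate labels first)"
        )
    return hits[0]


def slice_cam(cam: CAM, spec: SliceSpec) -> SliceResult:
    """Apply a slice spec to one CAM and validate the split.

    Pure: the input CAM is untouched.  Deletions are applied on the
    undirected projection, connected components are computed, and each
    component is materialized as a standalone CAM (concept/connector ids
    preserved, cam_id suffixed ``/0``, ``/1``, ... in order of smallest
    concept id).  Verdict PASS iff the component count equals
    ``expected_components``, every component meets the minimum size, and the
    anchors (if given) map one-to-one onto components.
    """
    delete_ids = {_resolve_text(cam, t) for t in spec.nodes_to_delete}
    g = cam.graph()
    g.remove_nodes_from(delete_ids)
    for pair in spec.edges_to_delete:
        ids = [_resolve_text(cam, t) for t in sorted(pair)]
        if len(ids) == 2 and g.has_edge(*ids):
            g.remove_edge(*ids)
    comps = sorted(nx.connected_components(g), key=lambda s: min(s))
    sub_cams: list[CAM] = []
    for i, comp in enumerate(comps):
        concepts = tuple(c for c in cam.concepts if c.id in comp)
        connectors = tuple(
            e for e in cam.connectors
            if e.source in comp and e.target in comp and g.has_edge(e.source, e.target)
        )
        sub_cams.append(
            CAM(
                cam_id=f"{cam.cam_id}/{i}",
                participant_id=cam.participant_id,
                concepts=concepts,
                connectors=connectors,
                topic=cam.topic,
            )
        )
    reasons: list[str] = []
    if len(comps) != spec.expected_components:
        reasons.append(
            f"expected {spec.expected_components} components, got {len(comps)}"
        )
    small = [s.cam_id for s in sub_cams if s.n_concepts < spec.min_component_size]
    if small:
        reasons.append(f"components below minimum size: {small}")
    names: dict[str, str] = {}
    if spec.anchors:
        for name, text in spec.anchors:
            holders = [
                s.cam_id
                for s in sub_cams
                if any(normalize_text(c.text) == text for c in s.concepts)
            ]
            if not holders:
                reasons.append(f"anchor {text!r} ({name}) missing after slicing")
            else:
                holder = holders[0]
                if holder in names:
                    reasons.append(
                        f"anchors {names[holder]!r} and {name!r} share component {holder}"
                    )
                else:
                    names[holder] = name
    return SliceResult(
        components=sub_cams,
        verdict="PASS" if not reasons else "FAIL",
        reasons=reasons,
        component_names=names,
    )


def slice_set(cams: CAMSet, spec: SliceSpec) -> dict[str, SliceResult]:
    """Slice every CAM in a set with the same spec."""
    return {cam.cam_id: slice_cam(cam, spec) for cam in cams}


def component_comparison(results: dict[str, SliceResult]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within-subject comparison of two named components across participants.

    Expects each sliced CAM's result to name exactly two components via
    anchors.  Returns ``(per_component, test)``: per-component descriptives
    (mean valence, node count, density per participant) and the paired t test
    on mean valence -- t = mean(d) / (sd(d)/sqrt(n)) with df = n-1, two-sided
    p, and the effect size d_z = mean(d)/sd(d).  Participants missing either
    component are excluded with a warning row; zero difference variance gives
    an undefined-flagged (NaN) t.
    """
    names = sorted({n for r in results.values() for n in r.component_names.values()})
    if len(names) != 2:
        raise ValueError(f"component comparison needs exactly 2 anchor names, got {names}")
    rows = []
    pairs: list[tuple[float, float]] = []
    excluded: list[str] = []
    for cam_id, res in sorted(results.items()):
        by_name = {}
        for sub in res.components:
            name = res.component_names.get(sub.cam_id)
            if name is None:
                continue
            macro = {r.indicator: r.value for r in macro_indicators(sub)}
            by_name[name] = macro
            rows.append(
                {
                    "cam_id": cam_id,
                    "component": name,
                    "mean_valence": macro["mean_valence"],
                    "num_nodes": macro["num_nodes"],
                    "density": macro["density"],
                }
            )
        if set(by_name) == set(names):
            pairs.append((by_name[names[0]]["mean_valence"], by_name[names[1]]["mean_valence"]))
        else:
            excluded.append(cam_id)
    per_component = pd.DataFrame(
        rows, columns=["cam_id", "component", "mean_valence", "num_nodes", "density"]
    )
    n = len(pairs)
    if n < 2:
        raise ValueError("need at least 2 complete pairs for the within t test")
    d = np.array([a - b for a, b in pairs])
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        t_stat, p, dz = float("nan"), float("nan"), float("nan")
    else:
        t_stat = float(d.mean() / (sd / math.sqrt(n)))
        from scipy import stats
        p = float(2 * stats.t.sf(abs(t_stat), df=n - 1))
        dz = float(d.mean() / sd)
    test = pd.DataFrame(
        [
            {
                "component_a": names[0],
                "component_b": names[1],
                "n_pairs": n,
                "mean_diff": float(d.mean()),
                "sd_diff": sd if sd > 0 else float("nan"),
                "t": t_stat,
                "df": n - 1,
                "p": p,
                "d_z": dz,
                "n_excluded": len(excluded),
            }
        ]
    )
    return per_component, test
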
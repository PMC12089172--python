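"""Shared fixtures: hand-built CAMs and a random-CAM factory for oracle tests."""

from __future__ import annotations

import random

import pytest

from camkit.model import AMBIVALENT, CAM, CAMSet, Concept, Connector


def make_cam(
    cam_id: str,
    nodes: dict,
    edges: list,
    participant_id: str | None = None,
    predefined: set | None = None,
) -> CAM:
    """Terse CAM builder: nodes = {id: (text, valence)}, edges = [(a, b,
    strength)] or [(a, b, strength, directed)]."""
    predefined = predefined or set()
    concepts = tuple(
        Concept(id=i, text=t, valence=v, predefined=i in predefined)
        for i, (t, v) in nodes.items()
    )
    connectors = tuple(
        Connector(
            id=f"e{k}",
            source=e[0],
            target=e[1],
            strength=e[2],
            directed=e[3] if len(e) > 3 else False,
        )
        for k, e in enumerate(edges)
    )
    return CAM(
        cam_id=cam_id,
        participant_id=participant_id or f"p-{cam_id}",
        concepts=concepts,
        connectors=connectors,
    )


def random_cam(rng: random.Random, cam_id: str, max_nodes: int = 8) -> CAM:
    """Random small CAM: random simple graph, random valences (ambivalent
    included), random signed strengths.  Pure-python randomness so it shares
    nothing with the numpy-based synthetic generator."""
    n = rng.randint(2, max_nodes)
    nodes = {}
    for i in range(n):
        v = rng.choice([-3, -2, -1, 0, 0, 1, 2, 3, AMBIVALENT])
        nodes[f"n{i}"] = (f"word{i}", v)
    possible = [(f"n{i}", f"n{j}") for i in range(n) for j in range(i + 1, n)]
    m = rng.randint(1, len(possible))
    edges = [
        (a, b, rng.choice([-3, -2, -1, 1, 2, 3]), rng.random() < 0.3)
        for a, b in rng.sample(possible, m)
    ]
    return make_cam(cam_id, nodes, edges)


def cam_adjacency(cam: CAM) -> tuple[dict, dict]:
    """(adjacency dict, strength dict) views for the brute-force oracles."""
    adj = {c.id: set() for c in cam.concepts}
    strength = {}
    for e in cam.connectors:
        adj[e.source].add(e.target)
        adj[e.target].add(e.source)
        strength[frozenset((e.source, e.target))] = e.strength
    return adj, strength


@pytest.fixture
def star_cam() -> CAM:
    """Center 'hub' with 5 leaves; classic single-central-concept topology."""
    nodes = {"c": ("hub", 1)}
    edges = []
    for i, v in enumerate([2, -1, 3, 0, -2]):
        nodes[f"l{i}"] = (f"leaf{i}", v)
        edges.append(("c", f"l{i}", i % 3 + 1))
    return make_cam("star", nodes, edges, predefined={"c"})


@pytest.fixture
def two_cluster_cam() -> CAM:
    """Two valence-opposed clusters joined by one negative bridge -- the
    own-car / public-transport study design in miniature."""
    nodes = {
        "a0": ("own car", 1),
        "a1": ("comfort", 2),
        "a2": ("parking", -1),
        "b0": ("public transport", -2),
        "b1": ("crowding", -2),
        "b2": ("delays", -1),
    }
    edges = [
        ("a0", "a1", 2),
        ("a0", "a2", 1),
        ("b0", "b1", 3),
        ("b0", "b2", 2),
        ("a0", "b0", -3),  # the bridge
    ]
    return make_cam("bridge", nodes, edges, predefined={"a0", "b0"})


@pytest.fixture
def small_set(star_cam, two_cluster_cam) -> CAMSet:
    extra = make_cam(
        "third",
        {"x": ("own car", -1), "y": ("cost", 2), "z": ("cost", -2)},
        [("x", "y", 1), ("x", "z", -1)],
    )
    return CAMSet(cams=[star_cam, two_cluster_cam, extra])
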
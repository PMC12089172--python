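"""Network indicators vs brute-force oracles, and the neighborhood variants."""

import math
import random

import networkx as nx
import numpy as np
import pytest

from camkit.model import AMBIVALENT, CAM, Concept, Connector
from camkit.indicators import (
    EXCLUDED,
    communities,
    macro_indicators,
    mezzo_indicators,
    micro_indicators,
    neighborhood_valence,
    numeric_valence,
)
from conftest import cam_adjacency, make_cam, random_cam
import _oracles as oracle


def macro(cam, name):
    return next(r.value for r in macro_indicators(cam) if r.indicator == name)


class TestNumericValence:
    def test_integer_passthrough_and_policies(self):
        c = Concept(id="a", text="x", valence=3)
        assert numeric_valence(c) == 3.0
        amb = Concept(id="a", text="x", valence=AMBIVALENT)
        assert numeric_valence(amb, "as_zero") == 0.0
        assert numeric_valence(amb, "exclude") is EXCLUDED

    def test_mean_with_ambivalent_as_zero(self):
        cam = make_cam(
            "c",
            {"a": ("p", 3), "b": ("q", -3), "c": ("r", 0), "d": ("s", AMBIVALENT)},
            [("a", "b", 1), ("b", "c", 1), ("c", "d", 1)],
        )
        assert macro(cam, "mean_valence") == pytest.approx(0.0)


class TestMacro:
    def test_density_formula(self):
        cam = make_cam(
            "c",
            {f"n{i}": (f"t{i}", 0) for i in range(4)},
            [("n0", "n1", 1), ("n1", "n2", 1), ("n2", "n3", 1)],
        )
        assert macro(cam, "density") == pytest.approx(0.5)

    def test_path_diameter(self):
        cam = make_cam(
            "c", {"a": ("x", 0), "b": ("y", 0), "c2": ("z", 0)},
            [("a", "b", 1), ("b", "c2", 1)],
        )
        assert macro(cam, "diameter") == 2.0

    def test_class_shares(self, star_cam):
        shares = [
            macro(star_cam, f"pct_{k}")
            for k in ("positive", "negative", "neutral", "ambivalent")
        ]
        assert sum(shares) == pytest.approx(1.0)
        all_pos = make_cam("c", {"a": ("x", 1), "b": ("y", 2)}, [("a", "b", 1)])
        assert macro(all_pos, "pct_positive") == 1.0
        assert macro(all_pos, "pct_negative") == 0.0

    def test_single_node_density_undefined(self):
        cam = make_cam("c", {"a": ("x", 1)}, [])
        assert math.isnan(macro(cam, "density"))

    def test_central_node_valence_prefers_predefined(self, star_cam):
        assert macro(star_cam, "central_node_valence") == 1.0


class TestMicro:
    def test_star_degrees_and_betweenness(self, star_cam):
        rows = {
            (r.indicator, r.focus): r.value
            for r in micro_indicators(star_cam, ["c", "l0"])
        }
        assert rows[("degree", "c")] == 5.0
        assert rows[("betweenness", "l0")] == 0.0

    def test_unknown_focus_rejected(self, star_cam):
        with pytest.raises(KeyError):
            micro_indicators(star_cam, ["nope"])


class TestMezzo:
    def test_disjoint_triangles(self):
        nodes = {f"a{i}": (f"x{i}", 1) for i in range(3)}
        nodes.update({f"b{i}": (f"y{i}", -1) for i in range(3)})
        edges = [("a0", "a1", 1), ("a1", "a2", 1), ("a0", "a2", 1),
                 ("b0", "b1", 1), ("b1", "b2", 1), ("b0", "b2", 1)]
        cam = make_cam("c", nodes, edges)
        rows = mezzo_indicators(cam)
        n_comp = next(r.value for r in rows if r.indicator == "n_components")
        sizes = sorted(r.value for r in rows if r.indicator == "community_size")
        assert n_comp == 2.0 and sizes == [3.0, 3.0]

    def test_clique_single_community(self):
        nodes = {f"n{i}": (f"t{i}", 0) for i in range(4)}
        edges = [(f"n{i}", f"n{j}", 1) for i in range(4) for j in range(i + 1, 4)]
        assert len(communities(make_cam("c", nodes, edges))) == 1

    def test_planted_two_block_recovery(self):
        rng = np.random.default_rng(21)
        nodes, edges = {}, []
        for i in range(8):
            nodes[f"n{i}"] = (f"t{i}", 0)
        for i in range(8):
            for j in range(i + 1, 8):
                same = (i < 4) == (j < 4)
                p = 0.9 if same else 0.05
                if rng.random() < p:
                    edges.append((f"n{i}", f"n{j}", 1))
        cam = make_cam("c", nodes, edges)
        comms = communities(cam)
        planted = [frozenset(f"n{i}" for i in range(4)), frozenset(f"n{i}" for i in range(4, 8))]
        assert sorted(comms, key=min) == sorted(planted, key=min)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(30))
    def test_macro_micro_match_brute_force(self, seed):
        cam = random_cam(random.Random(seed), f"o{seed}")
        adj, _ = cam_adjacency(cam)
        assert macro(cam, "density") == pytest.approx(oracle.density(adj))
        assert macro(cam, "diameter") == oracle.diameter_largest_component(adj)
        rows = {
            (r.indicator, r.focus): r.value
            for r in micro_indicators(cam, [c.id for c in cam.concepts])
        }
        for c in cam.concepts:
            assert rows[("degree", c.id)] == oracle.degree(adj, c.id)
            assert rows[("betweenness", c.id)] == pytest.approx(
                oracle.betweenness(adj, c.id)
            )


class TestNeighborhood:
    def test_plain_mean_star(self):
        cam = make_cam(
            "c",
            {"f": ("focus", 0), "a": ("p", 2), "b": ("q", -1), "c2": ("r", 3)},
            [("f", "a", 1), ("f", "b", 2), ("f", "c2", 3)],
        )
        assert neighborhood_valence(cam, "f", 1) == pytest.approx(4 / 3)
        # strength-weighted: (1*2 + 2*-1 + 3*3)/6
        assert neighborhood_valence(cam, "f", 3) == pytest.approx(9 / 6)

    def test_all_neutral_neighbors(self):
        cam = make_cam(
            "c", {"f": ("focus", 2), "a": ("p", 0), "b": ("q", 0)},
            [("f", "a", 1), ("f", "b", 1)],
        )
        assert neighborhood_valence(cam, "f", 1) == 0.0
        assert math.isnan(neighborhood_valence(cam, "f", 5))

    def test_two_cluster_sides_differ(self, two_cluster_cam):
        """Around the negative-cluster anchor the order-2 mean is negative;
        the removals isolate each side as in bridged study designs."""
        bridge = [("a0", "b0")]
        v2_pt = neighborhood_valence(two_cluster_cam, "b0", 2, removed_edges=bridge)
        v2_car = neighborhood_valence(two_cluster_cam, "a0", 2, removed_edges=bridge)
        assert v2_pt < 0
        assert v2_car > v2_pt

    def test_removals_identity_when_empty(self, two_cluster_cam):
        for v in range(1, 7):
            a = neighborhood_valence(two_cluster_cam, "a0", v)
            b = neighborhood_valence(two_cluster_cam, "a0", v, removed_edges=[], removed_nodes=[])
            assert a == b or (math.isnan(a) and math.isnan(b))

    def test_focus_removed_rejected(self, two_cluster_cam):
        with pytest.raises(KeyError):
            neighborhood_valence(two_cluster_cam, "a0", 1, removed_nodes=["a0"])

    @pytest.mark.parametrize("seed", range(25))
    @pytest.mark.parametrize("variant", range(1, 7))
    def test_all_variants_match_oracle(self, seed, variant):
        cam = random_cam(random.Random(1000 + seed), f"nv{seed}")
        adj, strength = cam_adjacency(cam)
        val = {
            c.id: (0.0 if c.valence == AMBIVALENT else float(c.valence))
            for c in cam.concepts
        }
        carriers = {
            c.id for c in cam.concepts if c.valence != AMBIVALENT and c.valence != 0
        }
        for c in cam.concepts:
            got = neighborhood_valence(cam, c.id, variant)
            want = oracle.neighborhood_mean_full(adj, strength, val, carriers, c.id, variant)
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want)
                assert -3.0 <= got <= 3.0
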
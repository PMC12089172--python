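"""Data model: invariants, parsing, canonical serialization, validation."""

import json
import random

import pytest
from hypothesis import given, settings, strategies as st

from camkit.model import (
    AMBIVALENT,
    CAM,
    Concept,
    Connector,
    IntegrityError,
    ParseError,
    StudyConfig,
    Violation,
    from_tables,
    parse_cam,
    to_concept_table,
    to_edge_list,
    validate_against_config,
    write_cam,
)
from conftest import make_cam, random_cam


class TestInvariants:
    def test_valence_must_be_scale_or_ambivalent(self):
        with pytest.raises(ParseError):
            Concept(id="a", text="x", valence=4)
        with pytest.raises(ParseError):
            Concept(id="a", text="x", valence="very positive")
        assert Concept(id="a", text="x", valence=AMBIVALENT).is_ambivalent

    def test_neutral_zero_is_legal(self):
        assert Concept(id="a", text="x", valence=0).valence == 0

    def test_empty_text_only_for_predefined(self):
        with pytest.raises(ParseError):
            Concept(id="a", text="   ")
        Concept(id="a", text="", predefined=True)  # allowed

    def test_connector_rejects_self_loop_and_zero_strength(self):
        with pytest.raises(IntegrityError):
            Connector(id="e", source="a", target="a", strength=1)
        with pytest.raises(ParseError):
            Connector(id="e", source="a", target="b", strength=0)

    def test_cam_rejects_dangling_endpoint_with_id_in_message(self):
        with pytest.raises(IntegrityError, match="n9"):
            make_cam("c", {"n1": ("x", 0)}, [("n1", "n9", 1)])

    def test_cam_rejects_parallel_connectors(self):
        with pytest.raises(IntegrityError, match="simple"):
            CAM(
                cam_id="c",
                concepts=(Concept(id="a", text="x"), Concept(id="b", text="y")),
                connectors=(
                    Connector(id="e1", source="a", target="b", strength=1),
                    Connector(id="e2", source="b", target="a", strength=2),
                ),
            )

    def test_cam_rejects_duplicate_concept_ids(self):
        with pytest.raises(IntegrityError, match="duplicate"):
            CAM(cam_id="c", concepts=(Concept(id="a", text="x"), Concept(id="a", text="y")))


class TestParseWrite:
    def test_minimal_document(self):
        cam = parse_cam(
            {"cam_id": "c", "concepts": [{"id": "n1", "text": "x", "valence": 2}]}
        )
        assert cam.n_concepts == 1 and cam.n_connectors == 0

    def test_missing_required_field_named(self):
        with pytest.raises(ParseError, match="cam_id"):
            parse_cam({"concepts": []})

    def test_legacy_ambivalent_code_mapped(self):
        cam = parse_cam(
            {"cam_id": "c", "concepts": [{"id": "n1", "text": "x", "valence": 10}]}
        )
        assert cam.concepts[0].valence == AMBIVALENT
        with pytest.raises(ParseError):
            parse_cam(
                {"cam_id": "c", "concepts": [{"id": "n1", "text": "x", "valence": 10}]},
                legacy_ambivalent_code=None,
            )

    def test_round_trip_fixture(self, two_cluster_cam):
        assert parse_cam(write_cam(two_cluster_cam)) == two_cluster_cam

    def test_round_trip_preserves_ambivalent(self):
        cam = make_cam("c", {"a": ("x", AMBIVALENT), "b": ("y", 0)}, [("a", "b", 1)])
        again = parse_cam(write_cam(cam))
        assert again.concept("a").valence == AMBIVALENT

    def test_write_deterministic_across_concept_order(self):
        c1 = make_cam("c", {"a": ("x", 1), "b": ("y", 2)}, [("a", "b", 1)])
        c2 = CAM(
            cam_id="c",
            participant_id=c1.participant_id,
            concepts=tuple(reversed(c1.concepts)),
            connectors=c1.connectors,
        )
        assert c1 == c2
        assert write_cam(c1) == write_cam(c2)

    def test_write_empty_connectors_is_empty_array(self):
        cam = make_cam("c", {"a": ("x", 1)}, [])
        assert json.loads(write_cam(cam))["connectors"] == []

    @settings(max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_round_trip_identity_on_random_cams(self, seed):
        cam = random_cam(random.Random(seed), f"rc{seed}")
        assert parse_cam(write_cam(cam)) == cam


class TestTables:
    def test_edge_list_row_count(self, star_cam):
        assert len(to_edge_list(star_cam)) == 5
        assert len(to_edge_list(make_cam("c", {"a": ("x", 1)}, []))) == 0

    def test_table_round_trip_isomorphic(self, two_cluster_cam):
        rebuilt = from_tables(
            to_concept_table(two_cluster_cam),
            to_edge_list(two_cluster_cam),
            cam_id=two_cluster_cam.cam_id,
            participant_id=two_cluster_cam.participant_id,
        )
        assert {c.id: (c.text, c.valence) for c in rebuilt.concepts} == {
            c.id: (c.text, c.valence) for c in two_cluster_cam.concepts
        }
        assert {(e.pair, e.strength, e.directed) for e in rebuilt.connectors} == {
            (e.pair, e.strength, e.directed) for e in two_cluster_cam.connectors
        }


class TestStudyConfigValidation:
    def test_config_field_ranges_enforced(self):
        with pytest.raises(Exception):
            StudyConfig(min_num_nodes=0)
        with pytest.raises(Exception):
            StudyConfig(max_num_words=9)
        with pytest.raises(Exception):
            StudyConfig(max_length_chars=10)

    def test_too_few_nodes(self, star_cam):
        violations = validate_against_config(star_cam, StudyConfig(min_num_nodes=7))
        assert Violation("TOO_FEW_NODES") in violations

    def test_disconnected_concept_named(self):
        cam = make_cam("c", {"a": ("x", 0), "b": ("y", 0), "z": ("lonely", 0)}, [("a", "b", 1)])
        violations = validate_against_config(cam, StudyConfig())
        assert Violation("DISCONNECTED_CONCEPT", ("z",)) in violations

    def test_compliant_star_is_clean(self, star_cam):
        assert validate_against_config(star_cam, StudyConfig(min_num_nodes=3)) == []

    def test_switch_rules(self):
        cam = make_cam(
            "c",
            {"a": ("x", AMBIVALENT), "b": ("y", 0)},
            [("a", "b", -2, True)],
        )
        cfg = StudyConfig(
            enable_ambivalent=False, enable_arrows=False, only_straight_con=True
        )
        rules = {v.rule for v in validate_against_config(cam, cfg)}
        assert {"AMBIVALENT_DISABLED", "ARROW_DISABLED", "OPPOSING_DISABLED"} <= rules

    def test_word_and_char_limits(self):
        cam = make_cam("c", {"a": ("one two three four", 0), "b": ("y" * 50, 0)}, [("a", "b", 1)])
        cfg = StudyConfig(max_num_words=3, max_length_chars=30)
        rules = {v.rule for v in validate_against_config(cam, cfg)}
        assert {"TOO_MANY_WORDS", "TOO_MANY_CHARS"} <= rules

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_empty_violations_iff_all_predicates_pass(self, seed):
        """Cross-check against independent per-rule predicates."""
        rng = random.Random(seed)
        cam = random_cam(rng, f"v{seed}")
        cfg = StudyConfig(
            min_num_nodes=rng.randint(1, 10),
            max_num_words=rng.randint(1, 5),
            max_length_chars=rng.choice([30, 40]),
            enable_ambivalent=rng.random() < 0.5,
            enable_arrows=rng.random() < 0.5,
            only_straight_con=rng.random() < 0.5,
        )
        connected = {e for c in cam.connectors for e in (c.source, c.target)}
        predicates = [
            cam.n_concepts >= cfg.min_num_nodes,
            cam.n_concepts <= 1 or all(c.id in connected for c in cam.concepts),
            all(len(c.text.split()) <= cfg.max_num_words for c in cam.concepts),
            all(len(c.text) <= cfg.max_length_chars for c in cam.concepts),
            cfg.enable_ambivalent or not any(c.is_ambivalent for c in cam.concepts),
            cfg.enable_arrows or not any(e.directed for e in cam.connectors),
            not cfg.only_straight_con or all(e.strength > 0 for e in cam.connectors),
        ]
        assert (validate_against_config(cam, cfg) == []) == all(predicates)
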
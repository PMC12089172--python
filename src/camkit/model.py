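"""Core CAM data model.

A cognitive-affective map (CAM) is one participant's belief network: concepts
(nodes) carrying free text and an affective valence on the integer scale -3
(strongly negative) to +3 (strongly positive) -- or the distinct *ambivalent*
state -- connected by signed, optionally directed connectors with strength in
{-3..-1, +1..+3} (positive = supporting, negative = opposing).  A CAM is a
simple graph: no self-loops and at most one connector per concept pair.

This module provides the domain types, invariant checking, validation of a CAM
against a study configuration, canonical (byte-stable) JSON serialization, and
tabular / GraphML interop for standard graph tooling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import pandas as pd

#: Distinct valence state for concepts rated simultaneously positive and
#: negative.  Kept as a string marker (never a number) so it cannot leak into
#: arithmetic unnoticed.
AMBIVALENT = "ambivalent"

VALENCE_RANGE = tuple(range(-3, 4))
STRENGTH_RANGE = tuple(v for v in range(-3, 4) if v != 0)


class CamError(ValueError):
    """Base class for CAM data errors."""


class ParseError(CamError):
    """Raised when a document does not match the canonical schema."""


class IntegrityError(CamError):
    """Raised when cross-references inside a CAM do not resolve."""


def _check_valence(valence: object) -> int | str:
    if valence == AMBIVALENT:
        return AMBIVALENT
    if isinstance(valence, bool) or not isinstance(valence, int):
        raise ParseError(f"valence must be an integer in -3..3 or {AMBIVALENT!r}, got {valence!r}")
    if valence not in VALENCE_RANGE:
        raise ParseError(f"valence {valence} outside -3..3")
    return valence


@dataclass(frozen=True)
class Concept:
    """A node of a CAM.

    Parameters
    ----------
    id : str
        Opaque identifier, unique within the owning CAM.
    text : str
        Free-text label drawn by the participant.  Must be non-empty after
        whitespace stripping unless the concept is predefined by the study.
    valence : int or str
        Integer in -3..+3 or the :data:`AMBIVALENT` marker.
    comment : str
        Optional free-text elaboration.
    position : tuple of float
        (x, y) in screen pixels, origin top-left; stored, not analyzed.
    predefined : bool
        Whether the concept was placed by the researcher.
    raw_text : str or None
        Original label before summarization, set by
        :func:`camkit.summarize.apply_summary`.
    """

    id: str
    text: str
    valence: int | str = 0
    comment: str = ""
    position: tuple[float, float] = (0.0, 0.0)
    predefined: bool = False
    raw_text: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "valence", _check_valence(self.valence))
        object.__setattr__(self, "position", (float(self.position[0]), float(self.position[1])))
        if not self.text.strip() and not self.predefined:
            raise ParseError(f"concept {self.id!r}: empty text on a non-predefined concept")

    @property
    def is_ambivalent(self) -> bool:
        return self.valence == AMBIVALENT


@dataclass(frozen=True)
class Connector:
    """An edge of a CAM with signed strength and optional direction.

    ``strength`` is an integer in {-3..-1, +1..+3}; positive connectors are
    supporting (solid lines), negative are opposing (dashed).  ``directed``
    True means an arrow source -> target, False a bidirectional line.
    """

    id: str
    source: str
    target: str
    strength: int
    directed: bool = False

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise IntegrityError(f"connector {self.id!r}: self-loop on {self.source!r}")
        if self.strength not in STRENGTH_RANGE:
            raise ParseError(
                f"connector {self.id!r}: strength {self.strength!r} not in -3..-1, +1..+3"
            )

    @property
    def pair(self) -> frozenset[str]:
        """Unordered endpoint pair (used to enforce the simple-graph rule)."""
        return frozenset((self.source, self.target))


@dataclass(frozen=True, eq=False)
class CAM:
    """One participant's cognitive-affective map.

    Equality is structural and order-insensitive: two CAMs are equal when
    they agree on all metadata and on the *sets* of concepts and connectors,
    regardless of storage order (parse/write round trips normalize order).
    """

    cam_id: str
    participant_id: str = ""
    concepts: tuple[Concept, ...] = ()
    connectors: tuple[Connector, ...] = ()
    topic: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "concepts", tuple(self.concepts))
        object.__setattr__(self, "connectors", tuple(self.connectors))
        ids = [c.id for c in self.concepts]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"CAM {self.cam_id!r}: duplicate concept ids {dupes}")
        conn_ids = [c.id for c in self.connectors]
        if len(set(conn_ids)) != len(conn_ids):
            dupes = sorted({i for i in conn_ids if conn_ids.count(i) > 1})
            raise IntegrityError(f"CAM {self.cam_id!r}: duplicate connector ids {dupes}")
        known = set(ids)
        dangling = sorted(
            {e for c in self.connectors for e in (c.source, c.target) if e not in known}
        )
        if dangling:
            raise IntegrityError(
                f"CAM {self.cam_id!r}: connector endpoints not found: {dangling}"
            )
        pairs = [c.pair for c in self.connectors]
        if len(set(pairs)) != len(pairs):
            raise IntegrityError(
                f"CAM {self.cam_id!r}: multiple connectors between one concept pair "
                "(CAMs are simple graphs)"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CAM):
            return NotImplemented
        return (
            (self.cam_id, self.participant_id, self.topic) ==
            (other.cam_id, other.participant_id, other.topic)
            and sorted(self.concepts, key=lambda c: c.id)
            == sorted(other.concepts, key=lambda c: c.id)
            and sorted(self.connectors, key=lambda e: e.id)
            == sorted(other.connectors, key=lambda e: e.id)
        )

    def __hash__(self) -> int:
        return hash((self.cam_id, frozenset(self.concepts), frozenset(self.connectors)))

    # -- lookups ---------------------------------------------------------

    def concept(self, concept_id: str) -> Concept:
        for c in self.concepts:
            if c.id == concept_id:
                return c
        raise KeyError(concept_id)

    def concepts_by_text(self, text: str) -> list[Concept]:
        return [c for c in self.concepts if c.text == text]

    @property
    def n_concepts(self) -> int:
        return len(self.concepts)

    @property
    def n_connectors(self) -> int:
        return len(self.connectors)

    # -- graph views -----------------------------------------------------

    def graph(self) -> nx.Graph:
        """Undirected simple-graph projection with node/edge attributes.

        Distance and degree computations in the toolkit run on this
        projection; in- and out-degree are deliberately not distinguished.
        """
        g = nx.Graph()
        for c in self.concepts:
            g.add_node(c.id, text=c.text, valence=c.valence, predefined=c.predefined)
        for e in self.connectors:
            g.add_edge(e.source, e.target, strength=e.strength, directed=e.directed, id=e.id)
        return g

    def digraph(self) -> nx.DiGraph:
        """Directed view: undirected connectors contribute both arcs."""
        g = nx.DiGraph()
        for c in self.concepts:
            g.add_node(c.id, text=c.text, valence=c.valence)
        for e in self.connectors:
            g.add_edge(e.source, e.target, strength=e.strength)
            if not e.directed:
                g.add_edge(e.target, e.source, strength=e.strength)
        return g

    def with_concepts(self, concepts: Sequence[Concept]) -> "CAM":
        return replace(self, concepts=tuple(concepts))


@dataclass
class CAMSet:
    """An ordered collection of CAMs from one study."""

    cams: list[CAM] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.cam_id for c in self.cams]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"duplicate cam_ids in set: {dupes}")

    def __iter__(self) -> Iterator[CAM]:
        return iter(self.cams)

    def __len__(self) -> int:
        return len(self.cams)

    def __getitem__(self, key: int | str) -> CAM:
        if isinstance(key, int):
            return self.cams[key]
        for cam in self.cams:
            if cam.cam_id == key:
                return cam
        raise KeyError(key)

    @property
    def cam_ids(self) -> list[str]:
        return [c.cam_id for c in self.cams]

    def all_concepts(self) -> Iterator[tuple[CAM, Concept]]:
        for cam in self.cams:
            for c in cam.concepts:
                yield cam, c


# StudyConfig field -> (minimum, maximum) for the integer-valued parameters.
_CONFIG_RANGES = {
    "min_num_nodes": (1, 50),
    "max_num_words": (1, 5),
    "max_length_chars": (30, 300),
}


@dataclass(frozen=True)
class StudyConfig:
    """Researcher-set parameters constraining what participants may draw.

    Mirrors the data-collection tool's study parameters: the minimum number
    of concepts before a CAM may be saved, per-concept word/character limits,
    and switches for ambivalent concepts, directed arrows and opposing
    (negative) connections.
    """

    min_num_nodes: int = 1
    max_num_words: int = 5
    max_length_chars: int = 300
    enable_ambivalent: bool = True
    enable_arrows: bool = True
    bidirectional_default: bool = True
    only_straight_con: bool = False

    def __post_init__(self) -> None:
        for name, (lo, hi) in _CONFIG_RANGES.items():
            v = getattr(self, name)
            if not isinstance(v, int) or not lo <= v <= hi:
                raise CamError(f"StudyConfig.{name}={v!r} outside allowed range {lo}-{hi}")

    @classmethod
    def from_json(cls, raw: str | Mapping) -> "StudyConfig":
        doc = json.loads(raw) if isinstance(raw, str) else dict(raw)
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in doc.items() if k in known})


@dataclass(frozen=True)
class Violation:
    """One broken study-configuration rule, as data (never an exception)."""

    rule: str
    elements: tuple[str, ...] = ()

    def __str__(self) -> str:
        return self.rule if not self.elements else f"{self.rule}({', '.join(self.elements)})"


# ---------------------------------------------------------------------------
# parsing / serialization


def parse_cam(raw: str | bytes | Mapping, *, legacy_ambivalent_code: int | None = 10) -> CAM:
    """Parse a canonical CAM JSON document into a :class:`CAM`.

    The canonical schema is the object written by :func:`write_cam`.  As a
    legacy dialect hook, a numeric valence equal to ``legacy_ambivalent_code``
    (default 10, as used by Valence-derived exports) is mapped to the
    :data:`AMBIVALENT` marker; pass ``None`` to disable the mapping.

    Raises
    ------
    ParseError
        On schema violations, naming the offending field.
    IntegrityError
        On dangling connector endpoints or duplicate ids, listing them.
    """
    if isinstance(raw, (str, bytes)):
        try:
            doc = json.loads(raw)
        except json.JSONDecodeError as exc:
            raise ParseError(f"not valid JSON: {exc}") from exc
    else:
        doc = raw
    if not isinstance(doc, Mapping):
        raise ParseError("top level must be a JSON object")
    for required in ("cam_id", "concepts"):
        if required not in doc:
            raise ParseError(f"missing required field {required!r}")
    try:
        concepts = []
        for cd in doc.get("concepts", []):
            valence = cd["valence"]
            if legacy_ambivalent_code is not None and valence == legacy_ambivalent_code:
                valence = AMBIVALENT
            pos = cd.get("position", {"x": 0.0, "y": 0.0})
            concepts.append(
                Concept(
                    id=str(cd["id"]),
                    text=str(cd["text"]),
                    valence=valence,
                    comment=str(cd.get("comment", "")),
                    position=(pos["x"], pos["y"]),
                    predefined=bool(cd.get("predefined", False)),
                    raw_text=cd.get("raw_text"),
                )
            )
        connectors = [
            Connector(
                id=str(ed["id"]),
                source=str(ed["source"]),
                target=str(ed["target"]),
                strength=ed["strength"],
                directed=bool(ed.get("directed", False)),
            )
            for ed in doc.get("connectors", [])
        ]
        return CAM(
            cam_id=str(doc.get("cam_id", "")),
            participant_id=str(doc.get("participant_id", "")),
            concepts=tuple(concepts),
            connectors=tuple(connectors),
            topic=doc.get("topic"),
        )
    except KeyError as exc:
        raise ParseError(f"missing required field {exc.args[0]!r}") from exc


def cam_to_dict(cam: CAM) -> dict:
    """Plain-dict form of a CAM in the canonical schema."""
    return {
        "cam_id": cam.cam_id,
        "participant_id": cam.participant_id,
        "topic": cam.topic,
        "concepts": [
            {
                "id": c.id,
                "text": c.text,
                "comment": c.comment,
                "valence": c.valence,
                "position": {"x": c.position[0], "y": c.position[1]},
                "predefined": c.predefined,
                **({"raw_text": c.raw_text} if c.raw_text is not None else {}),
            }
            for c in sorted(cam.concepts, key=lambda c: c.id)
        ],
        "connectors": [
            {
                "id": e.id,
                "source": e.source,
                "target": e.target,
                "strength": e.strength,
                "directed": e.directed,
            }
            for e in sorted(cam.connectors, key=lambda e: e.id)
        ],
    }


def write_cam(cam: CAM) -> str:
    """Serialize to canonical JSON: keys sorted, byte-identical for equal CAMs."""
    return json.dumps(cam_to_dict(cam), sort_keys=True, indent=1, ensure_ascii=False)


def read_cam_file(path) -> CAM:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_cam(fh.read())


def write_cam_file(cam: CAM, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_cam(cam))
        fh.write("\n")


def load_cam_set(paths: Iterable) -> CAMSet:
    paths = [str(p) for p in paths]
    return CAMSet(cams=[read_cam_file(p) for p in paths], provenance=paths)


# ---------------------------------------------------------------------------
# validation against a study configuration


def validate_against_config(cam: CAM, cfg: StudyConfig) -> list[Violation]:
    """Check a CAM against every study-configuration rule.

    Returns one :class:`Violation` per broken rule (with the offending
    element ids); an empty list means the CAM is compliant.  Rules mirror the
    collection tool's save-time checks: minimum concept count, no
    disconnected concepts, per-concept word and character limits, and the
    ambivalent / arrow / opposing-connection switches.
    """
    out: list[Violation] = []
    if cam.n_concepts < cfg.min_num_nodes:
        out.append(Violation("TOO_FEW_NODES"))
    if cam.n_concepts > 1:
        connected = {e for c in cam.connectors for e in (c.source, c.target)}
        lonely = tuple(sorted(c.id for c in cam.concepts if c.id not in connected))
        if lonely:
            out.append(Violation("DISCONNECTED_CONCEPT", lonely))
    wordy = tuple(
        sorted(c.id for c in cam.concepts if len(c.text.split()) > cfg.max_num_words)
    )
    if wordy:
        out.append(Violation("TOO_MANY_WORDS", wordy))
    long_ = tuple(sorted(c.id for c in cam.concepts if len(c.text) > cfg.max_length_chars))
    if long_:
        out.append(Violation("TOO_MANY_CHARS", long_))
    if not cfg.enable_ambivalent:
        amb = tuple(sorted(c.id for c in cam.concepts if c.is_ambivalent))
        if amb:
            out.append(Violation("AMBIVALENT_DISABLED", amb))
    if not cfg.enable_arrows:
        arrows = tuple(sorted(e.id for e in cam.connectors if e.directed))
        if arrows:
            out.append(Violation("ARROW_DISABLED", arrows))
    if cfg.only_straight_con:
        opposing = tuple(sorted(e.id for e in cam.connectors if e.strength < 0))
        if opposing:
            out.append(Violation("OPPOSING_DISABLED", opposing))
    return out


# ---------------------------------------------------------------------------
# tabular / GraphML interop


def to_edge_list(cam: CAM) -> pd.DataFrame:
    """Connector table (source, target, strength, directed), ordered by id."""
    rows = [
        {"source": e.source, "target": e.target, "strength": e.strength, "directed": e.directed}
        for e in sorted(cam.connectors, key=lambda e: e.id)
    ]
    return pd.DataFrame(rows, columns=["source", "target", "strength", "directed"])


def to_concept_table(cam: CAM) -> pd.DataFrame:
    rows = [
        {
            "id": c.id,
            "text": c.text,
            "comment": c.comment,
            "valence": c.valence,
            "x": c.position[0],
            "y": c.position[1],
            "predefined": c.predefined,
        }
        for c in sorted(cam.concepts, key=lambda c: c.id)
    ]
    return pd.DataFrame(rows, columns=["id", "text", "comment", "valence", "x", "y", "predefined"])


def from_tables(
    concepts: pd.DataFrame, edges: pd.DataFrame, cam_id: str = "", participant_id: str = ""
) -> CAM:
    """Reconstruct a CAM from its concept and edge tables (round-trip of
    :func:`to_concept_table` / :func:`to_edge_list`; connector ids are
    regenerated)."""
    cs = tuple(
        Concept(
            id=str(r.id),
            text=str(r.text),
            valence=r.valence if r.valence == AMBIVALENT else int(r.valence),
            comment=str(r.comment) if not pd.isna(r.comment) else "",
            position=(float(r.x), float(r.y)),
            predefined=bool(r.predefined),
        )
        for r in concepts.itertuples()
    )
    es = tuple(
        Connector(
            id=f"e{i}",
            source=str(r.source),
            target=str(r.target),
            strength=int(r.strength),
            directed=bool(r.directed),
        )
        for i, r in enumerate(edges.itertuples())
    )
    return CAM(cam_id=cam_id, participant_id=participant_id, concepts=cs, connectors=es)


def to_graphml(cam: CAM, path) -> None:
    """GraphML export for downstream graph tools (valence kept as string so
    the ambivalent state survives)."""
    g = nx.Graph()
    for c in cam.concepts:
        g.add_node(c.id, text=c.text, valence=str(c.valence), predefined=c.predefined)
    for e in cam.connectors:
        g.add_edge(e.source, e.target, strength=e.strength, directed=e.directed)
    nx.write_graphml(g, path)
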
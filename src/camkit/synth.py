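"""Synthetic CAM generator with known ground truth.

Emulates the data regimes that different study designs produce: a single
predefined central concept yields a *star* topology, two opposing predefined
anchors yield *two clusters* joined by one bridge, predefined roots yield a
*tree*, and free drawing yields a partially connected *mesh*.  Concept
valences follow a per-participant latent attitude: mu_cam ~ Normal(mu0, tau),
valence = clip(round(Normal(mu_cam, sigma)), -3, 3), with an independent coin
flip turning a concept ambivalent.  Text noise (planted typos at OSA distance
exactly 1, or dictionary synonyms) exercises the summarization machinery.

Every generated set comes with a ground-truth record sufficient to score
summarization recovery, clustering recovery, slicing verdicts and reliability
simulations.  One pseudo-random stream is derived per CAM from (seed, CAM
index), so regenerating CAM i is stable under changes of ``n_cams``.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .data import DEFAULT_SYNONYMS, DEFAULT_VOCABULARY
from .model import AMBIVALENT, CAM, CAMSet, Concept, Connector, StudyConfig
from .summarize import osa_distance


@dataclass(frozen=True)
class GenConfig:
    """Parameters of the synthetic study.

    ``n_concepts`` is an inclusive (min, max) range drawn uniformly per CAM;
    it must stay within the collection tool's 1-50 limit.  ``group_means``
    optionally splits participants into latent attitude groups (first half /
    second half) with different mu0 -- the planted structure that valence
    clustering should recover.
    """

    n_cams: int = 30
    topology: str = "two_cluster"  # star | two_cluster | tree | mesh | free
    n_concepts: tuple[int, int] = (8, 14)
    mu0: float = 0.0
    tau: float = 1.0
    sigma: float = 0.8
    p_ambivalent: float = 0.05
    p_directed: float = 0.2
    p_extra_edge: float = 0.15
    p_typo: float = 0.1
    p_synonym: float = 0.0
    group_means: tuple[float, ...] | None = None
    vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY
    synonyms: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_SYNONYMS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.n_concepts
        if not (1 <= lo <= hi <= 50):
            raise ValueError("n_concepts range must lie within 1..50")
        for p in (self.p_ambivalent, self.p_directed, self.p_extra_edge,
                  self.p_typo, self.p_synonym):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.topology not in ("star", "two_cluster", "tree", "mesh", "free"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.topology == "two_cluster" and lo < 2:
            raise ValueError("two_cluster needs at least 2 concepts (the anchors)")
        if hi > len(self.vocabulary):
            raise ValueError("vocabulary smaller than the maximum CAM size")

    def study_config(self) -> StudyConfig:
        """The study configuration these CAMs are generated to satisfy."""
        return StudyConfig(
            min_num_nodes=self.n_concepts[0],
            max_num_words=3,
            max_length_chars=30,
            enable_ambivalent=self.p_ambivalent > 0,
            enable_arrows=self.p_directed > 0,
            bidirectional_default=True,
            only_straight_con=False,  # two_cluster bridges are opposing
        )


def _cam_rng(cfg: GenConfig, index: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, index])


def _draw_valence(rng: np.random.Generator, mu: float, cfg: GenConfig):
    if cfg.p_ambivalent > 0 and rng.random() < cfg.p_ambivalent:
        return AMBIVALENT
    return int(np.clip(np.round(rng.normal(mu, cfg.sigma)), -3, 3))


def _edges_for_topology(
    rng: np.random.Generator, topology: str, n: int, p_extra: float
) -> tuple[list[tuple[int, int]], list[tuple[int, int]], dict[int, int]]:
    """Return (within edges, bridge edges, cluster membership by node)."""
    cluster = {i: 0 for i in range(n)}
    edges: list[tuple[int, int]] = []
    bridge: list[tuple[int, int]] = []
    if topology == "star":
        edges = [(0, i) for i in range(1, n)]
    elif topology == "two_cluster":
        cluster[1] = 1
        members: dict[int, list[int]] = {0: [0], 1: [1]}
        for i in range(2, n):
            side = int(rng.integers(0, 2))
            cluster[i] = side
            attach = members[side][int(rng.integers(0, len(members[side])))]
            edges.append((attach, i))
            members[side].append(i)
        bridge = [(0, 1)]
    elif topology == "tree":
        for i in range(1, n):
            edges.append((int(rng.integers(0, i)), i))
    else:  # mesh / free: random spanning tree plus extra edges
        for i in range(1, n):
            edges.append((int(rng.integers(0, i)), i))
        existing = {frozenset(e) for e in edges}
        for i in range(n):
            for j in range(i + 1, n):
                if frozenset((i, j)) not in existing and rng.random() < p_extra:
                    edges.append((i, j))
    return edges, bridge, cluster


def generate_cam_set(cfg: GenConfig) -> tuple[CAMSet, dict]:
    """Generate a CAM set and its ground-truth record.

    The record contains per-CAM latent attitudes (``mu``), attitude group
    indices when ``group_means`` is set, two-cluster memberships and the
    bridge pair, and (after :func:`inject_text_noise`) planted text-noise
    identities.  Generated CAMs satisfy :meth:`GenConfig.study_config`.
    """
    cams = []
    truth: dict = {
        "mu": {}, "group": {}, "clusters": {}, "bridge": {},
        "topology": cfg.topology, "seed": cfg.seed,
    }
    n_groups = len(cfg.group_means) if cfg.group_means else 0
    for i in range(cfg.n_cams):
        rng = _cam_rng(cfg, i)
        cam_id = f"cam{i:04d}"
        if n_groups:
            group = min(n_groups - 1, i * n_groups // cfg.n_cams)
            mu = rng.normal(cfg.group_means[group], cfg.tau)
            truth["group"][cam_id] = group
        else:
            mu = rng.normal(cfg.mu0, cfg.tau)
        truth["mu"][cam_id] = float(mu)
        lo, hi = cfg.n_concepts
        n = int(rng.integers(lo, hi + 1))
        texts = [
            cfg.vocabulary[j]
            for j in rng.choice(len(cfg.vocabulary), size=n, replace=False)
        ]
        edges, bridge, cluster = _edges_for_topology(
            rng, cfg.topology, n, cfg.p_extra_edge
        )
        n_predef = 1 if cfg.topology in ("star", "tree") else 2 if cfg.topology == "two_cluster" else 0
        angles = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        concepts = tuple(
            Concept(
                id=f"{cam_id}-n{j}",
                text=texts[j],
                valence=_draw_valence(rng, mu, cfg),
                position=(
                    round(400 + 250 * float(np.cos(angles[j])), 1),
                    round(300 + 250 * float(np.sin(angles[j])), 1),
                ),
                predefined=j < n_predef,
            )
            for j in range(n)
        )
        connectors = []
        for k, (a, b) in enumerate(edges):
            connectors.append(
                Connector(
                    id=f"{cam_id}-e{k}",
                    source=f"{cam_id}-n{a}",
                    target=f"{cam_id}-n{b}",
                    strength=int(rng.integers(1, 4)),
                    directed=bool(cfg.p_directed > 0 and rng.random() < cfg.p_directed),
                )
            )
        for k, (a, b) in enumerate(bridge):
            connectors.append(
                Connector(
                    id=f"{cam_id}-b{k}",
                    source=f"{cam_id}-n{a}",
                    target=f"{cam_id}-n{b}",
                    strength=int(rng.integers(-3, 0)),
                    directed=False,
                )
            )
        cams.append(
            CAM(
                cam_id=cam_id,
                participant_id=f"p{i:04d}",
                concepts=concepts,
                connectors=tuple(connectors),
                topic=f"synthetic/{cfg.topology}",
            )
        )
        if cfg.topology == "two_cluster":
            truth["clusters"][cam_id] = {
                f"{cam_id}-n{j}": side for j, side in cluster.items()
            }
            truth["bridge"][cam_id] = [texts[0], texts[1]]
    return CAMSet(cams=cams, provenance=[f"synth:{cfg.topology}:seed={cfg.seed}"]), truth


# ---------------------------------------------------------------------------
# text noise


_LETTERS = string.ascii_lowercase


def _make_typo(rng: np.random.Generator, word: str) -> str:
    """One edit at OSA distance exactly 1: adjacent transposition of two
    differing characters, or substitution by a different letter."""
    if len(word) >= 2 and rng.random() < 0.5:
        positions = [i for i in range(len(word) - 1) if word[i] != word[i + 1]]
        if positions:
            i = positions[int(rng.integers(0, len(positions)))]
            return word[:i] + word[i + 1] + word[i] + word[i + 2 :]
    i = int(rng.integers(0, len(word)))
    choices = [c for c in _LETTERS if c != word[i]]
    return word[:i] + choices[int(rng.integers(0, len(choices)))] + word[i + 1 :]


def inject_text_noise(
    cams: CAMSet, cfg: GenConfig, noise_seed: int | None = None
) -> tuple[CAMSet, dict]:
    """Replace a fraction of concept texts by typos or dictionary synonyms.

    Each non-predefined concept is independently typo'd with probability
    ``cfg.p_typo`` (the variant is at OSA distance exactly 1 from its base)
    or replaced by a synonym with probability ``cfg.p_synonym``.  Returns the
    noisy set plus the planted record: ``typo_pairs`` / ``synonym_pairs`` as
    (base, variant) lists and the full variant -> base grouping.
    """
    record: dict = {"typo_pairs": [], "synonym_pairs": [], "groups": {}}
    syn = {k: list(v) for k, v in cfg.synonyms.items()}
    new_cams = []
    for idx, cam in enumerate(cams):
        rng = np.random.default_rng(
            [cfg.seed if noise_seed is None else noise_seed, 10_000 + idx]
        )
        new_concepts = []
        for c in cam.concepts:
            text = c.text
            if not c.predefined:
                u = rng.random()
                if u < cfg.p_typo:
                    variant = _make_typo(rng, text)
                    assert osa_distance(text, variant) == 1
                    record["typo_pairs"].append((text, variant))
                    record["groups"][variant] = text
                    text = variant
                elif u < cfg.p_typo + cfg.p_synonym and syn.get(text):
                    options = syn[text]
                    variant = options[int(rng.integers(0, len(options)))]
                    record["synonym_pairs"].append((text, variant))
                    record["groups"][variant] = text
                    text = variant
            new_concepts.append(replace(c, text=text) if text != c.text else c)
        new_cams.append(cam.with_concepts(new_concepts))
    return CAMSet(cams=new_cams, provenance=list(cams.provenance)), record


def simulate_rater_codings(
    texts: Sequence[str],
    planted_groups: Mapping[str, str],
    n_raters: int,
    noise_rate: float,
    seed: int,
    n_categories: int | None = None,
):
    """Simulated raters for reliability calibration.

    Each rater starts from the planted grouping (variant -> base category)
    and independently mislabels each item with probability ``noise_rate``
    into a uniformly random other category; raters use their own category
    name vocabularies.  At ``noise_rate`` 0 all raters share the planted
    partition; at 1 they are independent.
    """
    from .reliability import RaterCoding

    rng = np.random.default_rng(seed)
    base_of = {t: planted_groups.get(t, t) for t in texts}
    categories = sorted(set(base_of.values()))
    if n_categories is not None:
        categories = categories[:n_categories]
        base_of = {t: b if b in categories else categories[0] for t, b in base_of.items()}
    codings = []
    for r in range(n_raters):
        assignments = {}
        for t in texts:
            cat = base_of[t]
            if rng.random() < noise_rate:
                others = [c for c in categories if c != cat] or categories
                cat = others[int(rng.integers(0, len(others)))]
            assignments[t] = f"rater{r}:{cat}"  # private vocabulary
        codings.append(RaterCoding(f"rater{r}", assignments))
    return codings
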
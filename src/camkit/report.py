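"""Descriptive report of a CAM dataset, in APA-style markdown tables.

Every number in the bundle is recomputed from the inputs at build time --
nothing is cached -- and the markdown rendering is pure, so equal bundles
produce identical bytes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import AMBIVALENT, CAMSet
from .protocol import Protocol, protocol_stats
from .summarize import SummaryMap
from .wordlevel import word_list


def _m_sd(values: list[float]) -> tuple[float, float]:
    m = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else float("nan")
    return m, sd


@dataclass
class ReportBundle:
    n_cams: int
    concepts_mean: float
    concepts_sd: float
    connectors_mean: float
    connectors_sd: float
    share_positive: float
    share_negative: float
    share_neutral: float
    share_ambivalent: float
    n_categories: int
    coverage: float          # mapped concepts / total concepts
    top_categories: pd.DataFrame
    concept_stats: pd.DataFrame | None = None
    protocol_usage: pd.DataFrame | None = None


def build_report(
    cams: CAMSet,
    smap: SummaryMap | None = None,
    protocol: Protocol | None = None,
    include_concept_stats: bool = False,
) -> tuple[ReportBundle, str]:
    """Build the report bundle and its markdown rendering."""
    if len(cams) == 0:
        raise ValueError("need at least one CAM")
    c_counts = [float(cam.n_concepts) for cam in cams]
    e_counts = [float(cam.n_connectors) for cam in cams]
    cm, csd = _m_sd(c_counts)
    em, esd = _m_sd(e_counts)
    classes = {"positive": 0, "negative": 0, "neutral": 0, "ambivalent": 0}
    total = 0
    mapped = 0
    cat_counts: dict[str, int] = {}
    for _, c in cams.all_concepts():
        total += 1
        if c.valence == AMBIVALENT:
            classes["ambivalent"] += 1
        elif c.valence > 0:
            classes["positive"] += 1
        elif c.valence < 0:
            classes["negative"] += 1
        else:
            classes["neutral"] += 1
        if smap is not None:
            lookup = c.raw_text if c.raw_text is not None else c.text
            cat = smap.category_for(lookup)
            if cat is not None:
                mapped += 1
                cat_counts[cat] = cat_counts.get(cat, 0) + 1
    top = pd.DataFrame(
        sorted(cat_counts.items(), key=lambda kv: (-kv[1], kv[0]))[:10],
        columns=["category", "n"],
    )
    bundle = ReportBundle(
        n_cams=len(cams),
        concepts_mean=cm,
        concepts_sd=csd,
        connectors_mean=em,
        connectors_sd=esd,
        share_positive=classes["positive"] / total,
        share_negative=classes["negative"] / total,
        share_neutral=classes["neutral"] / total,
        share_ambivalent=classes["ambivalent"] / total,
        n_categories=len(cat_counts),
        coverage=(mapped / total) if smap is not None else 0.0,
        top_categories=top,
        concept_stats=word_list(cams, smap) if include_concept_stats else None,
        protocol_usage=protocol_stats(protocol) if protocol is not None else None,
    )
    return bundle, render_markdown(bundle)


def _fmt(x: float, digits: int = 2) -> str:
    return "--" if isinstance(x, float) and np.isnan(x) else f"{x:.{digits}f}"


def render_markdown(b: ReportBundle) -> str:
    """Markdown rendering with M / SD / N notation."""
    lines = [
        "# CAM dataset report",
        "",
        "## Dataset descriptives",
        "",
        "| Statistic | Value |",
        "| --- | --- |",
        f"| CAMs (N) | {b.n_cams} |",
        f"| Concepts per CAM | M = {_fmt(b.concepts_mean)}, SD = {_fmt(b.concepts_sd)} |",
        f"| Connectors per CAM | M = {_fmt(b.connectors_mean)}, SD = {_fmt(b.connectors_sd)} |",
        f"| Share positive | {_fmt(100 * b.share_positive, 1)}% |",
        f"| Share negative | {_fmt(100 * b.share_negative, 1)}% |",
        f"| Share neutral | {_fmt(100 * b.share_neutral, 1)}% |",
        f"| Share ambivalent | {_fmt(100 * b.share_ambivalent, 1)}% |",
        "",
        "## Summarization",
        "",
        f"Categories in use: {b.n_categories}; "
        f"coverage: {_fmt(100 * b.coverage, 1)}% of concepts mapped.",
    ]
    if len(b.top_categories):
        lines += ["", "| Category | n |", "| --- | --- |"]
        lines += [
            f"| {r.category} | {int(r.n)} |" for r in b.top_categories.itertuples()
        ]
    if b.concept_stats is not None:
        lines += [
            "",
            "## Concept statistics",
            "",
            "| Text | N | M valence | SD valence | M degree | SD degree |",
            "| --- | --- | --- | --- | --- | --- |",
        ]
        lines += [
            f"| {r.text} | {int(r.n_total)} | {_fmt(r.mean_valence)} | "
            f"{_fmt(r.sd_valence)} | {_fmt(r.mean_degree)} | {_fmt(r.sd_degree)} |"
            for r in b.concept_stats.itertuples()
        ]
    if b.protocol_usage is not None and len(b.protocol_usage):
        lines += ["", "## Protocol usage", "", "| Operation | Count |", "| --- | --- |"]
        lines += [
            f"| {r.operation} | {int(r.count)} |" for r in b.protocol_usage.itertuples()
        ]
    return "\n".join(lines) + "\n"
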
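"""Word-level outputs: the word list with valence/degree statistics, per-CAM
frequency tables split by valence class, and per-category composition
summaries of the summarization.

Standard deviations use the sample (n-1) denominator and are NaN-flagged for
single observations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import AMBIVALENT, CAMSet
from .indicators import numeric_valence
from .summarize import SummaryMap, normalize_text, summarized_text, valence_class


def _sd(values: list[float]) -> float:
    return float(np.std(values, ddof=1)) if len(values) > 1 else float("nan")


def word_list(
    cams: CAMSet,
    smap: SummaryMap | None = None,
    split_by_valence: bool = False,
) -> pd.DataFrame:
    """One row per unique concept text with pooled statistics.

    Columns: text, n_total, mean_valence, sd_valence, mean_degree, sd_degree.
    With ``smap`` the summarized labels are tallied instead of raw texts, and
    ``split_by_valence`` appends the valence class to mapped labels
    (e.g. ``Cost_positive`` vs ``Cost_negative``).  Sorted by n_total
    descending, then text ascending.
    """
    buckets: dict[str, dict[str, list[float]]] = {}
    for cam in cams:
        g = cam.graph()
        for c in cam.concepts:
            if smap is None:
                key = normalize_text(c.raw_text if c.raw_text is not None else c.text)
            else:
                eff = SummaryMap(smap.entries, split_by_valence)
                lookup = c.raw_text if c.raw_text is not None else c.text
                cat = eff.category_for(lookup)
                if cat is None:
                    key = normalize_text(lookup)
                else:
                    key = f"{cat}_{valence_class(c.valence)}" if split_by_valence else cat
            b = buckets.setdefault(key, {"valence": [], "degree": []})
            b["valence"].append(numeric_valence(c))
            b["degree"].append(float(g.degree(c.id)))
    rows = [
        {
            "text": text,
            "n_total": len(b["valence"]),
            "mean_valence": float(np.mean(b["valence"])),
            "sd_valence": _sd(b["valence"]),
            "mean_degree": float(np.mean(b["degree"])),
            "sd_degree": _sd(b["degree"]),
        }
        for text, b in buckets.items()
    ]
    df = pd.DataFrame(
        rows, columns=["text", "n_total", "mean_valence", "sd_valence", "mean_degree", "sd_degree"]
    )
    return df.sort_values(["n_total", "text"], ascending=[False, True], ignore_index=True)


def per_cam_frequencies(cams: CAMSet) -> pd.DataFrame:
    """CAM x concept frequency table split by valence class.

    For every CAM and unique concept text: N (total), N_positive, N_negative,
    N_neutral, N_ambivalent; N is always the sum of the four classes.  Texts
    absent from a CAM get all-zero counts, so the table is a dense matrix in
    long format (cam_id, text, N, ...).
    """
    texts = sorted({normalize_text(c.text) for _, c in cams.all_concepts()})
    rows = []
    for cam in cams:
        counts = {t: {"N": 0, "positive": 0, "negative": 0, "neutral": 0, "ambivalent": 0} for t in texts}
        for c in cam.concepts:
            t = normalize_text(c.text)
            counts[t]["N"] += 1
            counts[t][valence_class(c.valence)] += 1
        for t in texts:
            rows.append(
                {
                    "cam_id": cam.cam_id,
                    "text": t,
                    "N": counts[t]["N"],
                    "N_positive": counts[t]["positive"],
                    "N_negative": counts[t]["negative"],
                    "N_neutral": counts[t]["neutral"],
                    "N_ambivalent": counts[t]["ambivalent"],
                }
            )
    return pd.DataFrame(
        rows,
        columns=["cam_id", "text", "N", "N_positive", "N_negative", "N_neutral", "N_ambivalent"],
    )


def category_composition(cams: CAMSet, smap: SummaryMap) -> pd.DataFrame:
    """Per-category breakdown of which raw texts it absorbed.

    Columns: category, raw_text, count, share (of the category's total) --
    the table behind per-category pie charts / barplots.
    """
    if not smap.entries:
        raise ValueError("summary map is empty")
    tallies: dict[str, dict[str, int]] = {}
    for _, c in cams.all_concepts():
        raw = normalize_text(c.raw_text if c.raw_text is not None else c.text)
        cat = smap.entries.get(raw)
        if cat is not None:
            tallies.setdefault(cat, {})[raw] = tallies.setdefault(cat, {}).get(raw, 0) + 1
    rows = []
    for cat in sorted(tallies):
        total = sum(tallies[cat].values())
        for raw, n in sorted(tallies[cat].items(), key=lambda kv: (-kv[1], kv[0])):
            rows.append({"category": cat, "raw_text": raw, "count": n, "share": n / total})
    return pd.DataFrame(rows, columns=["category", "raw_text", "count", "share"])
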
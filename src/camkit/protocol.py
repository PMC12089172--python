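"""Tamper-evident, replayable protocol of analysis steps.

Summarizing qualitative CAM data involves researcher decisions; the protocol
makes them transparent and *verifiable*.  Every recorded operation appends
one JSON line holding the operation name, a full parameter snapshot (seeds
included), content digests of its inputs and outputs, and a rolling hash
chaining the entry to its predecessor.  Editing any earlier entry breaks the
chain; replaying the protocol against the raw inputs re-executes every step
and compares output digests, turning inspection into verification.

Timestamps are recorded but excluded from all digests, so replay verdicts
ignore wall-clock time.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import CAM, CAMSet, write_cam


class ProtocolError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# content digests


def digest(obj) -> str:
    """Stable content hash of the objects the toolkit passes between steps."""
    h = hashlib.sha256()
    h.update(_canonical_bytes(obj))
    return h.hexdigest()


def _canonical_bytes(obj) -> bytes:
    if isinstance(obj, CAM):
        return write_cam(obj).encode()
    if isinstance(obj, CAMSet):
        return b"\x00".join(write_cam(c).encode() for c in obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_csv(index=True, float_format="%.12g").encode()
    if isinstance(obj, pd.Series):
        return obj.to_csv(float_format="%.12g").encode()
    if isinstance(obj, np.ndarray):
        return np.ascontiguousarray(obj).tobytes() + str(obj.shape).encode()
    if isinstance(obj, (bytes, bytearray)):
        return bytes(obj)
    if isinstance(obj, str):
        return obj.encode()
    try:
        return json.dumps(obj, sort_keys=True, default=_json_fallback).encode()
    except TypeError:
        return repr(obj).encode()


def _json_fallback(obj):
    if hasattr(obj, "__dict__"):
        return {"__class__": type(obj).__name__, **vars(obj)}
    if isinstance(obj, (set, frozenset)):
        return sorted(map(str, obj))
    return str(obj)


def _entry_hash(prev_hash: str, entry: Mapping) -> str:
    core = {k: v for k, v in entry.items() if k not in ("timestamp", "hash")}
    h = hashlib.sha256()
    h.update(prev_hash.encode())
    h.update(json.dumps(core, sort_keys=True).encode())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# operation registry (used by replay)

REGISTRY: dict[str, Callable] = {}


def register(name: str):
    """Register a callable under a stable operation name for replay."""

    def deco(fn: Callable) -> Callable:
        REGISTRY[name] = fn
        return fn

    return deco


def _builtin_registry() -> None:
    # Imported lazily to avoid cycles; names are the public operation names.
    from .aggregate import aggregate as _aggregate
    from .indicators import indicators_for_set as _indicators_for_set
    from .summarize import SummaryMap, apply_summary as _apply_summary
    from .synth import GenConfig, generate_cam_set as _generate_cam_set
    from .wordlevel import word_list as _word_list

    REGISTRY.setdefault(
        "synth.generate_cam_set",
        lambda *, cfg: _generate_cam_set(GenConfig(**_revive_gen_cfg(cfg)))[0],
    )
    REGISTRY.setdefault(
        "summarize.apply_summary",
        lambda cams, *, entries, split_by_valence=False: _apply_summary(
            cams, SummaryMap(entries=entries, split_by_valence=split_by_valence)
        ),
    )
    REGISTRY.setdefault(
        "indicators.indicators_for_set",
        lambda cams, *, levels=("macro",), focus=(): _indicators_for_set(
            cams, levels=tuple(levels), focus=tuple(focus)
        ),
    )
    REGISTRY.setdefault("aggregate.aggregate", lambda cams: _aggregate(cams).nodes)
    REGISTRY.setdefault("wordlevel.word_list", _word_list)


def _revive_gen_cfg(cfg: Mapping) -> dict:
    """JSON round trips turn tuples into lists; restore tuple-typed fields."""
    out = dict(cfg)
    for key in ("n_concepts", "group_means", "vocabulary"):
        if out.get(key) is not None:
            out[key] = tuple(out[key])
    return out


_builtin_registry()


# ---------------------------------------------------------------------------
# protocol sessions


@dataclass
class Protocol:
    """An append-only list of protocol entries with a rolling hash chain."""

    entries: list[dict] = field(default_factory=list)
    path: str | None = None

    @property
    def head_hash(self) -> str:
        return self.entries[-1]["hash"] if self.entries else ""

    def append(self, entry: dict) -> dict:
        entry = dict(entry)
        entry["seq"] = len(self.entries) + 1
        entry["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        entry["hash"] = _entry_hash(self.head_hash, entry)
        self.entries.append(entry)
        if self.path:
            with open(self.path, "a", encoding="utf-8") as fh:
                fh.write(json.dumps(entry, sort_keys=True) + "\n")
                fh.flush()
        return entry

    def verify_chain(self) -> None:
        """Raise if any entry's hash does not match the chained recomputation."""
        prev = ""
        for i, e in enumerate(self.entries):
            expect = _entry_hash(prev, e)
            if e.get("hash") != expect:
                raise ProtocolError(f"hash chain broken at entry {i + 1} ({e.get('op')!r})")
            prev = e["hash"]

    @classmethod
    def load(cls, path) -> "Protocol":
        entries = []
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    entries.append(json.loads(line))
        return cls(entries=entries, path=None)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for e in self.entries:
                fh.write(json.dumps(e, sort_keys=True) + "\n")


class Session:
    """Executes operations over a named object namespace, recording each one.

    >>> s = Session()
    >>> s.put("raw", cam_set)                       # doctest: +SKIP
    >>> s.run("summarize.apply_summary", inputs=["raw"], outputs=["summarized"],
    ...       params={"entries": {...}, "split_by_valence": False})  # doctest: +SKIP
    """

    def __init__(self, protocol: Protocol | None = None):
        self.protocol = protocol or Protocol()
        self.namespace: dict[str, object] = {}

    def put(self, name: str, obj) -> None:
        self.namespace[name] = obj

    def get(self, name: str):
        return self.namespace[name]

    def run(
        self,
        op: str,
        inputs: Sequence[str] = (),
        outputs: Sequence[str] = (),
        params: Mapping | None = None,
    ):
        """Execute a registered operation and append its protocol entry."""
        if op not in REGISTRY:
            raise ProtocolError(f"operation {op!r} not registered")
        params = dict(params or {})
        in_objs = [self.namespace[n] for n in inputs]
        result = REGISTRY[op](*in_objs, **params)
        out_objs = [result] if len(outputs) == 1 else list(result)
        for name, obj in zip(outputs, out_objs):
            self.namespace[name] = obj
        self.protocol.append(
            {
                "op": op,
                "params": json.loads(json.dumps(params, sort_keys=True, default=_json_fallback)),
                "inputs": {n: digest(o) for n, o in zip(inputs, in_objs)},
                "outputs": {n: digest(o) for n, o in zip(outputs, out_objs)},
            }
        )
        return result


@dataclass
class ReplayReport:
    verdict: str                  # "PASS" | "FAIL"
    first_divergence: int | None  # 1-based entry number, None when PASS
    details: list[str] = field(default_factory=list)


def replay(protocol: Protocol, raw_inputs: Mapping[str, object]) -> ReplayReport:
    """Re-execute a protocol from raw inputs and verify every digest.

    ``raw_inputs`` must provide (by name) every object a recorded step
    consumes that no earlier step produced; their digests are checked against
    the recorded input digests.  The verdict is PASS iff the hash chain is
    intact and every recomputed output digest matches the record; otherwise
    the first diverging step is named.
    """
    protocol.verify_chain()
    ns: dict[str, object] = dict(raw_inputs)
    details: list[str] = []
    for e in protocol.entries:
        seq = e["seq"]
        for name, recorded in e["inputs"].items():
            if name not in ns:
                return ReplayReport("FAIL", seq, [f"step {seq}: missing input {name!r}"])
            actual = digest(ns[name])
            if actual != recorded:
                return ReplayReport(
                    "FAIL", seq,
                    [f"step {seq} ({e['op']}): input {name!r} digest mismatch"],
                )
        fn = REGISTRY.get(e["op"])
        if fn is None:
            return ReplayReport("FAIL", seq, [f"step {seq}: unknown operation {e['op']!r}"])
        in_objs = [ns[n] for n in e["inputs"]]
        result = fn(*in_objs, **_revive_params(e["params"]))
        out_names = list(e["outputs"])
        out_objs = [result] if len(out_names) == 1 else list(result)
        for name, obj in zip(out_names, out_objs):
            ns[name] = obj
            actual = digest(obj)
            if actual != e["outputs"][name]:
                return ReplayReport(
                    "FAIL", seq,
                    [f"step {seq} ({e['op']}): output {name!r} digest mismatch"],
                )
        details.append(f"step {seq} ({e['op']}): ok")
    return ReplayReport("PASS", None, details)


def _revive_params(params: Mapping) -> dict:
    return {str(k): v for k, v in params.items()}


def protocol_stats(protocol: Protocol) -> pd.DataFrame:
    """Usage counts per operation -- which functionalities were applied."""
    counts: dict[str, int] = {}
    for e in protocol.entries:
        counts[e["op"]] = counts.get(e["op"], 0) + 1
    rows = [{"operation": op, "count": n} for op, n in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["operation", "count"])
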
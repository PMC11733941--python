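"""Frequency tables over edge-type binary sequences.

Tables are trained from solved instances: for every pruning edge of every
solution, the relevant-window sequence is extracted and tallied under the
edge-type label.  Within a type, sequences are ranked by descending count
with lexicographic tie-breaks (0 < 1), which makes training reproducible.
The accumulated-probability curve of a type maps the k-th ranked sequence
to the normalized index k/K; a peaked empirical law shows up as a curve
that majorizes the uniform diagonal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .encoding import BitString, edge_sequence


class DataError(ValueError):
    """Inconsistent training data (e.g. mixed sequence lengths)."""


def parse_label(type_label: str) -> Tuple[str, int, str]:
    """Split ``KINDi-L-KINDj`` into (kind_i, span, kind_j)."""
    try:
        kind_i, span, kind_j = type_label.split("-")
        return kind_i, int(span), kind_j
    except ValueError as exc:
        raise ValueError(f"bad edge-type label {type_label!r}") from exc


def sequence_length(type_label: str) -> int:
    """Relevant-bit count of an edge type: span - 3 window positions."""
    _, span, _ = parse_label(type_label)
    length = span - 3
    if length < 1:
        raise ValueError(f"edge type {type_label!r} has no relevant bits")
    return length


def kmax(type_label: str) -> int:
    """Mathematically possible distinct sequences for an edge type.

    One bit of every independent-edge sequence is non-free (equivalently:
    feasible sequences come in complete-flip pairs, or one window position
    is pinned by a repeat), so the count is 2^(L-1) for window length L.
    """
    return 2 ** (sequence_length(type_label) - 1)


def raw_count(type_label: str) -> int:
    """Unconstrained sequence count 2^L for window length L."""
    return 2 ** sequence_length(type_label)


@dataclass
class FrequencyTable:
    """Per-edge-type ranked sequences with counts and probabilities."""

    entries: Dict[str, List[Tuple[str, int, float]]] = field(
        default_factory=dict)
    meta: Dict[str, object] = field(default_factory=dict)

    def types(self) -> List[str]:
        return sorted(self.entries)

    def sequences(self, type_label: str) -> List[str]:
        """Ranked sequence strings for a type ([] when unseen)."""
        return [seq for seq, _, _ in self.entries.get(type_label, [])]

    def probabilities(self, type_label: str) -> Dict[str, float]:
        if type_label not in self.entries:
            raise KeyError(f"edge type {type_label!r} not in table")
        return {seq: p for seq, _, p in self.entries[type_label]}

    def to_csv(self, path) -> None:
        rows = []
        for label in self.types():
            for rank, (seq, count, prob) in enumerate(self.entries[label],
                                                      start=1):
                rows.append({"edge_type": label, "sequence": seq,
                             "count": count, "probability": prob,
                             "rank": rank})
        df = pd.DataFrame(rows,
                          columns=["edge_type", "sequence", "count",
                                   "probability", "rank"])
        with open(path, "w") as fh:
            for key, val in sorted(self.meta.items()):
                fh.write(f"#{key}={val}\n")
            df.to_csv(fh, index=False)

    @staticmethod
    def from_csv(path) -> "FrequencyTable":
        meta: Dict[str, object] = {}
        with open(path) as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if not line.startswith("#"):
                    fh.seek(pos)
                    break
                key, val = line[1:].rstrip("\n").split("=", 1)
                meta[key] = val
                pos = fh.tell()
            df = pd.read_csv(fh, dtype={"sequence": str})
        table = FrequencyTable(meta=meta)
        for label, group in df.groupby("edge_type"):
            group = group.sort_values("rank")
            table.entries[str(label)] = [
                (str(r.sequence), int(r.count), float(r.probability))
                for r in group.itertuples()]
        return table


def split(items: Sequence, ratio: float = 0.8,
          seed: int = 0) -> Tuple[list, list]:
    """Deterministic shuffled split into ceil(ratio*N) / remainder."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    items = list(items)
    if not items:
        raise ValueError("cannot split an empty collection")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(items))
    n_train = math.ceil(ratio * len(items))
    train = [items[k] for k in idx[:n_train]]
    test = [items[k] for k in idx[n_train:]]
    return train, test


def build_table(solutions: Iterable[Tuple[BitString, Sequence]],
                meta: Dict[str, object] | None = None) -> FrequencyTable:
    """Tally relevant-window sequences of solved instances per edge type.

    ``solutions`` yields pairs of a normalized global bit string and the
    pruning edges of its instance (objects with ``i``, ``j`` and
    ``type_label`` attributes).
    """
    counts: Dict[str, Dict[str, int]] = {}
    lengths: Dict[str, int] = {}
    for bits, edges in solutions:
        for e in edges:
            seq = edge_sequence(bits, e.i, e.j).as_str()
            label = e.type_label
            if label in lengths and lengths[label] != len(seq):
                raise DataError(
                    f"inconsistent sequence length for type {label!r}")
            lengths[label] = len(seq)
            counts.setdefault(label, {})[seq] = (
                counts.get(label, {}).get(seq, 0) + 1)
    table = FrequencyTable(meta=dict(meta or {}))
    for label, tally in counts.items():
        total = sum(tally.values())
        ranked = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
        table.entries[label] = [(seq, c, c / total) for seq, c in ranked]
    return table


def accumulated_curve(table: FrequencyTable, type_label: str
                      ) -> List[Tuple[float, float]]:
    """(k/K, cumulative probability) for the ranked sequences of a type."""
    if type_label not in table.entries:
        raise KeyError(f"edge type {type_label!r} not in table")
    entries = table.entries[type_label]
    K = len(entries)
    out = []
    cum = 0.0
    for k, (_, _, p) in enumerate(entries, start=1):
        cum += p
        out.append((k / K, cum))
    return out


def curve_csv(table: FrequencyTable, path) -> None:
    rows = []
    for label in table.types():
        for idx, cum in accumulated_curve(table, label):
            rows.append({"edge_type": label, "index": idx,
                         "cumulative_probability": cum})
    pd.DataFrame(rows).to_csv(path, index=False)
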
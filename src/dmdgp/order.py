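"""The DMDGP vertex order for Pro/Gly-free protein backbones.

The order interleaves the five backbone atoms (N, CA, C, H, HA) so that
every vertex from position 4 onward has its three immediate predecessors at
rigid-geometry or NMR-detectable distances.  Residue 1 contributes
(N, HA, C, CA); every later residue contributes (H, N, CA, HA, C), and each
intermediary residue additionally repeats its CA immediately after its C —
the repetition keeps the three-predecessor (H2) hypothesis intact across
the peptide bond.  Total length: 6 n - 3 vertices for n residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import pandas as pd

ATOM_KINDS = ("N", "CA", "C", "H", "HA")


@dataclass(frozen=True)
class OrderedVertex:
    """One slot of the order: a backbone atom with its reference positions."""

    position: int          # 1-based index in the order
    kind: str              # one of ATOM_KINDS
    residue: int           # 1-based residue index
    is_repeat: bool = False
    refs: Optional[Tuple[int, int, int]] = None  # (pos-1, pos-2, pos-3)

    def __post_init__(self) -> None:
        if self.kind not in ATOM_KINDS:
            raise ValueError(f"unknown atom kind {self.kind!r}")
        if self.is_repeat and self.kind != "CA":
            raise ValueError("only CA vertices may repeat")


@dataclass(frozen=True)
class BackboneOrder:
    vertices: Tuple[OrderedVertex, ...]
    n_residues: int
    _index: Dict[Tuple[str, int, bool], int] = field(
        default=None, repr=False, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        idx = {(v.kind, v.residue, v.is_repeat): v.position
               for v in self.vertices}
        object.__setattr__(self, "_index", idx)

    def __len__(self) -> int:
        return len(self.vertices)

    def __getitem__(self, position: int) -> OrderedVertex:
        """Vertex at 1-based ``position``."""
        if not 1 <= position <= len(self.vertices):
            raise IndexError(f"position {position} out of range")
        return self.vertices[position - 1]

    def position_of(self, kind: str, residue: int,
                    repeat: bool = False) -> int:
        """1-based position of an atom's (first or repeated) occurrence."""
        try:
            return self._index[(kind, residue, repeat)]
        except KeyError:
            raise KeyError(f"no vertex {kind}^{residue} (repeat={repeat})")

    @property
    def repeat_positions(self) -> Tuple[int, ...]:
        return tuple(v.position for v in self.vertices if v.is_repeat)

    def to_tsv(self, path) -> None:
        """Export: position, atom kind, residue, is_repeat, ref positions."""
        rows = []
        for v in self.vertices:
            r = v.refs or (None, None, None)
            rows.append({"position": v.position, "kind": v.kind,
                         "residue": v.residue, "is_repeat": int(v.is_repeat),
                         "ref1": r[0], "ref2": r[1], "ref3": r[2]})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def build_order(n_residues: int) -> BackboneOrder:
    """Build the backbone order for ``n_residues`` >= 2 residues.

    Positions 1-4 are (N1, HA1, C1, CA1); residue i >= 2 contributes
    (Hi, Ni, CAi, HAi, Ci) and, for intermediary residues (2 <= i <= n-1),
    a repeated CAi directly after Ci.  Every vertex at position t >= 4
    references positions (t-1, t-2, t-3).
    """
    if n_residues < 2:
        raise ValueError("n_residues must be >= 2")

    spec: List[Tuple[str, int, bool]] = [
        ("N", 1, False), ("HA", 1, False), ("C", 1, False), ("CA", 1, False),
    ]
    for i in range(2, n_residues + 1):
        spec += [("H", i, False), ("N", i, False), ("CA", i, False),
                 ("HA", i, False), ("C", i, False)]
        if i <= n_residues - 1:
            spec.append(("CA", i, True))

    vertices = []
    for pos, (kind, res, rep) in enumerate(spec, start=1):
        refs = (pos - 1, pos - 2, pos - 3) if pos >= 4 else None
        vertices.append(OrderedVertex(pos, kind, res, rep, refs))
    return BackboneOrder(tuple(vertices), n_residues)


def classify_edge(order: BackboneOrder, i: int, j: int) -> str:
    """Edge-type label ``KINDi-L-KINDj`` with L = j - i + 1 vertices spanned.

    The label groups pruning edges by their endpoint atoms and segment
    length, e.g. the restraint between HA of residue 1 and H of residue 3
    in a 3-residue order is ``HA-10-H``.
    """
    if not (1 <= i < j <= len(order)):
        raise ValueError(f"invalid edge positions ({i}, {j})")
    return f"{order[i].kind}-{j - i + 1}-{order[j].kind}"


def relevant_positions(i: int, j: int) -> Tuple[int, ...]:
    """Bit positions i+3..j — the only bits that move |x_i - x_j|."""
    if j < i + 3:
        raise ValueError(f"edge ({i}, {j}) has no searchable bits")
    return tuple(range(i + 3, j + 1))
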
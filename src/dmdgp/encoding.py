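"""Binary representation of backbone conformations.

Each vertex from position 4 onward contributes one orientation bit: on
which side of the plane of its three immediate predecessors (taken in the
order t-1, t-2, t-3) the atom lies.  The first three bits are 0 by
convention.  Position 4 is a pure mirror symmetry — both branches are
always feasible — so strings are normalized by flipping everything from
position 4 onward whenever b4 = 1; repeated-CA and degenerate
(single-intersection) positions carry a fixed bit 0 and are exempt from
every flip.  Dropping the four leading fixed bits of a normalized string
gives the reduced representation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, List, Sequence, Tuple

from . import geometry
from .geometry import Point3
from .model import Conformation, DMDGPInstance
from .order import relevant_positions
from .synthetic import TRILAT_TOL


class ContractError(ValueError):
    """Operation applied to a bit string in the wrong state."""


class InfeasibleInstanceError(ValueError):
    """Decoding hit an empty sphere intersection."""


@dataclass(frozen=True)
class BitString:
    """A run of orientation bits starting at ``offset`` in the order.

    ``fixed`` holds the (absolute) positions whose bits are not free —
    repeated vertices and degenerate placements — and are therefore
    excluded from all flips.
    """

    bits: Tuple[int, ...]
    offset: int = 1
    fixed: FrozenSet[int] = frozenset()

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("bits must be 0/1")
        if self.offset < 1:
            raise ValueError("offset must be >= 1")

    def __len__(self) -> int:
        return len(self.bits)

    @property
    def positions(self) -> range:
        return range(self.offset, self.offset + len(self.bits))

    def bit(self, position: int) -> int:
        if position not in self.positions:
            raise IndexError(f"position {position} outside bit string")
        return self.bits[position - self.offset]

    def as_str(self) -> str:
        return "".join(str(b) for b in self.bits)

    def flip_from(self, position: int) -> "BitString":
        """Invert every non-fixed bit at ``position`` and beyond."""
        new = tuple(
            b if (pos < position or pos in self.fixed) else 1 - b
            for pos, b in zip(self.positions, self.bits))
        return BitString(new, self.offset, self.fixed)

    def restrict(self, positions: Sequence[int]) -> "BitString":
        """Contiguous restriction to ``positions`` (new offset = first)."""
        pos = list(positions)
        if pos != list(range(pos[0], pos[-1] + 1)):
            raise ValueError("restriction must be contiguous")
        return BitString(tuple(self.bit(p) for p in pos), pos[0],
                         frozenset(p for p in self.fixed
                                   if pos[0] <= p <= pos[-1]))

    def to_text(self) -> str:
        """ASCII serialization: header with length/offset/fixed, then bits."""
        fixed = ",".join(str(p) for p in sorted(self.fixed))
        return (f"#length={len(self.bits)} offset={self.offset} "
                f"fixed={fixed}\n{self.as_str()}\n")

    @staticmethod
    def from_text(text: str) -> "BitString":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if len(lines) != 2 or not lines[0].startswith("#"):
            raise ValueError("expected a header line and a bit line")
        meta = dict(kv.split("=", 1)
                    for kv in lines[0].lstrip("#").split())
        fixed = frozenset(int(p) for p in meta["fixed"].split(",")
                          if p) if meta.get("fixed") else frozenset()
        return BitString(tuple(int(c) for c in lines[1]),
                         int(meta["offset"]), fixed)


def _ref(coords: Sequence[Point3], t: int) -> Tuple[Point3, Point3, Point3]:
    # predecessors in order (t-1, t-2, t-3): the convention shared with
    # trilateration's "positive point first" return order
    return coords[t - 2], coords[t - 3], coords[t - 4]


def encode(conf: Conformation, tol: float = geometry.ON_PLANE_TOL
           ) -> BitString:
    """Normalized global bit string of a conformation.

    Repeated vertices and on-plane (degenerate) placements record bit 0 and
    are marked fixed.  Raises a degenerate-reference error naming the
    position if some predecessor triple is collinear.
    """
    order = conf.order
    bits: List[int] = [0, 0, 0]
    fixed = {1, 2, 3}
    for t in range(4, len(order) + 1):
        if order[t].is_repeat:
            bits.append(0)
            fixed.add(t)
            continue
        try:
            b = geometry.orientation_bit(_ref(conf.coords, t),
                                         conf.coords[t - 1], tol)
        except geometry.DegenerateReferenceError as exc:
            raise geometry.DegenerateReferenceError(
                f"collinear references at position {t}") from exc
        if b == 0 and abs(geometry.signed_volume(
                _ref(conf.coords, t), conf.coords[t - 1])) <= tol:
            fixed.add(t)
        bits.append(b)
    return normalize(BitString(tuple(bits), 1, frozenset(fixed)))


def normalize(b: BitString) -> BitString:
    """Flip bits 4..end (sparing fixed positions) whenever b4 = 1."""
    if b.offset != 1:
        raise ContractError("normalize applies to global strings")
    if len(b) >= 4 and b.bit(4) == 1:
        return b.flip_from(4)
    return b


def reduce(b: BitString) -> BitString:
    """Drop the four leading fixed bits of a normalized global string."""
    if b.offset != 1 or len(b) < 4:
        raise ContractError("reduce applies to global strings")
    if b.bits[:3] != (0, 0, 0) or b.bit(4) != 0:
        raise ContractError("reduce requires a normalized string")
    return BitString(b.bits[4:], 5,
                     frozenset(p for p in b.fixed if p >= 5))


def decode(b: BitString, instance: DMDGPInstance,
           tol: float = 1e-6) -> Conformation:
    """Rebuild canonical-frame coordinates from a global bit string.

    Repeated vertices copy their first occurrence; degenerate positions
    take the unique in-plane point regardless of the stored bit; free
    positions take the intersection point whose orientation bit matches.
    """
    if b.offset != 1 or len(b) != len(instance.order):
        raise ContractError("decode requires a full-length global string")
    order = instance.order
    coords: List[Point3] = list(geometry.place_first_three(
        instance.distance(1, 2), instance.distance(1, 3),
        instance.distance(2, 3)))
    first_ca = {order[t].residue: t for t in range(1, len(order) + 1)
                if order[t].kind == "CA" and not order[t].is_repeat}
    for t in range(4, len(order) + 1):
        v = order[t]
        if v.is_repeat:
            coords.append(coords[first_ca[v.residue] - 1])
            continue
        pts = geometry.trilaterate(
            coords[t - 2], coords[t - 3], coords[t - 4],
            instance.distance(t - 1, t), instance.distance(t - 2, t),
            instance.distance(t - 3, t), tol=TRILAT_TOL)
        if not pts:
            raise InfeasibleInstanceError(
                f"empty sphere intersection at position {t}")
        if len(pts) == 1:
            coords.append(pts[0])
        else:
            coords.append(pts[0] if b.bit(t) == 1 else pts[1])
    conf = Conformation(order, tuple(coords))
    for t in range(4, len(order) + 1):
        for back in (1, 2, 3):
            if abs(conf.distance(t - back, t)
                   - instance.distance(t - back, t)) > tol:
                raise InfeasibleInstanceError(
                    f"discretization restraint ({t - back}, {t}) violated")
    return conf


def edge_sequence(b: BitString, i: int, j: int) -> BitString:
    """Restriction of a global string to the relevant window of edge (i, j)."""
    if b.offset != 1:
        raise ContractError("edge_sequence applies to global strings")
    return b.restrict(relevant_positions(i, j))


def to_canonical_frame(conf: Conformation) -> Conformation:
    """Rigidly move a conformation so its first three atoms sit canonically.

    The transform is re-derived from the first three atoms (no fitting):
    x1 maps to the origin, x2 to the negative x-axis, x3 into the y > 0
    half of the xy-plane.  Proper rotation only, so chirality — and hence
    the bit string — is preserved.
    """
    x1, x2, x3 = conf.coords[0], conf.coords[1], conf.coords[2]
    u = geometry._sub(x2, x1)
    r1 = geometry._unit((-u[0], -u[1], -u[2]))
    v = geometry._sub(x3, x1)
    proj = geometry._dot(v, r1)
    w = (v[0] - proj * r1[0], v[1] - proj * r1[1], v[2] - proj * r1[2])
    r2 = geometry._unit(w)
    r3 = geometry._cross(r1, r2)
    new = []
    for p in conf.coords:
        q = geometry._sub(p, x1)
        new.append((geometry._dot(q, r1), geometry._dot(q, r2),
                    geometry._dot(q, r3)))
    return Conformation(conf.order, tuple(new))
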
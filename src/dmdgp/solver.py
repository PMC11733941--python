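"""SBBU-style solving of DMDGP instances.

Pruning edges are ordered (ascending by j, then i) and grouped into
constraint components: edges sharing relevant bit positions are *coupled*
and live in one component; a singleton component is an *independent*
constraint.  The first edge of a component is searched exhaustively over
its free relevant bits — left-first depth-first (DFS) or in descending
empirical-frequency order (FBS) — and each later edge is solved by
extending the component's partial assignment, falling back on its complete
flip (the only other viable sequence, by the DMDGP symmetry).

Node accounting follows the two conventions of the underlying search
costs: FBS charges every tested root-leaf path in full, ``rank x window
length``; DFS counts unique expanded tree nodes (one shared root plus one
level per free bit, shared prefixes counted once).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Dict, FrozenSet, Iterable, List, Optional, Tuple

from . import geometry
from .encoding import BitString, normalize
from .model import Conformation, DMDGPInstance
from .order import classify_edge, relevant_positions
from .synthetic import TRILAT_TOL

DEFAULT_TOL = 1e-6


class InfeasibleEdgeError(ValueError):
    """No bit sequence satisfies a pruning edge.

    ``nodes`` carries the accounting cost of the exhausted search so that
    callers retrying under a symmetry flip can keep honest totals.
    """

    def __init__(self, message: str, nodes: int = 0) -> None:
        super().__init__(message)
        self.nodes = nodes


@dataclass(frozen=True)
class PruningEdge:
    i: int
    j: int
    value: float
    relevant: Tuple[int, ...]
    type_label: str

    @property
    def window_length(self) -> int:
        return len(self.relevant)


@dataclass(frozen=True)
class ConstraintComponent:
    edges: Tuple[PruningEdge, ...]
    bit_support: FrozenSet[int]

    @property
    def independent(self) -> bool:
        return len(self.edges) == 1


@dataclass
class SolveStats:
    strategy: str
    per_edge: List[dict] = field(default_factory=list)

    def add(self, edge: PruningEdge, nodes: int) -> None:
        self.per_edge.append({"i": edge.i, "j": edge.j,
                              "type": edge.type_label, "nodes": nodes})

    @property
    def per_type(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for row in self.per_edge:
            out[row["type"]] = out.get(row["type"], 0) + row["nodes"]
        return out

    @property
    def total_nodes(self) -> int:
        return sum(row["nodes"] for row in self.per_edge)

    def to_json(self) -> str:
        return json.dumps({"strategy": self.strategy,
                           "per_edge": self.per_edge,
                           "per_type": self.per_type,
                           "total_nodes": self.total_nodes}, indent=2)


@dataclass(frozen=True)
class Solution:
    conformation: Conformation
    bits: BitString


def pruning_edges(instance: DMDGPInstance) -> List[PruningEdge]:
    """Instance pruning edges in processing order (ascending j, then i)."""
    edges = []
    for r in instance.pruning_restraints:
        edges.append(PruningEdge(r.i, r.j, r.value,
                                 relevant_positions(r.i, r.j),
                                 classify_edge(instance.order, r.i, r.j)))
    return sorted(edges, key=lambda e: (e.j, e.i))


def decompose(edges: Iterable[PruningEdge]) -> List[ConstraintComponent]:
    """Connected components of the share-a-relevant-bit graph.

    Edges keep the global processing order inside each component, and
    components are ordered by their first edge.
    """
    edges = list(edges)
    parent = list(range(len(edges)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    sets = [set(e.relevant) for e in edges]
    for a in range(len(edges)):
        for b in range(a + 1, len(edges)):
            if sets[a] & sets[b]:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
    groups: Dict[int, List[int]] = {}
    for idx in range(len(edges)):
        groups.setdefault(find(idx), []).append(idx)
    comps = []
    for members in sorted(groups.values(), key=lambda m: m[0]):
        comp_edges = tuple(edges[m] for m in members)
        support = frozenset().union(*(e.relevant for e in comp_edges))
        comps.append(ConstraintComponent(comp_edges, support))
    return comps


class Realizer:
    """Incremental coordinate realization for one instance.

    Radii and reference mutual distances are fixed by the instance, so the
    set of degenerate (single-intersection) positions is branch-independent
    and probed once; ``free`` holds every position with a genuine binary
    choice (position 4 included), ``fixed`` the repeats and degenerate
    positions.
    """

    def __init__(self, instance: DMDGPInstance,
                 tol: float = DEFAULT_TOL) -> None:
        self.instance = instance
        self.order = instance.order
        self.tol = tol
        self.first_ca = {self.order[t].residue: t
                         for t in range(1, len(self.order) + 1)
                         if self.order[t].kind == "CA"
                         and not self.order[t].is_repeat}
        self.free: FrozenSet[int] = frozenset()
        self.fixed: FrozenSet[int] = frozenset()
        self._probe()

    def _probe(self) -> None:
        free, fixed = set(), {1, 2, 3}
        coords = self.realize({}, record=(free, fixed))
        if len(coords) != len(self.order):
            raise InfeasibleEdgeError("instance not realizable")
        self.free = frozenset(free)
        self.fixed = frozenset(fixed)

    def realize(self, bits: Dict[int, int], upto: Optional[int] = None,
                record: Optional[tuple] = None) -> List[geometry.Point3]:
        """Coordinates of positions 1..upto; unassigned free bits read 0."""
        inst, order = self.instance, self.order
        upto = upto or len(order)
        coords: List[geometry.Point3] = list(geometry.place_first_three(
            inst.distance(1, 2), inst.distance(1, 3), inst.distance(2, 3)))
        for t in range(4, upto + 1):
            v = order[t]
            if v.is_repeat:
                coords.append(coords[self.first_ca[v.residue] - 1])
                if record is not None:
                    record[1].add(t)
                continue
            pts = geometry.trilaterate(
                coords[t - 2], coords[t - 3], coords[t - 4],
                inst.distance(t - 1, t), inst.distance(t - 2, t),
                inst.distance(t - 3, t), tol=TRILAT_TOL)
            if not pts:
                from .encoding import InfeasibleInstanceError
                raise InfeasibleInstanceError(
                    f"empty sphere intersection at position {t}")
            if len(pts) == 1:
                coords.append(pts[0])
                if record is not None:
                    record[1].add(t)
            else:
                if record is not None:
                    record[0].add(t)
                coords.append(pts[0] if bits.get(t, 0) == 1 else pts[1])
        return coords

    def edge_feasible(self, edge: PruningEdge, bits: Dict[int, int]) -> bool:
        coords = self.realize(bits, upto=edge.j)
        return abs(geometry.dist(coords[edge.i - 1], coords[edge.j - 1])
                   - edge.value) <= self.tol


def _window_string(edge: PruningEdge, bits: Dict[int, int],
                   fixed: FrozenSet[int]) -> BitString:
    return BitString(tuple(bits.get(p, 0) for p in edge.relevant),
                     edge.relevant[0],
                     frozenset(p for p in fixed if p in edge.relevant))


# ---------------------------------------------------------------------------
# generic search engines; exposed so that worked tree scenarios can be run
# directly against the accounting

def dfs_engine(free_slots: int,
               feasible: Callable[[Tuple[int, ...]], bool]
               ) -> Tuple[Tuple[int, ...], int]:
    """Left-first DFS over a binary tree with one level per free slot.

    The single root is shared by all paths; feasibility is tested at the
    leaves.  Returns the first feasible leaf (as a bit tuple) and the
    number of unique expanded nodes, root included.
    """
    nodes = 0
    found: List[Tuple[int, ...]] = []

    def visit(prefix: Tuple[int, ...]) -> bool:
        nonlocal nodes
        nodes += 1
        if len(prefix) == free_slots:
            if feasible(prefix):
                found.append(prefix)
                return True
            return False
        return visit(prefix + (0,)) or visit(prefix + (1,))

    if not visit(()):
        raise InfeasibleEdgeError("DFS exhausted the tree", nodes)
    return found[0], nodes


def fbs_engine(candidates: Iterable[Tuple[int, ...]],
               feasible: Callable[[Tuple[int, ...]], bool],
               path_length: int) -> Tuple[Tuple[int, ...], int]:
    """Frequency-ordered path testing with full-path accounting.

    Candidates are tested in the given order; if the accepted candidate is
    the k-th tested, the cost is ``k * path_length`` nodes.
    """
    k = 0
    for cand in candidates:
        k += 1
        if feasible(cand):
            return cand, k * path_length
    raise InfeasibleEdgeError("FBS exhausted all candidates",
                              k * path_length)


def _free_window(edge: PruningEdge, realizer: Realizer,
                 fixed_bits: Dict[int, int]) -> List[int]:
    return [p for p in edge.relevant
            if p in realizer.free and p not in fixed_bits]


def solve_edge_dfs(edge: PruningEdge, realizer: Realizer,
                   fixed_bits: Optional[Dict[int, int]] = None
                   ) -> Tuple[BitString, int]:
    """Left-first DFS over the edge's free relevant bits."""
    fixed_bits = dict(fixed_bits or {})
    slots = _free_window(edge, realizer, fixed_bits)

    def feasible(prefix: Tuple[int, ...]) -> bool:
        trial = dict(fixed_bits)
        trial.update(zip(slots, prefix))
        return realizer.edge_feasible(edge, trial)

    leaf, nodes = dfs_engine(len(slots), feasible)
    assignment = dict(fixed_bits)
    assignment.update(zip(slots, leaf))
    return _window_string(edge, assignment, realizer.fixed), nodes


def solve_edge_fbs(edge: PruningEdge, realizer: Realizer,
                   table, fixed_bits: Optional[Dict[int, int]] = None
                   ) -> Tuple[BitString, int]:
    """Frequency-ordered search over the edge's free relevant bits.

    Table candidates inconsistent with fixed/forced bits are skipped
    without being charged; remaining unseen sequences are appended in
    left-first (lexicographic, 0 < 1) order, so the search is complete
    even with an empty table.
    """
    fixed_bits = dict(fixed_bits or {})
    slots = _free_window(edge, realizer, fixed_bits)
    pinned = {p: fixed_bits.get(p, 0) for p in edge.relevant
              if p not in slots}

    seen = set()
    ordered: List[Tuple[int, ...]] = []
    for seq in table.sequences(edge.type_label) if table is not None else ():
        if len(seq) != edge.window_length:
            continue
        full = {p: int(c) for p, c in zip(edge.relevant, seq)}
        if any(full[p] != v for p, v in pinned.items()):
            continue  # conflicts with fixed bits: not testable, not charged
        cand = tuple(full[p] for p in slots)
        if cand not in seen:
            seen.add(cand)
            ordered.append(cand)
    for m in range(2 ** len(slots)):
        cand = tuple((m >> (len(slots) - 1 - s)) & 1
                     for s in range(len(slots)))
        if cand not in seen:
            seen.add(cand)
            ordered.append(cand)

    def feasible(cand: Tuple[int, ...]) -> bool:
        trial = dict(fixed_bits)
        trial.update(zip(slots, cand))
        return realizer.edge_feasible(edge, trial)

    leaf, nodes = fbs_engine(ordered, feasible, edge.window_length)
    assignment = dict(fixed_bits)
    assignment.update(zip(slots, leaf))
    return _window_string(edge, assignment, realizer.fixed), nodes


def flip(seq: BitString) -> BitString:
    """Complete flip of an edge sequence (fixed positions spared)."""
    return seq.flip_from(seq.offset)


def solve(instance: DMDGPInstance, strategy: str = "dfs",
          table=None, tol: float = DEFAULT_TOL
          ) -> Tuple[Solution, SolveStats]:
    """Solve an instance edge by edge with DFS or FBS ordering.

    Components are processed in edge order; inside a component each later
    edge is searched under the current partial assignment, with a
    component-wide complete flip as fallback (the flip inverts every
    earlier window in full and therefore preserves every satisfied edge).
    Unconstrained bits default to 0.
    """
    if strategy not in ("dfs", "fbs"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if strategy == "fbs" and table is None:
        raise ValueError("fbs strategy requires a frequency table")
    realizer = Realizer(instance, tol=tol)
    stats = SolveStats(strategy)
    assigned: Dict[int, int] = {}

    def search(edge: PruningEdge) -> Tuple[BitString, int]:
        if strategy == "dfs":
            return solve_edge_dfs(edge, realizer, assigned)
        return solve_edge_fbs(edge, realizer, table, assigned)

    for comp in decompose(pruning_edges(instance)):
        comp_assigned: List[int] = []
        done: List[PruningEdge] = []

        def flip_points(edge: PruningEdge) -> List[int]:
            # positions p from which the component's assignment may be
            # complete-flipped without breaking a solved edge: every earlier
            # window must lie fully below p or fully at/above p, and the
            # flip must reach into the failing edge's window
            in_window = [p for p in comp_assigned if p in edge.relevant]
            if not in_window:
                return []
            pts = []
            for p in sorted(set(comp_assigned), reverse=True):
                if p > max(in_window):
                    continue
                if all(f.relevant[0] >= p or f.relevant[-1] < p
                       for f in done):
                    pts.append(p)
            return pts

        for edge in comp.edges:
            try:
                seq, nodes = search(edge)
            except InfeasibleEdgeError as exc:
                # partial-reflection fallback: the failing edge may need
                # the other member of an earlier edge's flip pair
                nodes = exc.nodes
                seq = None
                snapshot = dict(assigned)
                pts = flip_points(edge)
                # reflections compose: a bit flips iff an odd number of
                # chosen flip origins lie at or below it
                for mask in range(1, 2 ** len(pts)):
                    chosen = [p for k, p in enumerate(pts) if mask >> k & 1]
                    assigned.clear()
                    assigned.update(snapshot)
                    for q in comp_assigned:
                        if sum(p <= q for p in chosen) % 2:
                            assigned[q] = 1 - assigned[q]
                    try:
                        seq, extra = search(edge)
                        nodes += extra
                        break
                    except InfeasibleEdgeError as exc2:
                        nodes += exc2.nodes
                if seq is None:
                    raise InfeasibleEdgeError(
                        f"edge ({edge.i}, {edge.j}) infeasible under every "
                        f"partial reflection", nodes)
            stats.add(edge, nodes)
            done.append(edge)
            for p in edge.relevant:
                if p in realizer.free and p not in assigned:
                    assigned[p] = seq.bit(p)
                    comp_assigned.append(p)

    bits = BitString(
        tuple(assigned.get(t, 0) for t in range(1, len(instance.order) + 1)),
        1, realizer.fixed | frozenset({1, 2, 3}))
    bits = normalize(bits)
    coords = realizer.realize(
        {p: bits.bit(p) for p in realizer.free})
    conf = Conformation(instance.order, tuple(coords))
    for r in instance.restraints:
        if abs(conf.distance(r.i, r.j) - r.value) > tol:
            raise InfeasibleEdgeError(
                f"solution violates restraint ({r.i}, {r.j})")
    return Solution(conf, bits), stats


def bp_reference(instance: DMDGPInstance, tol: float = DEFAULT_TOL,
                 max_free_bits: int = 22) -> List[BitString]:
    """Exhaustive branch-and-prune over all normalized global strings.

    Enumerates the full tree (b4 pinned to 0 by normalization), pruning a
    branch as soon as a pruning edge ending at the current depth is
    violated.  Used as the brute-force oracle for the build-up solver.
    """
    realizer = Realizer(instance, tol=tol)
    n_free = len(realizer.free)
    if n_free > max_free_bits:
        raise ValueError(
            f"{n_free} free bits exceed the cap of {max_free_bits}")
    order = instance.order
    edges_at: Dict[int, List[PruningEdge]] = {}
    for e in pruning_edges(instance):
        edges_at.setdefault(e.j, []).append(e)

    inst = instance
    solutions: List[BitString] = []

    def descend(t: int, coords: List[geometry.Point3],
                bits: Dict[int, int]) -> None:
        if t > len(order):
            full = BitString(
                tuple(bits.get(p, 0) for p in range(1, len(order) + 1)),
                1, realizer.fixed | frozenset({1, 2, 3}))
            solutions.append(full)
            return
        v = order[t]
        if v.is_repeat:
            candidates = [(None, coords[realizer.first_ca[v.residue] - 1])]
        else:
            pts = geometry.trilaterate(
                coords[t - 2], coords[t - 3], coords[t - 4],
                inst.distance(t - 1, t), inst.distance(t - 2, t),
                inst.distance(t - 3, t), tol=TRILAT_TOL)
            if not pts:
                return
            if len(pts) == 1:
                candidates = [(None, pts[0])]
            elif t == 4:
                candidates = [(0, pts[1])]  # normalization pins b4 = 0
            else:
                candidates = [(0, pts[1]), (1, pts[0])]
        for bit, p in candidates:
            ok = True
            for e in edges_at.get(t, ()):
                if abs(geometry.dist(coords[e.i - 1], p) - e.value) > tol:
                    ok = False
                    break
            if not ok:
                continue
            if bit is not None:
                bits[t] = bit
            coords.append(p)
            descend(t + 1, coords, bits)
            coords.pop()
            bits.pop(t, None)

    coords0 = list(geometry.place_first_three(
        inst.distance(1, 2), inst.distance(1, 3), inst.distance(2, 3)))
    descend(4, coords0, {})
    return solutions
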
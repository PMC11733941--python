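"""DMDGP instance data model and restraint I/O.

An instance couples a backbone order with exact distance restraints of two
roles: *discretization* distances (each vertex to its three immediate
predecessors, hypothesis H2, plus the clique on the first three vertices,
hypothesis H1) and *pruning* distances (extra restraints that cut branches
of the search tree).  The default pruning policy emulates the three
NMR/peptide-plane edge families analysed in the field:

* ``HA-HA``  — alpha-hydrogen of residue i to alpha-hydrogen of residue i+1
* ``HA-H``   — alpha-hydrogen of residue i to amide hydrogen of residue i+2
* ``C-CA``   — carboxyl carbon of residue i to alpha-carbon of residue i+1
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import geometry
from .geometry import Point3
from .order import BackboneOrder, build_order

DEFAULT_POLICY = ("HA-HA", "HA-H", "C-CA")


class ModelError(ValueError):
    """Instance violates a structural hypothesis (H1/H2)."""


class ParseError(ValueError):
    """Malformed restraint or coordinate file."""


@dataclass(frozen=True)
class DistanceRestraint:
    i: int
    j: int
    value: float
    role: str                      # "discretization" | "pruning"
    kind_i: str = ""
    kind_j: str = ""
    res_i: int = 0
    res_j: int = 0

    def __post_init__(self) -> None:
        if not self.i < self.j:
            raise ValueError("restraint requires i < j")
        if self.role not in ("discretization", "pruning"):
            raise ValueError(f"unknown role {self.role!r}")
        # a repeated CA sits at distance 0 from its first occurrence; that
        # restraint is kept so that H2 holds literally
        if self.value < 0 or (self.value == 0 and self.j - self.i != 3):
            raise ValueError("restraint value must be positive")
        if (self.role == "discretization") != (self.j - self.i <= 3):
            raise ValueError(
                f"role {self.role!r} inconsistent with span {self.j - self.i}"
            )


@dataclass(frozen=True)
class Conformation:
    """Coordinates for every vertex of an order (repeats share coordinates)."""

    order: BackboneOrder
    coords: Tuple[Point3, ...]

    def __post_init__(self) -> None:
        if len(self.coords) != len(self.order):
            raise ValueError("one coordinate per order position required")

    def point(self, position: int) -> Point3:
        return self.coords[position - 1]

    def distance(self, i: int, j: int) -> float:
        return geometry.dist(self.coords[i - 1], self.coords[j - 1])

    def to_tsv(self, path) -> None:
        rows = []
        for v, p in zip(self.order.vertices, self.coords):
            rows.append({"position": v.position, "kind": v.kind,
                         "residue": v.residue,
                         "x": f"{p[0]:.6f}", "y": f"{p[1]:.6f}",
                         "z": f"{p[2]:.6f}"})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @staticmethod
    def from_tsv(path, order: Optional[BackboneOrder] = None) -> "Conformation":
        df = pd.read_csv(path, sep="\t")
        n_res = int(df["residue"].max())
        order = order or build_order(n_res)
        if len(df) != len(order):
            raise ParseError("coordinate row count does not match order")
        coords = tuple((float(r.x), float(r.y), float(r.z))
                       for r in df.itertuples())
        return Conformation(order, coords)


@dataclass(frozen=True)
class GeometryParams:
    """Rigid-geometry parameters for the idealized backbone.

    Bond lengths in Angstrom, angles in degrees.  ``omega`` is the peptide
    torsion (180 deg = trans, planar); ``omega_jitter`` adds a Gaussian
    deviation per peptide bond, emulating the small non-planarity of
    experimental structures (0 keeps peptide planes exact, which makes the
    bits of in-plane atoms degenerate).  When jitter is on, deviations are
    redrawn until at least ``omega_jitter_min`` degrees from planarity: the
    separation between the two flip classes of a C..CA pruning edge grows
    only quadratically in the peptide deviation, so a deviation floor keeps
    every pruning constraint decidable at the solver's feasibility
    tolerance.  ``tor_lo``/``tor_hi`` bound the magnitudes of the two
    sampled backbone torsions per residue.
    """

    bond_n_ca: float = 1.458
    bond_ca_c: float = 1.525
    bond_c_n: float = 1.329
    bond_n_h: float = 1.01
    bond_ca_ha: float = 1.09
    ang_n_ca_c: float = 111.0
    ang_ca_c_n: float = 117.2
    ang_c_n_ca: float = 121.7
    ang_c_n_h: float = 119.0
    ang_h_n_ca: float = 119.3
    ang_n_ca_ha: float = 108.5
    ang_ha_ca_c: float = 109.4
    omega: float = 180.0
    omega_jitter: float = 0.0
    omega_jitter_min: float = 1.0
    tor_lo: float = 20.0
    tor_hi: float = 160.0

    def __post_init__(self) -> None:
        for name in ("bond_n_ca", "bond_ca_c", "bond_c_n",
                     "bond_n_h", "bond_ca_ha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("ang_n_ca_c", "ang_ca_c_n", "ang_c_n_ca",
                     "ang_c_n_h", "ang_h_n_ca", "ang_n_ca_ha",
                     "ang_ha_ca_c"):
            if not 0.0 < getattr(self, name) < 180.0:
                raise ValueError(f"{name} must be in (0, 180) degrees")
        if self.omega_jitter < 0:
            raise ValueError("omega_jitter must be >= 0")
        if self.omega_jitter > 0 and not (
                0 <= self.omega_jitter_min < 3 * self.omega_jitter):
            raise ValueError(
                "omega_jitter_min must be small relative to omega_jitter")
        if not 0.0 < self.tor_lo < self.tor_hi < 180.0:
            raise ValueError("need 0 < tor_lo < tor_hi < 180")


@dataclass(frozen=True)
class DMDGPInstance:
    order: BackboneOrder
    restraints: Tuple[DistanceRestraint, ...]
    _dist: Dict[Tuple[int, int], float] = field(
        default=None, repr=False, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_dist", {(r.i, r.j): r.value for r in self.restraints})
        self.validate()

    def validate(self) -> None:
        """Check hypotheses H1 (first-three clique) and H2 (predecessors)."""
        for (i, j) in ((1, 2), (1, 3), (2, 3)):
            if (i, j) not in self._dist:
                raise ModelError(
                    f"H1 violated: missing distance ({i}, {j})")
        for t in range(4, len(self.order) + 1):
            for back in (1, 2, 3):
                if (t - back, t) not in self._dist:
                    raise ModelError(
                        f"H2 violated at vertex {t}: "
                        f"missing distance ({t - back}, {t})")

    def distance(self, i: int, j: int) -> float:
        if i > j:
            i, j = j, i
        return self._dist[(i, j)]

    def has_distance(self, i: int, j: int) -> bool:
        if i > j:
            i, j = j, i
        return (i, j) in self._dist

    @property
    def pruning_restraints(self) -> Tuple[DistanceRestraint, ...]:
        return tuple(r for r in self.restraints if r.role == "pruning")


def _restraint(order: BackboneOrder, i: int, j: int, value: float,
               role: str) -> DistanceRestraint:
    vi, vj = order[i], order[j]
    return DistanceRestraint(i, j, value, role, vi.kind, vj.kind,
                             vi.residue, vj.residue)


def pruning_pairs(order: BackboneOrder,
                  policy: Sequence[str] = DEFAULT_POLICY
                  ) -> List[Tuple[int, int]]:
    """Endpoint positions of the pruning edges a policy generates."""
    n = order.n_residues
    pairs: List[Tuple[int, int]] = []
    if "HA-HA" in policy:
        pairs += [(order.position_of("HA", i), order.position_of("HA", i + 1))
                  for i in range(1, n)]
    if "HA-H" in policy:
        pairs += [(order.position_of("HA", i), order.position_of("H", i + 2))
                  for i in range(1, n - 1)]
    if "C-CA" in policy:
        pairs += [(order.position_of("C", i), order.position_of("CA", i + 1))
                  for i in range(1, n)]
    return sorted(pairs)


def build_instance(conf: Conformation,
                   policy: Sequence[str] = DEFAULT_POLICY) -> DMDGPInstance:
    """Measure a DMDGP instance off a conformation (planted solution).

    Emits the H1 clique, all H2 discretization restraints, and one pruning
    restraint per policy edge; every value is the Euclidean distance between
    the endpoint coordinates, so the generating conformation satisfies the
    instance exactly.
    """
    order = conf.order
    restraints: List[DistanceRestraint] = []
    for (i, j) in ((1, 2), (1, 3), (2, 3)):
        restraints.append(_restraint(order, i, j, conf.distance(i, j),
                                     "discretization"))
    for t in range(4, len(order) + 1):
        for back in (3, 2, 1):
            restraints.append(_restraint(order, t - back, t,
                                         conf.distance(t - back, t),
                                         "discretization"))
    for (i, j) in pruning_pairs(order, policy):
        restraints.append(_restraint(order, i, j, conf.distance(i, j),
                                     "pruning"))
    return DMDGPInstance(order, tuple(restraints))


# ---------------------------------------------------------------------------
# restraint TSV dialect:
#   i <tab> j <tab> value_A <tab> role <tab> kind_i <tab> kind_j
#     <tab> res_i <tab> res_j
# header lines start with '#'

_COLUMNS = ("i", "j", "value_A", "role", "kind_i", "kind_j", "res_i", "res_j")


def write_restraints(instance: DMDGPInstance, path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_COLUMNS) + "\n")
        fh.write(f"#n_residues={instance.order.n_residues}\n")
        for r in sorted(instance.restraints, key=lambda r: (r.j, r.i)):
            fh.write(f"{r.i}\t{r.j}\t{r.value:.9f}\t{r.role}\t"
                     f"{r.kind_i}\t{r.kind_j}\t{r.res_i}\t{r.res_j}\n")


def read_restraints(path) -> DMDGPInstance:
    """Parse the restraint TSV and validate H1/H2.

    Raises :class:`ParseError` with the offending line number on malformed
    input and :class:`ModelError` naming the first vertex whose
    discretization restraints are incomplete.
    """
    restraints: List[DistanceRestraint] = []
    n_residues = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#n_residues="):
                    n_residues = int(line.split("=", 1)[1])
                continue
            parts = line.split("\t")
            if len(parts) != len(_COLUMNS):
                raise ParseError(
                    f"line {lineno}: expected {len(_COLUMNS)} fields, "
                    f"got {len(parts)}")
            try:
                i, j = int(parts[0]), int(parts[1])
                value = float(parts[2])
                role = parts[3]
                kind_i, kind_j = parts[4], parts[5]
                res_i, res_j = int(parts[6]), int(parts[7])
                restraints.append(DistanceRestraint(
                    i, j, value, role, kind_i, kind_j, res_i, res_j))
            except (ValueError, TypeError) as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    if not restraints:
        raise ParseError("no restraints found")
    if n_residues is None:
        max_pos = max(r.j for r in restraints)
        n_residues = (max_pos + 3) // 6
    order = build_order(n_residues)
    return DMDGPInstance(order, tuple(restraints))
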
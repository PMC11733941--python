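"""Synthetic backbone conformations with planted DMDGP solutions.

The generator walks the backbone order vertex by vertex, exactly as a DMDGP
solver would: the first three vertices are placed canonically, every later
vertex is trilaterated from its three immediate predecessors, and whenever
the three spheres meet in two points the choice is one sampled bit.  The
three sphere radii at each step are *implied by the rigid-geometry
parameters*:

* bonded and two-bond (1-3) pairs follow from bond lengths and angles;
* peptide-plane 1-4 pairs (CA..H, CA..CA across the peptide bond) follow
  from the peptide torsion omega (180 deg + optional jitter);
* the two genuinely torsion-dependent pairs — HA(i-1)..H(i), which spans
  the psi torsion of residue i-1, and H(i)..HA(i), which spans the phi
  torsion of residue i — use one sampled torsion magnitude each.  These are
  the distances an NMR experiment would contribute.

Repeated CA vertices copy the coordinates of their first occurrence and
consume no random bits; so do degenerate (single-intersection) vertices,
which at omega = 180 are exactly the in-plane peptide atoms N and CA.
"""

from __future__ import annotations

from typing import Callable, Dict, List, Optional

import numpy as np

from . import geometry
from .geometry import InfeasibleGeometryError, Point3
from .model import Conformation, GeometryParams
from .order import OrderedVertex, build_order

#: sphere-intersection tolerance used during generation and decoding; the
#: discriminant clip (TRILAT_TOL**2) must sit above the squared coordinate
#: error that accumulates along an exactly-planar chain (~1e-16) and far
#: below the squared out-of-plane offset of a jittered peptide (~1e-2)
TRILAT_TOL = 1e-5

BitSampler = Callable[[np.random.Generator, int], int]


def _fair_coin(rng: np.random.Generator, position: int) -> int:
    return int(rng.integers(0, 2))


class _RadiusModel:
    """Discretization distances implied by a parameter set.

    ``psi[i]`` is the sampled magnitude of the torsion HA(i)-CA(i)-C(i)-N(i+1)
    and ``phi[i]`` of H(i)-N(i)-CA(i)-HA(i); ``omega[i]`` is the (possibly
    jittered) peptide torsion between residues i and i+1.
    """

    def __init__(self, params: GeometryParams,
                 phi: Dict[int, float], psi: Dict[int, float],
                 omega: Dict[int, float]) -> None:
        self.p = params
        self.phi = phi
        self.psi = psi
        self.omega = omega

    def first_three(self) -> tuple:
        p = self.p
        d12 = geometry.dist13(p.bond_n_ca, p.bond_ca_ha, p.ang_n_ca_ha)
        d13 = geometry.dist13(p.bond_n_ca, p.bond_ca_c, p.ang_n_ca_c)
        d23 = geometry.dist13(p.bond_ca_ha, p.bond_ca_c, p.ang_ha_ca_c)
        return d12, d13, d23

    def _d_ca_h(self, i: int) -> float:
        # CA(i) .. H(i+1): 1-4 across the peptide bond, torsion omega - 180
        p = self.p
        return geometry.chain_end_distance(
            [p.bond_ca_c, p.bond_c_n, p.bond_n_h],
            [p.ang_ca_c_n, p.ang_c_n_h],
            [self.omega[i] - 180.0])

    def _d_ca_ca(self, i: int) -> float:
        # CA(i) .. CA(i+1): 1-4 across the peptide bond, torsion omega
        p = self.p
        return geometry.chain_end_distance(
            [p.bond_ca_c, p.bond_c_n, p.bond_n_ca],
            [p.ang_ca_c_n, p.ang_c_n_ca],
            [self.omega[i]])

    def _d_ha_h(self, i: int) -> float:
        # HA(i) .. H(i+1): 1-5, spans psi(i) and the peptide torsion
        p = self.p
        return geometry.chain_end_distance(
            [p.bond_ca_ha, p.bond_ca_c, p.bond_c_n, p.bond_n_h],
            [p.ang_ha_ca_c, p.ang_ca_c_n, p.ang_c_n_h],
            [self.psi[i], self.omega[i] - 180.0])

    def _d_h_ha(self, i: int) -> float:
        # H(i) .. HA(i): 1-4 within the residue, spans phi(i)
        p = self.p
        return geometry.chain_end_distance(
            [p.bond_n_h, p.bond_n_ca, p.bond_ca_ha],
            [p.ang_h_n_ca, p.ang_n_ca_ha],
            [self.phi[i]])

    def radii(self, v: OrderedVertex) -> tuple:
        """(r to t-3, r to t-2, r to t-1) for a non-repeat vertex t >= 4."""
        p, i = self.p, v.residue
        if v.kind == "CA" and i == 1:
            # refs: N1, HA1, C1 — all bonded to CA
            return p.bond_n_ca, p.bond_ca_ha, p.bond_ca_c
        if v.kind == "H":
            # refs: HA(i-1), C(i-1), CA(i-1)
            return (self._d_ha_h(i - 1),
                    geometry.dist13(p.bond_c_n, p.bond_n_h, p.ang_c_n_h),
                    self._d_ca_h(i - 1))
        if v.kind == "N":
            # refs: C(i-1), CA(i-1), H(i)
            return (p.bond_c_n,
                    geometry.dist13(p.bond_ca_c, p.bond_c_n, p.ang_ca_c_n),
                    p.bond_n_h)
        if v.kind == "CA":
            # refs: CA(i-1), H(i), N(i)
            return (self._d_ca_ca(i - 1),
                    geometry.dist13(p.bond_n_h, p.bond_n_ca, p.ang_h_n_ca),
                    p.bond_n_ca)
        if v.kind == "HA":
            # refs: H(i), N(i), CA(i)
            return (self._d_h_ha(i),
                    geometry.dist13(p.bond_n_ca, p.bond_ca_ha, p.ang_n_ca_ha),
                    p.bond_ca_ha)
        if v.kind == "C":
            # refs: N(i), CA(i), HA(i)
            return (geometry.dist13(p.bond_n_ca, p.bond_ca_c, p.ang_n_ca_c),
                    p.bond_ca_c,
                    geometry.dist13(p.bond_ca_ha, p.bond_ca_c, p.ang_ha_ca_c))
        raise AssertionError(f"unhandled vertex kind {v.kind}")


def sample_conformation(n_residues: int,
                        params: Optional[GeometryParams] = None,
                        bit_sampler: Optional[BitSampler] = None,
                        seed: int = 0) -> Conformation:
    """Sample an idealized backbone conformation over the DMDGP order.

    ``bit_sampler(rng, position)`` chooses the branch (orientation bit) at
    every free position; the default is a fair coin.  Repeated and
    degenerate positions consume no random bits.  Identical seeds give
    identical coordinates.
    """
    params = params or GeometryParams()
    bit_sampler = bit_sampler or _fair_coin
    order = build_order(n_residues)
    rng = np.random.default_rng(seed)

    # per-residue torsions, sampled in a fixed sweep so that the stream of
    # random draws does not depend on branch outcomes
    phi = {i: float(rng.uniform(params.tor_lo, params.tor_hi))
           for i in range(2, n_residues + 1)}
    psi = {i: float(rng.uniform(params.tor_lo, params.tor_hi))
           for i in range(1, n_residues)}
    def _omega_dev() -> float:
        if params.omega_jitter <= 0:
            return 0.0
        while True:
            dev = float(rng.normal(0.0, params.omega_jitter))
            if abs(dev) >= params.omega_jitter_min:
                return dev

    omega = {i: params.omega + _omega_dev() for i in range(1, n_residues)}
    model = _RadiusModel(params, phi, psi, omega)

    coords: List[Point3] = []
    try:
        x1, x2, x3 = geometry.place_first_three(*model.first_three())
    except InfeasibleGeometryError as exc:
        raise InfeasibleGeometryError(
            f"infeasible first-three placement: {exc}") from exc
    coords += [x1, x2, x3]

    first_occurrence = {("CA", order[t].residue): t
                        for t in range(1, len(order) + 1)
                        if order[t].kind == "CA" and not order[t].is_repeat}

    for t in range(4, len(order) + 1):
        v = order[t]
        if v.is_repeat:
            coords.append(coords[first_occurrence[("CA", v.residue)] - 1])
            continue
        r3, r2, r1 = model.radii(v)  # to t-3, t-2, t-1
        a, b, c = coords[t - 4], coords[t - 3], coords[t - 2]
        points = geometry.trilaterate(c, b, a, r1, r2, r3, tol=TRILAT_TOL)
        if not points:
            raise InfeasibleGeometryError(
                f"no sphere intersection at position {t} ({v.kind}^{v.residue})")
        if len(points) == 1:
            coords.append(points[0])
            continue
        bit = int(bit_sampler(rng, t))
        if bit not in (0, 1):
            raise ValueError("bit sampler must return 0 or 1")
        coords.append(points[0] if bit == 1 else points[1])
    return Conformation(order, tuple(coords))
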
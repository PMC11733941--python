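"""PDB backbone extraction and fixture writing.

Only the first model of a file is read, and only the five backbone atoms
N, CA, C, H, HA are kept (altLoc other than blank/'A' discarded).  Chains
are cut into *segments*: maximal runs of contiguous, non-Pro/non-Gly
residues that carry all five atoms — the unit on which instances are built
and binary sequences extracted.  A fixture writer emits synthetic
conformations as poly-ALA ATOM records so tests run without downloads.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from typing import Dict, List, Tuple

import pandas as pd
from Bio.PDB import PDBParser

from .geometry import Point3
from .model import Conformation
from .order import build_order

BACKBONE_ATOMS = ("N", "CA", "C", "H", "HA")
EXCLUDED_RESIDUES = ("PRO", "GLY")


@dataclass(frozen=True)
class ResidueRecord:
    chain: str
    resseq: int
    icode: str
    resname: str
    atoms: Dict[str, Point3]

    @property
    def complete(self) -> bool:
        return all(k in self.atoms for k in BACKBONE_ATOMS)


@dataclass(frozen=True)
class Segment:
    source_id: str
    chain: str
    residues: Tuple[ResidueRecord, ...]

    @property
    def start(self) -> int:
        return self.residues[0].resseq

    @property
    def end(self) -> int:
        return self.residues[-1].resseq

    def __len__(self) -> int:
        return len(self.residues)


def parse_first_model(pdb_text: str,
                      source_id: str = "") -> List[ResidueRecord]:
    """Backbone residue records from the first model of a PDB file."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure(
            source_id or "pdb", io.StringIO(pdb_text))
    models = list(structure)
    if not models:
        warnings.warn("no ATOM records found")
        return []
    model = models[0]
    records: List[ResidueRecord] = []
    for chain in model:
        for residue in chain:
            hetflag, resseq, icode = residue.id
            if hetflag.strip():
                continue
            atoms: Dict[str, Point3] = {}
            for atom in residue:
                name = atom.get_name()
                if name not in BACKBONE_ATOMS:
                    continue
                if atom.get_altloc() not in (" ", "A"):
                    continue
                x, y, z = atom.get_coord()
                atoms[name] = (float(x), float(y), float(z))
            if atoms:
                records.append(ResidueRecord(chain.id, int(resseq),
                                             icode.strip(), residue.resname,
                                             atoms))
    return records


def segmentize(residues: List[ResidueRecord],
               source_id: str = "") -> List[Segment]:
    """Cut parsed residues into Pro/Gly-free complete-backbone segments.

    Breaks at Pro/Gly residues (which are dropped), chain changes,
    numbering gaps, insertion codes and residues missing any of the five
    backbone atoms; runs of fewer than 2 residues are discarded.
    """
    segments: List[Segment] = []
    run: List[ResidueRecord] = []

    def close() -> None:
        if len(run) >= 2:
            segments.append(Segment(source_id, run[0].chain, tuple(run)))
        run.clear()

    for rec in residues:
        breaking = (rec.resname in EXCLUDED_RESIDUES
                    or not rec.complete
                    or rec.icode != "")
        contiguous = (run
                      and rec.chain == run[-1].chain
                      and rec.resseq == run[-1].resseq + 1)
        if breaking:
            close()
            continue
        if run and not contiguous:
            close()
        run.append(rec)
    close()
    return segments


def segment_to_conformation(segment: Segment) -> Conformation:
    """Arrange a segment's coordinates over the DMDGP order.

    Repeated CA vertices reuse the residue's single CA coordinate.
    """
    order = build_order(len(segment))
    coords = []
    for v in order.vertices:
        coords.append(segment.residues[v.residue - 1].atoms[v.kind])
    return Conformation(order, tuple(coords))


# within-residue PDB output order for the five backbone atoms
_PDB_ATOM_ORDER = ("N", "CA", "C", "H", "HA")
_ELEMENT = {"N": "N", "CA": "C", "C": "C", "H": "H", "HA": "H"}


def write_fixture_pdb(conf: Conformation, path,
                      source_id: str = "SYNTH") -> None:
    """Write a sampled conformation as poly-ALA ATOM records.

    Synthetic fixture: idealized backbone geometry, one atom per distinct
    order vertex (repeated CA vertices collapse onto a single record).
    The first residue carries no amide hydrogen — the order's first block
    has none, mirroring a real N-terminus — so segment extraction on a
    fixture starts at residue 2.
    """
    per_res: Dict[int, Dict[str, Point3]] = {}
    for v, p in zip(conf.order.vertices, conf.coords):
        if not v.is_repeat:
            per_res.setdefault(v.residue, {})[v.kind] = p
    lines = [f"HEADER    SYNTHETIC BACKBONE FIXTURE            {source_id}",
             "MODEL        1"]
    serial = 1
    for res in sorted(per_res):
        for name in _PDB_ATOM_ORDER:
            if name not in per_res[res]:
                continue
            x, y, z = per_res[res][name]
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} ALA A{res:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {_ELEMENT[name]:>2s}")
            serial += 1
    lines += ["TER", "ENDMDL", "END", ""]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def segments_manifest(segments: List[Segment], path) -> None:
    """Segment manifest CSV: source id, chain, start, end, length."""
    rows = [{"source_id": s.source_id, "chain": s.chain,
             "start": s.start, "end": s.end, "length": len(s)}
            for s in segments]
    pd.DataFrame(rows, columns=["source_id", "chain", "start",
                                "end", "length"]).to_csv(path, index=False)
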
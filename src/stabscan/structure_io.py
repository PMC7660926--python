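"""Read, validate, slice and write protein structures in PDB format.

Residues are addressed by author (deposited) numbering throughout; no
internal renumbering is ever exposed.  Only the 20 standard amino acids are
retained; HETATM records, waters and non-standard residues are dropped with
a logged warning.  Residues missing any of the N/CA/C backbone atoms are
kept but flagged as unresolved so downstream scans can skip and report them.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_AA = set(THREE_TO_ONE.values())

BACKBONE_ATOMS = ("N", "CA", "C")


class PdbParseError(ValueError):
    """Raised for malformed or empty PDB input."""


class StructureError(ValueError):
    """Raised for invalid structure-level operations."""


@dataclass
class AtomRecord:
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name!r}: coords must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"atom {self.name!r}: occupancy {self.occupancy} outside [0, 1]")


@dataclass(frozen=True)
class ResidueKey:
    chain_id: str
    seq_number: int
    insertion_code: str = ""
    aa: str = "X"

    def __post_init__(self) -> None:
        if self.aa not in STANDARD_AA and self.aa != "X":
            raise StructureError(f"unknown amino-acid code {self.aa!r}")


@dataclass
class Residue:
    key: ResidueKey
    atoms: list[AtomRecord]
    # Volume of the residue occupying this position in the template; set by
    # the mutation machinery so the scorer can penalise cavity/overpacking.
    template_volume: float | None = None

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_backbone(self) -> bool:
        names = {a.name for a in self.atoms}
        return all(b in names for b in BACKBONE_ATOMS)


@dataclass
class Structure:
    residues: list[Residue]
    source_id: str = ""
    # Author positions requested in a slice but absent from the model.
    missing_positions: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.key.chain_id, None)
        return list(seen)

    def resolved(self) -> list[Residue]:
        """Residues with a complete N/CA/C backbone."""
        return [r for r in self.residues if r.has_backbone()]

    def unresolved_keys(self) -> list[ResidueKey]:
        return [r.key for r in self.residues if not r.has_backbone()]

    def find(self, position: int, chain_id: str | None = None) -> Residue | None:
        for r in self.residues:
            if r.key.seq_number == position and (chain_id is None or r.key.chain_id == chain_id):
                return r
        return None

    def sequence(self) -> str:
        return "".join(r.key.aa for r in self.residues)

    def copy(self) -> "Structure":
        return copy.deepcopy(self)


def _resolve_altlocs(atoms: list[AtomRecord], policy: str) -> list[AtomRecord]:
    by_name: dict[str, list[AtomRecord]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    out = []
    for name in order:
        group = by_name[name]
        if len(group) == 1:
            out.append(group[0])
        elif policy == "first":
            out.append(group[0])
        else:  # highest_occupancy, ties broken by altloc character order
            out.append(max(group, key=lambda a: (a.occupancy, _neg_ord(a.altloc))))
    return out


def _neg_ord(altloc: str) -> float:
    # Higher key wins in max(); earlier altloc letter should win ties.
    return -ord(altloc) if altloc else 0.0


def read_pdb(text: str, altloc_policy: str = "highest_occupancy") -> Structure:
    """Parse fixed-column PDB text into a :class:`Structure`.

    Only ATOM records for standard amino acids are retained.  Altloc
    duplicates are resolved per ``altloc_policy`` (``first`` or
    ``highest_occupancy``; ties broken by altloc character order).
    """
    if altloc_policy not in ("first", "highest_occupancy"):
        raise ValueError(f"unknown altloc policy {altloc_policy!r}")
    if not text or not text.strip():
        raise PdbParseError("empty PDB input")

    raw: dict[tuple, list[AtomRecord]] = {}
    order: list[tuple] = []
    dropped: set[str] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec == "HETATM":
            dropped.add(line[17:20].strip() or "?")
            continue
        if rec != "ATOM  " and rec.rstrip() != "ATOM":
            continue
        try:
            name = line[12:16].strip()
            altloc = line[16].strip()
            resname = line[17:20].strip()
            chain = line[21].strip()
            seq = int(line[22:26])
            icode = line[26].strip()
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            occ_field = line[54:60].strip()
            occ = float(occ_field) if occ_field else 1.0
            element = line[76:78].strip() if len(line) >= 78 else name[:1]
        except (ValueError, IndexError) as exc:
            raise PdbParseError(f"malformed ATOM record at line {lineno}: {exc}") from exc
        if resname not in THREE_TO_ONE:
            dropped.add(resname)
            continue
        key = (chain, seq, icode, THREE_TO_ONE[resname])
        if key not in raw:
            order.append(key)
            raw[key] = []
        raw[key].append(AtomRecord(name=name, element=element or name[:1],
                                   coords=np.array([x, y, z]), occupancy=min(occ, 1.0),
                                   altloc=altloc))
    if dropped:
        logger.warning("dropped non-standard/HETATM residues: %s", ", ".join(sorted(dropped)))
    if not order:
        raise PdbParseError("no standard amino-acid ATOM records found")

    residues = []
    for chain, seq, icode, aa in order:
        atoms = _resolve_altlocs(raw[(chain, seq, icode, aa)], altloc_policy)
        residues.append(Residue(key=ResidueKey(chain, seq, icode, aa), atoms=atoms))
    s = Structure(residues=residues)
    incomplete = s.unresolved_keys()
    if incomplete:
        logger.warning("%d residues missing N/CA/C backbone atoms (kept, flagged)", len(incomplete))
    return s


def write_pdb(s: Structure) -> str:
    """Serialise a Structure to fixed-column PDB text (v3.3 ATOM records)."""
    if not s.residues:
        raise StructureError("cannot write an empty Structure")
    lines = []
    serial = 1
    for res in s.residues:
        if not res.atoms:
            raise StructureError(f"residue {res.key} has no atoms")
        resname = ONE_TO_THREE.get(res.key.aa, "UNK")
        for a in res.atoms:
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            lines.append(
                "ATOM  {serial:5d} {name:<4s}{alt:1s}{res:<3s} {chain:1s}"
                "{seq:4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
                "          {elem:>2s}".format(
                    serial=serial, name=name, alt=a.altloc or " ", res=resname,
                    chain=res.key.chain_id or "A", seq=res.key.seq_number,
                    icode=res.key.insertion_code or " ",
                    x=a.coords[0], y=a.coords[1], z=a.coords[2],
                    occ=a.occupancy, b=0.0, elem=a.element[:2]))
            serial += 1
        serial = min(serial, 99999)
    lines.append("END")
    return "\n".join(lines) + "\n"


def slice_domain(s: Structure, chain: str, start: int, end: int) -> Structure:
    """Residues with ``start <= seq_number <= end`` on ``chain``, order kept.

    Author positions inside the range that are absent from the model are
    recorded in ``missing_positions`` on the result.
    """
    if start > end:
        raise StructureError(f"invalid slice: start {start} > end {end}")
    if chain not in s.chains():
        raise StructureError(f"chain {chain!r} not present (chains: {s.chains()})")
    picked = [copy.deepcopy(r) for r in s.residues
              if r.key.chain_id == chain and start <= r.key.seq_number <= end]
    if not picked:
        raise StructureError(f"slice {chain}:{start}-{end} selects no residues")
    present = {r.key.seq_number for r in picked}
    missing = [p for p in range(start, end + 1) if p not in present]
    return Structure(residues=picked, source_id=s.source_id, missing_positions=missing)
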
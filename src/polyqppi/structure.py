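"""Atom/residue/chain data model for two-chain docked complexes.

PDB files are read and written through :mod:`gemmi`; on top of that this
module enforces the conventions the downstream interface analysis relies on:
only the first MODEL is kept, alternate locations are resolved to the
highest-occupancy conformer (ties: first listed), waters are dropped, and
every atom can carry a van der Waals radius for solvent-accessible surface
area computation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "ComplexStructure",
    "PdbParseError",
    "EmptyStructureError",
    "DEFAULT_VDW_RADII",
    "FALLBACK_VDW_RADIUS",
    "read_pdb",
    "write_pdb",
    "assign_vdw_radii",
]


class PdbParseError(ValueError):
    """A fixed-width ATOM/HETATM record could not be parsed."""


class EmptyStructureError(ValueError):
    """The input contained no usable ATOM records."""


#: Bondi-type van der Waals radii (Å) for the elements that occur in
#: protein docking models.  Injectable per call for sensitivity analyses.
DEFAULT_VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
    "D": 1.20,
}

#: Radius assigned (with a logged warning) to elements absent from the table.
FALLBACK_VDW_RADIUS = 1.80

ResidueKey = tuple[str, int, str]


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Å
    vdw_radius: float | None
    residue_key: ResidueKey

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial} ({self.name}): coordinates must be 3 finite floats")

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    number: int
    icode: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.number, self.icode)


@dataclass
class ComplexStructure:
    """One docked two-chain model: ordered chains of ordered residues."""

    chains: list[tuple[str, list[Residue]]]
    source_path: str = ""

    def __post_init__(self) -> None:
        seen: set[ResidueKey] = set()
        for _, residues in self.chains:
            for res in residues:
                if res.key in seen:
                    raise ValueError(f"duplicate residue key {res.key}")
                seen.add(res.key)

    @property
    def chain_ids(self) -> list[str]:
        return [cid for cid, _ in self.chains]

    def chain(self, chain_id: str) -> list[Residue]:
        for cid, residues in self.chains:
            if cid == chain_id:
                return residues
        raise KeyError(f"chain {chain_id!r} not in structure (has {self.chain_ids})")

    def residues(self) -> Iterator[Residue]:
        for _, chain_residues in self.chains:
            yield from chain_residues

    def atoms(self) -> Iterator[Atom]:
        for res in self.residues():
            yield from res.atoms

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    @property
    def n_residues(self) -> int:
        return sum(1 for _ in self.residues())

    def subset(self, chain_ids: list[str]) -> "ComplexStructure":
        """New structure containing only the named chains (shared Atom objects)."""
        missing = [c for c in chain_ids if c not in self.chain_ids]
        if missing:
            raise KeyError(f"chains {missing} not in structure (has {self.chain_ids})")
        chains = [(cid, residues) for cid, residues in self.chains if cid in chain_ids]
        return ComplexStructure(chains=chains, source_path=self.source_path)


def _validate_atom_lines(text: str, path: str) -> int:
    """Fixed-width sanity check of ATOM/HETATM records.

    gemmi recovers silently from malformed coordinate fields, so malformed
    records are rejected here with the offending line number.  Returns the
    number of ATOM/HETATM records seen.
    """
    n_records = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        n_records += 1
        if len(line.rstrip()) < 54:
            raise PdbParseError(f"{path}: line {lineno}: ATOM record shorter than 54 columns")
        try:
            int(line[6:11])
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
        except ValueError as exc:
            raise PdbParseError(f"{path}: line {lineno}: malformed fixed-width ATOM record ({exc})") from exc
    return n_records


def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Highest-occupancy conformer per atom name; ties keep the first listed."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in res:
        prev = best.get(atom.name)
        if prev is None:
            best[atom.name] = atom
            order.append(atom.name)
        elif atom.occ > prev.occ:
            best[atom.name] = atom
    return [best[name] for name in order]


def _element_symbol(g_atom: gemmi.Atom) -> str:
    el = g_atom.element.name
    if el and el != "X":
        return el.upper()
    # Infer from the atom-name convention: first alphabetic character.
    for ch in g_atom.name:
        if ch.isalpha():
            return ch.upper()
    return "X"


_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


def read_pdb(path: str | Path) -> ComplexStructure:
    """Read the first model of a PDB file into a :class:`ComplexStructure`.

    Waters are dropped, alternate locations resolved to the
    highest-occupancy conformer, and chains/residues kept in file order
    with residues sorted by (number, insertion code).
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise IOError(f"cannot read PDB file {path}: {exc}") from exc
    _validate_atom_lines(text, str(path))

    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no ATOM/HETATM records")
    model = st[0]

    chains: list[tuple[str, list[Residue]]] = []
    serial = 0
    for g_chain in model:
        residues: list[Residue] = []
        for g_res in g_chain:
            if g_res.name in _WATER_NAMES:
                continue
            res = Residue(
                chain_id=g_chain.name,
                number=g_res.seqid.num,
                icode=g_res.seqid.icode.strip(),
                res_name=g_res.name,
            )
            for g_atom in _resolve_altlocs(g_res):
                serial += 1
                res.atoms.append(
                    Atom(
                        serial=serial,
                        name=g_atom.name,
                        element=_element_symbol(g_atom),
                        coords=np.array([g_atom.pos.x, g_atom.pos.y, g_atom.pos.z]),
                        vdw_radius=None,
                        residue_key=(g_chain.name, g_res.seqid.num, g_res.seqid.icode.strip()),
                    )
                )
            if res.atoms:
                residues.append(res)
        if residues:
            residues.sort(key=lambda r: (r.number, r.icode))
            chains.append((g_chain.name, residues))

    structure = ComplexStructure(chains=chains, source_path=str(path))
    if structure.n_atoms == 0:
        raise EmptyStructureError(f"{path}: structure is empty after dropping waters")
    return structure


def write_pdb(structure: ComplexStructure, path: str | Path) -> None:
    """Write fixed-width ATOM records with TER between chains and END."""
    if structure.n_atoms == 0:
        raise ValueError("cannot write an empty structure")
    st = gemmi.Structure()
    st.name = "polyqppi"
    model = gemmi.Model("1")
    for chain_id, residues in structure.chains:
        g_chain = gemmi.Chain(chain_id)
        for res in residues:
            g_res = gemmi.Residue()
            g_res.name = res.res_name
            g_res.seqid = gemmi.SeqId(res.number, res.icode or " ")
            g_res.het_flag = "A"                       # force ATOM records
            g_res.entity_type = gemmi.EntityType.Polymer
            for atom in res.atoms:
                g_atom = gemmi.Atom()
                g_atom.name = atom.name
                g_atom.element = gemmi.Element(atom.element)
                g_atom.pos = gemmi.Position(*atom.coords)
                g_atom.occ = 1.0
                g_res.add_atom(g_atom)
            g_chain.add_residue(g_res)
        model.add_chain(g_chain)
    st.add_model(model)
    try:
        st.write_pdb(str(path))
    except OSError as exc:
        raise IOError(f"cannot write PDB file {path}: {exc}") from exc


def assign_vdw_radii(
    structure: ComplexStructure,
    radius_table: Mapping[str, float] | None = None,
) -> ComplexStructure:
    """Assign a van der Waals radius to every atom, in place.

    Elements missing from the table get :data:`FALLBACK_VDW_RADIUS` with a
    logged warning.  Returns the same structure for chaining.
    """
    table = DEFAULT_VDW_RADII if radius_table is None else radius_table
    warned: set[str] = set()
    for atom in structure.atoms():
        radius = table.get(atom.element)
        if radius is None:
            if atom.element not in warned:
                logger.warning(
                    "element %s not in radius table; using fallback %.2f Å",
                    atom.element,
                    FALLBACK_VDW_RADIUS,
                )
                warned.add(atom.element)
            radius = FALLBACK_VDW_RADIUS
        if not (radius > 0) or not math.isfinite(radius):
            raise ValueError(f"non-positive vdW radius {radius} for element {atom.element}")
        atom.vdw_radius = radius
    return structure
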
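"""PISA-style interface quantities for a two-chain docked complex.

The central primitive is a deterministic Shrake–Rupley solvent-accessible
surface area (SASA): each atom sphere is inflated by the probe radius
(default 1.4 Å, water) and sampled with a fixed golden-angle spiral point
set; the accessible fraction of points gives the atom's area.  Buried area
per residue (ΔASA = isolated-chain SASA − in-complex SASA) defines the
interface: any residue burying more than a small threshold is an interface
residue.  Inter-chain hydrogen bonds and salt bridges are detected by
heavy-atom distance criteria, since docking models carry no hydrogens.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .structure import Atom, ComplexStructure, ResidueKey

__all__ = [
    "SasaResult",
    "InterfaceReport",
    "sphere_points",
    "shrake_rupley_sasa",
    "residue_delta_asa",
    "interface_residues",
    "detect_hydrogen_bonds",
    "detect_salt_bridges",
    "report_to_frame",
    "report_summary",
    "write_report",
]

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_N_POINTS = 960
#: ΔASA above this (Å²) marks an interface residue; absorbs quadrature noise.
DEFAULT_INTERFACE_THRESHOLD = 0.01
DEFAULT_HBOND_MAX_DIST = 3.5
DEFAULT_SALT_BRIDGE_MAX_DIST = 4.0


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-angle spiral point set on the unit sphere."""
    if n < 16:
        raise ValueError(f"need at least 16 sphere points, got {n}")
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


@dataclass
class SasaResult:
    """Per-atom and per-residue solvent-accessible areas (Å²)."""

    per_atom_area: dict[int, float]          # atom serial -> Å²
    per_residue_area: dict[ResidueKey, float]
    total: float
    params: tuple[float, int]                # (probe_radius, n_points)


def _sasa_atoms(structure: ComplexStructure, include_hydrogens: bool) -> list[Atom]:
    atoms = []
    for atom in structure.atoms():
        if atom.is_hydrogen and not include_hydrogens:
            continue
        if atom.vdw_radius is None or atom.vdw_radius <= 0:
            raise ValueError(
                f"atom {atom.serial} ({atom.name}) has no positive vdW radius; "
                "call assign_vdw_radii first"
            )
        atoms.append(atom)
    return atoms


def shrake_rupley_sasa(
    structure: ComplexStructure,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    include_hydrogens: bool = False,
) -> SasaResult:
    """Shrake–Rupley SASA of a structure with assigned radii.

    Deterministic for fixed ``n_points``: the sample points come from a
    fixed spiral construction, no RNG involved.
    """
    atoms = _sasa_atoms(structure, include_hydrogens)
    if not atoms:
        raise ValueError("no atoms eligible for SASA computation")
    coords = np.array([a.coords for a in atoms])
    if not np.all(np.isfinite(coords)):
        raise ValueError("NaN/inf coordinate in SASA atom set")
    radii = np.array([a.vdw_radius for a in atoms]) + probe_radius
    unit = sphere_points(n_points)

    tree = cKDTree(coords)
    max_r = radii.max()
    per_atom: dict[int, float] = {}
    per_residue: dict[ResidueKey, float] = {}
    for i, atom in enumerate(atoms):
        neighbors = tree.query_ball_point(coords[i], radii[i] + max_r)
        neighbors = [j for j in neighbors if j != i
                     and np.dot(coords[j] - coords[i], coords[j] - coords[i])
                     < (radii[i] + radii[j]) ** 2]
        if neighbors:
            pts = coords[i] + radii[i] * unit
            d2 = cdist(pts, coords[neighbors], "sqeuclidean")
            occluded = (d2 < (radii[neighbors] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - occluded.mean()
        else:
            frac = 1.0
        area = frac * 4.0 * np.pi * radii[i] ** 2
        per_atom[atom.serial] = area
        per_residue[atom.residue_key] = per_residue.get(atom.residue_key, 0.0) + area

    return SasaResult(
        per_atom_area=per_atom,
        per_residue_area=per_residue,
        total=float(sum(per_atom.values())),
        params=(probe_radius, n_points),
    )


Bond = tuple[Atom, Atom, float]


@dataclass
class InterfaceReport:
    """Interface characterisation of one two-chain complex."""

    receptor_chain: str
    partner_chain: str
    delta_asa: dict[ResidueKey, float]
    interface_residues: dict[str, set[ResidueKey]]
    n_interface: dict[str, int] = field(default_factory=dict)
    pct_interface: dict[str, float] = field(default_factory=dict)
    interface_area: float = 0.0
    buried_area: dict[str, float] = field(default_factory=dict)
    pct_buried_area: dict[str, float] = field(default_factory=dict)
    chain_sasa_isolated: dict[str, float] = field(default_factory=dict)
    chain_residue_counts: dict[str, int] = field(default_factory=dict)
    hbonds: list[Bond] = field(default_factory=list)
    salt_bridges: list[Bond] = field(default_factory=list)
    threshold: float = DEFAULT_INTERFACE_THRESHOLD

    def interface_residue_numbers(self, chain_id: str) -> set[int]:
        """Author residue numbers of the interface residues of one chain."""
        return {key[1] for key in self.interface_residues[chain_id]}

    def metrics(self) -> dict[str, float]:
        """The six comparison metrics used for preference classification."""
        r, p = self.receptor_chain, self.partner_chain
        return {
            "n_interface_receptor": float(self.n_interface[r]),
            "pct_interface_receptor": self.pct_interface[r],
            "n_interface_partner": float(self.n_interface[p]),
            "pct_interface_partner": self.pct_interface[p],
            "buried_area": self.interface_area,
            "pct_buried_area": self.pct_buried_area[r],
        }


# Heavy-atom donor/acceptor capability for the 20 standard residues.
# Backbone: N donates (except proline), O / OXT accept.
_SIDECHAIN_DONORS: dict[str, set[str]] = {
    "ARG": {"NE", "NH1", "NH2"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "LYS": {"NZ"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TRP": {"NE1"},
    "TYR": {"OH"},
}
_SIDECHAIN_ACCEPTORS: dict[str, set[str]] = {
    "ASN": {"OD1"},
    "ASP": {"OD1", "OD2"},
    "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
}
_BASIC_ATOMS: dict[str, set[str]] = {
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
    "HIS": {"ND1", "NE2"},
}
_ACIDIC_ATOMS: dict[str, set[str]] = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}


def _is_donor(atom: Atom, res_name: str) -> bool:
    if atom.name == "N" and res_name != "PRO":
        return True
    return atom.name in _SIDECHAIN_DONORS.get(res_name, set())


def _is_acceptor(atom: Atom, res_name: str) -> bool:
    if atom.name in ("O", "OXT"):
        return True
    return atom.name in _SIDECHAIN_ACCEPTORS.get(res_name, set())


def _chain_atoms_with_resnames(structure: ComplexStructure, chain_id: str) -> list[tuple[Atom, str]]:
    return [(atom, res.res_name) for res in structure.chain(chain_id) for atom in res.atoms]


def detect_salt_bridges(
    complex_structure: ComplexStructure,
    receptor_chain: str,
    partner_chain: str,
    max_dist: float = DEFAULT_SALT_BRIDGE_MAX_DIST,
) -> list[Bond]:
    """Inter-chain basic-N / acidic-O contacts within ``max_dist`` Å.

    Basic: LYS NZ, ARG NE/NH1/NH2, HIS ND1/NE2; acidic: ASP OD1/OD2,
    GLU OE1/OE2.  Returned as (basic atom, acidic atom, distance).
    """
    def classify(atoms: list[tuple[Atom, str]], table: dict[str, set[str]]) -> list[Atom]:
        return [a for a, rn in atoms if a.name in table.get(rn, set())]

    rec = _chain_atoms_with_resnames(complex_structure, receptor_chain)
    par = _chain_atoms_with_resnames(complex_structure, partner_chain)
    bonds: list[Bond] = []
    for basic_side, acidic_side in ((rec, par), (par, rec)):
        basic = classify(basic_side, _BASIC_ATOMS)
        acidic = classify(acidic_side, _ACIDIC_ATOMS)
        if not basic or not acidic:
            continue
        d = cdist([a.coords for a in basic], [a.coords for a in acidic])
        for i, j in zip(*np.nonzero(d <= max_dist)):
            bonds.append((basic[i], acidic[j], float(d[i, j])))
    bonds.sort(key=lambda b: (b[0].serial, b[1].serial))
    return bonds


def detect_hydrogen_bonds(
    complex_structure: ComplexStructure,
    receptor_chain: str,
    partner_chain: str,
    max_dist: float = DEFAULT_HBOND_MAX_DIST,
    exclude_salt_bridges: bool = True,
) -> list[Bond]:
    """Inter-chain donor(N/O)–acceptor(O/N) heavy-atom contacts ≤ ``max_dist`` Å.

    No angle criterion is applied (the models lack hydrogens).  By default a
    contact that also satisfies the salt-bridge criterion is reported only as
    a salt bridge, not double-counted here.
    """
    rec = _chain_atoms_with_resnames(complex_structure, receptor_chain)
    par = _chain_atoms_with_resnames(complex_structure, partner_chain)

    excluded: set[frozenset[int]] = set()
    if exclude_salt_bridges:
        for a, b, _ in detect_salt_bridges(
            complex_structure, receptor_chain, partner_chain
        ):
            excluded.add(frozenset((a.serial, b.serial)))

    bonds: list[Bond] = []
    seen: set[frozenset[int]] = set()
    for donor_side, acceptor_side in ((rec, par), (par, rec)):
        donors = [a for a, rn in donor_side if _is_donor(a, rn)]
        acceptors = [a for a, rn in acceptor_side if _is_acceptor(a, rn)]
        if not donors or not acceptors:
            continue
        d = cdist([a.coords for a in donors], [a.coords for a in acceptors])
        for i, j in zip(*np.nonzero(d <= max_dist)):
            pair = frozenset((donors[i].serial, acceptors[j].serial))
            if pair in excluded or pair in seen:
                continue
            seen.add(pair)
            bonds.append((donors[i], acceptors[j], float(d[i, j])))
    bonds.sort(key=lambda b: (b[0].serial, b[1].serial))
    return bonds


def residue_delta_asa(
    complex_structure: ComplexStructure,
    receptor_chain: str,
    partner_chain: str,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    threshold: float = DEFAULT_INTERFACE_THRESHOLD,
    hbond_max_dist: float = DEFAULT_HBOND_MAX_DIST,
    salt_bridge_max_dist: float = DEFAULT_SALT_BRIDGE_MAX_DIST,
) -> InterfaceReport:
    """Full interface report: ΔASA per residue, interface sets, area, bonds.

    Each chain's SASA is computed once in isolation and once in the
    two-chain complex with identical parameters; ΔASA = isolated − complex
    (non-negative by construction, since occlusion only grows).
    The interface area is half the total buried area,
    (SASA_A + SASA_B − SASA_AB) / 2, the usual PISA convention.
    """
    if receptor_chain == partner_chain:
        raise ValueError("receptor and partner chain must differ")
    rec_residues = complex_structure.chain(receptor_chain)   # raises on missing
    par_residues = complex_structure.chain(partner_chain)
    rec_keys = {r.key for r in rec_residues}
    par_keys = {r.key for r in par_residues}
    if rec_keys & par_keys:
        raise ValueError("receptor and partner chains share residue keys")

    pair = complex_structure.subset([receptor_chain, partner_chain])
    sasa_ab = shrake_rupley_sasa(pair, probe_radius, n_points)
    sasa_a = shrake_rupley_sasa(
        complex_structure.subset([receptor_chain]), probe_radius, n_points
    )
    sasa_b = shrake_rupley_sasa(
        complex_structure.subset([partner_chain]), probe_radius, n_points
    )

    delta: dict[ResidueKey, float] = {}
    for isolated in (sasa_a, sasa_b):
        for key, area in isolated.per_residue_area.items():
            delta[key] = area - sasa_ab.per_residue_area.get(key, 0.0)

    buried_a = sum(delta[k] for k in delta if k[0] == receptor_chain)
    buried_b = sum(delta[k] for k in delta if k[0] == partner_chain)

    report = InterfaceReport(
        receptor_chain=receptor_chain,
        partner_chain=partner_chain,
        delta_asa=delta,
        interface_residues={receptor_chain: set(), partner_chain: set()},
        interface_area=(sasa_a.total + sasa_b.total - sasa_ab.total) / 2.0,
        buried_area={receptor_chain: buried_a, partner_chain: buried_b},
        pct_buried_area={
            receptor_chain: 100.0 * buried_a / sasa_a.total if sasa_a.total else 0.0,
            partner_chain: 100.0 * buried_b / sasa_b.total if sasa_b.total else 0.0,
        },
        chain_sasa_isolated={receptor_chain: sasa_a.total, partner_chain: sasa_b.total},
        chain_residue_counts={
            receptor_chain: len(rec_residues),
            partner_chain: len(par_residues),
        },
        hbonds=detect_hydrogen_bonds(
            complex_structure, receptor_chain, partner_chain, hbond_max_dist
        ),
        salt_bridges=detect_salt_bridges(
            complex_structure, receptor_chain, partner_chain, salt_bridge_max_dist
        ),
        threshold=threshold,
    )
    interface_residues(report, threshold)
    return report


def interface_residues(
    report: InterfaceReport, threshold: float = DEFAULT_INTERFACE_THRESHOLD
) -> dict[str, set[ResidueKey]]:
    """Fill interface sets/counts/percentages: residue iff ΔASA > threshold."""
    sets: dict[str, set[ResidueKey]] = {
        report.receptor_chain: set(),
        report.partner_chain: set(),
    }
    for key, d in report.delta_asa.items():
        if d > threshold:
            sets[key[0]].add(key)
    report.interface_residues = sets
    report.threshold = threshold
    for chain_id, keys in sets.items():
        n_chain = report.chain_residue_counts.get(chain_id, 0)
        report.n_interface[chain_id] = len(keys)
        report.pct_interface[chain_id] = 100.0 * len(keys) / n_chain if n_chain else 0.0
    return sets


def report_to_frame(report: InterfaceReport) -> pd.DataFrame:
    """Per-residue table: ΔASA, interface membership, bond participation."""
    hbond_keys = {a.residue_key for a, _, _ in report.hbonds} | {
        b.residue_key for _, b, _ in report.hbonds
    }
    bridge_keys = {a.residue_key for a, _, _ in report.salt_bridges} | {
        b.residue_key for _, b, _ in report.salt_bridges
    }
    rows = []
    for key in sorted(report.delta_asa, key=lambda k: (k[0], k[1], k[2])):
        chain_id, number, icode = key
        rows.append(
            {
                "chain": chain_id,
                "residue_number": number,
                "icode": icode,
                "delta_asa": report.delta_asa[key],
                "is_interface": key in report.interface_residues[chain_id],
                "in_hbond": key in hbond_keys,
                "in_salt_bridge": key in bridge_keys,
            }
        )
    return pd.DataFrame(rows)


def report_summary(report: InterfaceReport) -> dict:
    """JSON-ready metrics summary of one complex."""
    return {
        "receptor_chain": report.receptor_chain,
        "partner_chain": report.partner_chain,
        "threshold": report.threshold,
        "interface_area": report.interface_area,
        "n_interface": dict(report.n_interface),
        "pct_interface": dict(report.pct_interface),
        "buried_area": dict(report.buried_area),
        "pct_buried_area": dict(report.pct_buried_area),
        "n_hbonds": len(report.hbonds),
        "n_salt_bridges": len(report.salt_bridges),
        "metrics": report.metrics(),
    }


def write_report(report: InterfaceReport, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
    report_to_frame(report).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(report_summary(report), indent=2))
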
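"""Synthetic docked complexes and study inputs with known ground truth.

The generators trade structural realism for provability: chains are
idealized extended strands (3.8 Å Cα spacing) of single-Cα residues, with
side-chain stub atoms only where hydrogen bonds or salt bridges are
planted.  Partner atoms are placed so that a contact atom occludes exactly
its planted receptor residue and nothing else: with carbon radii 1.70 Å and
a 1.4 Å probe, two atoms interact below 6.2 Å separation, so a contact
height of 5.5 Å buries the planted residue while the neighbouring Cα at
√(5.5² + 3.8²) = 6.68 Å stays untouched.  Every stub position was chosen
with the same margin analysis (documented in docs/methods.md).

``generate_variant_study`` emulates the 71-interactor ATXN1 comparison:
paired wt (Q29, residues 1–816) and expanded (Q82, residues 1–869)
receptor models whose interface sets realize a planted per-region profile
and whose metric ordering realizes a planted binding preference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .interface import residue_delta_asa
from .regions import REGION_LABELS, assign_regions, build_scheme
from .structure import Atom, ComplexStructure, Residue, assign_vdw_radii, write_pdb

__all__ = [
    "ComplexSpec",
    "StudySpec",
    "StudyOutput",
    "generate_contact_complex",
    "generate_variant_study",
    "generate_interactor_counts",
]

_CA_SPACING = 3.8
_CONTACT_HEIGHT = 5.5       # plain contact partner Cα above receptor Cα
_FAR_OFFSET = 30.0          # y of non-contact partner residues
_HBOND_DIST = 2.9
_SALT_BRIDGE_DIST = 3.4
_STUB_HEIGHT = 2.0          # receptor side-chain stub above the strand
_MAX_JITTER = 0.15          # keeps every occlusion margin intact


@dataclass
class ComplexSpec:
    """Blueprint for one synthetic two-chain contact complex."""

    receptor_length: int = 80
    partner_length: int = 40
    planted_interface: frozenset[int] = frozenset()
    n_hbonds: int = 0
    n_salt_bridges: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        planted = frozenset(int(i) for i in self.planted_interface)
        object.__setattr__(self, "planted_interface", planted)
        if planted and not all(1 <= i <= self.receptor_length for i in planted):
            raise ValueError("planted_interface must lie within [1, receptor_length]")
        if self.n_hbonds + self.n_salt_bridges > len(planted):
            raise ValueError(
                f"cannot plant {self.n_hbonds} H-bonds + {self.n_salt_bridges} salt bridges "
                f"on a {len(planted)}-residue interface"
            )
        if len(planted) > self.partner_length:
            raise ValueError("partner chain too short for the planted interface")


def _strand_residue(chain_id: str, number: int, res_name: str, serial: int,
                    atoms: list[tuple[str, str, np.ndarray]]) -> tuple[Residue, int]:
    res = Residue(chain_id=chain_id, number=number, icode="", res_name=res_name)
    for name, element, xyz in atoms:
        serial += 1
        res.atoms.append(
            Atom(serial=serial, name=name, element=element, coords=xyz,
                 vdw_radius=None, residue_key=(chain_id, number, ""))
        )
    return res, serial


def generate_contact_complex(
    spec: ComplexSpec,
    out_path: str | Path | None = None,
    verify: bool = False,
) -> tuple[ComplexStructure, dict]:
    """Build a two-chain complex realizing ``spec`` exactly.

    Receptor chain A runs along x; partner chain B contributes one contact
    residue per planted receptor residue (partner residues 1..k, in order
    of the sorted planted positions) and parks its remaining residues 30 Å
    away.  The first ``n_salt_bridges`` planted residues carry LYS NZ /
    GLU OE1 pairs at 3.4 Å, the next ``n_hbonds`` carry ASN ND2 / GLN OE1
    pairs at 2.9 Å.  With ``verify`` the planted truth is re-derived by a
    high-density SASA pass before returning.  Pure function of spec + seed.
    """
    rng = np.random.default_rng(spec.seed)
    planted = sorted(spec.planted_interface)
    bond_kind: dict[int, str] = {}
    for i, resnum in enumerate(planted):
        if i < spec.n_salt_bridges:
            bond_kind[resnum] = "salt"
        elif i < spec.n_salt_bridges + spec.n_hbonds:
            bond_kind[resnum] = "hbond"

    serial = 0
    receptor: list[Residue] = []
    for num in range(1, spec.receptor_length + 1):
        x = _CA_SPACING * (num - 1)
        kind = bond_kind.get(num)
        if kind == "salt":
            atoms = [("CA", "C", np.array([x, 0.0, 0.0])),
                     ("NZ", "N", np.array([x, _STUB_HEIGHT, 0.0]))]
            res, serial = _strand_residue("A", num, "LYS", serial, atoms)
        elif kind == "hbond":
            atoms = [("CA", "C", np.array([x, 0.0, 0.0])),
                     ("ND2", "N", np.array([x, _STUB_HEIGHT, 0.0]))]
            res, serial = _strand_residue("A", num, "ASN", serial, atoms)
        else:
            res, serial = _strand_residue(
                "A", num, "GLY", serial, [("CA", "C", np.array([x, 0.0, 0.0]))]
            )
        receptor.append(res)

    partner: list[Residue] = []
    truth_hbonds: list[tuple[int, int]] = []
    truth_bridges: list[tuple[int, int]] = []
    for j, resnum in enumerate(planted, start=1):
        x = _CA_SPACING * (resnum - 1)
        z = rng.uniform(-_MAX_JITTER, _MAX_JITTER)
        kind = bond_kind.get(resnum)
        if kind == "salt":
            oe_y = _STUB_HEIGHT + _SALT_BRIDGE_DIST
            atoms = [("CA", "C", np.array([x, oe_y + 2.0, z])),
                     ("OE1", "O", np.array([x, oe_y, z]))]
            res, serial = _strand_residue("B", j, "GLU", serial, atoms)
            truth_bridges.append((resnum, j))
        elif kind == "hbond":
            oe_y = _STUB_HEIGHT + _HBOND_DIST
            atoms = [("CA", "C", np.array([x, oe_y + 2.1, z])),
                     ("OE1", "O", np.array([x, oe_y, z]))]
            res, serial = _strand_residue("B", j, "GLN", serial, atoms)
            truth_hbonds.append((resnum, j))
        else:
            res, serial = _strand_residue(
                "B", j, "GLY", serial,
                [("CA", "C", np.array([x, _CONTACT_HEIGHT, z]))],
            )
        partner.append(res)
    for j in range(len(planted) + 1, spec.partner_length + 1):
        x = _CA_SPACING * (j - 1)
        res, serial = _strand_residue(
            "B", j, "GLY", serial, [("CA", "C", np.array([x, _FAR_OFFSET, 0.0]))]
        )
        partner.append(res)

    structure = ComplexStructure(chains=[("A", receptor), ("B", partner)])
    assign_vdw_radii(structure)
    truth = {
        "receptor_interface": set(planted),
        "partner_interface": set(range(1, len(planted) + 1)),
        "hbonds": truth_hbonds,
        "salt_bridges": truth_bridges,
    }

    if verify:
        report = residue_delta_asa(structure, "A", "B", n_points=3840)
        found = report.interface_residue_numbers("A")
        if found != truth["receptor_interface"]:
            raise AssertionError(
                f"generator self-check failed: interface {sorted(found)} != planted {planted}"
            )
        if len(report.hbonds) != spec.n_hbonds or len(report.salt_bridges) != spec.n_salt_bridges:
            raise AssertionError("generator self-check failed: bond counts differ from spec")

    if out_path is not None:
        write_pdb(structure, out_path)
    return structure, truth


@dataclass
class StudySpec:
    """Blueprint for a paired wt/expanded docking study with planted truth."""

    n_interactors: int
    region_gain: dict[str, int] = field(default_factory=dict)
    preference_mix: dict[str, int] | None = None   # default: all "expanded"
    noise: float = 0.0       # Poisson rate of paired extra after-polyQ residues
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_interactors < 1:
            raise ValueError("n_interactors must be >= 1")
        for label in self.region_gain:
            if label not in REGION_LABELS:
                raise ValueError(f"unknown region label {label!r} in region_gain")
        if self.preference_mix is None:
            self.preference_mix = {"expanded": self.n_interactors}
        if sum(self.preference_mix.values()) != self.n_interactors:
            raise ValueError("preference_mix counts must sum to n_interactors")
        if set(self.preference_mix) - {"wt", "expanded", "no_preference"}:
            raise ValueError("preference_mix labels must be wt/expanded/no_preference")


@dataclass
class StudyOutput:
    out_dir: Path
    metadata_path: Path
    metadata: pd.DataFrame
    truth_preferences: pd.DataFrame    # interactor_id, preference
    truth_regions: pd.DataFrame        # interactor_id, variant, region, count


# Sampling windows (wt coordinates) that keep each planted residue inside a
# single reporting region: "before" avoids the 20-residue flank, "after"
# avoids the flank and the AXH domain.
_BEFORE_WINDOW = (1, 156)
_AFTER_WINDOW = (300, 500)
_AXH_WINDOW = (562, 693)
_PARTNER_LENGTH = 60
_DEFAULT_GAIN = {"after_polyQ": 2}


def _sample_positions(rng: np.random.Generator, window: tuple[int, int], n: int,
                      taken: set[int]) -> list[int]:
    available = [p for p in range(window[0], window[1] + 1) if p not in taken]
    if n > len(available):
        raise ValueError(f"window {window} exhausted while planting {n} residues")
    chosen = list(rng.choice(available, size=n, replace=False))
    taken.update(chosen)
    return [int(c) for c in chosen]


def _map_to_expanded(positions: set[int]) -> set[int]:
    return {p + 53 if p > 196 else p for p in positions}


def _gain_window(label: str, variant: str) -> tuple[int, int]:
    offset = 53 if variant == "expanded_Q82" else 0
    if label == "before_polyQ":
        return _BEFORE_WINDOW
    if label == "after_polyQ":
        return (_AFTER_WINDOW[0] + offset, _AFTER_WINDOW[1] + offset)
    if label == "AXH":
        return (_AXH_WINDOW[0] + offset, _AXH_WINDOW[1] + offset)
    if label == "flank_before_20":
        return (177, 196)
    if label == "flank_after_20":
        start = 226 + (53 if variant == "expanded_Q82" else 0)
        return (start, start + 19)
    if label == "polyQ":
        return (197, 225 + (53 if variant == "expanded_Q82" else 0))
    raise ValueError(f"unknown region label {label!r}")


def generate_variant_study(spec: StudySpec, out_dir: str | Path) -> StudyOutput:
    """Write a paired wt/expanded study: PDBs, dock metadata, truth tables.

    Each interactor gets a base interface (1–3 residues before the polyQ,
    5–9 in the AXH domain, 2–4 elsewhere after the polyQ) that is identical
    in both variants up to the +53 coordinate shift; the variant named by
    the planted preference additionally gains ``region_gain`` residues per
    region (default 2 after the polyQ when no gain is specified), so the
    interface-count ordering realizes the preference exactly.  ``noise``
    adds Poisson-distributed extra after-polyQ residues to *both* variants,
    inflating between-interactor variability without touching the paired
    differences.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    labels = (
        ["wt"] * spec.preference_mix.get("wt", 0)
        + ["expanded"] * spec.preference_mix.get("expanded", 0)
        + ["no_preference"] * spec.preference_mix.get("no_preference", 0)
    )
    rng.shuffle(labels)
    gains = spec.region_gain or {}
    schemes = {"wt_Q29": build_scheme("wt_Q29"), "expanded_Q82": build_scheme("expanded_Q82")}

    meta_rows, pref_rows, region_rows = [], [], []
    for idx, pref in enumerate(labels, start=1):
        interactor = f"synth_{idx:03d}"
        taken: set[int] = set()
        base = set(_sample_positions(rng, _BEFORE_WINDOW, int(rng.integers(1, 4)), taken))
        base |= set(_sample_positions(rng, _AXH_WINDOW, int(rng.integers(5, 10)), taken))
        base |= set(_sample_positions(rng, _AFTER_WINDOW, int(rng.integers(2, 5)), taken))
        if spec.noise > 0:
            base |= set(_sample_positions(rng, _AFTER_WINDOW, int(rng.poisson(spec.noise)), taken))

        sets = {"wt_Q29": set(base), "expanded_Q82": _map_to_expanded(base)}
        if pref != "no_preference":
            variant = "wt_Q29" if pref == "wt" else "expanded_Q82"
            effective_gains = gains if sum(gains.values()) > 0 else _DEFAULT_GAIN
            taken_v = set(sets[variant])
            for label, k in effective_gains.items():
                window = _gain_window(label, variant)
                sets[variant].update(_sample_positions(rng, window, k, taken_v))

        for variant, planted in sets.items():
            length = schemes[variant].length
            cspec = ComplexSpec(
                receptor_length=length,
                partner_length=_PARTNER_LENGTH,
                planted_interface=frozenset(planted),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            rel_path = f"{interactor}_{variant}.pdb"
            generate_contact_complex(cspec, out_path=out_dir / rel_path)
            meta_rows.append(
                {
                    "interactor_id": interactor,
                    "variant": variant,
                    "model_id": "m1",
                    "zscore": float(np.round(rng.normal(-1.5, 0.5), 3)),
                    "probability": float(np.round(rng.uniform(0.6, 0.95), 3)),
                    "structure_path": rel_path,
                }
            )
            for label in REGION_LABELS:
                count = sum(
                    1 for p in planted if label in assign_regions(p, schemes[variant])
                )
                region_rows.append(
                    {
                        "interactor_id": interactor,
                        "variant": variant,
                        "region": label,
                        "count": count,
                    }
                )
        pref_rows.append({"interactor_id": interactor, "preference": pref})

    metadata = pd.DataFrame(meta_rows)
    truth_preferences = pd.DataFrame(pref_rows)
    truth_regions = pd.DataFrame(region_rows)
    metadata_path = out_dir / "metadata.tsv"
    metadata.to_csv(metadata_path, sep="\t", index=False)
    truth_preferences.to_csv(out_dir / "truth_preferences.tsv", sep="\t", index=False)
    truth_regions.to_csv(out_dir / "truth_regions.tsv", sep="\t", index=False)
    return StudyOutput(
        out_dir=out_dir,
        metadata_path=metadata_path,
        metadata=metadata,
        truth_preferences=truth_preferences,
        truth_regions=truth_regions,
    )


def generate_interactor_counts(
    n: int,
    slope: float = 4.89,
    intercept: float = 18.9,
    noise_sd: float = 55.0,
    seed: int = 0,
    x_range: tuple[int, int] = (1, 60),
) -> pd.DataFrame:
    """Interactor-count table with a planted linear relation.

    x is discrete uniform over ``x_range`` (counts in species B, e.g.
    mouse), y = slope·x + intercept + N(0, noise_sd) truncated at 0 and
    rounded to integer counts (species A, e.g. human).
    """
    if n < 3:
        raise ValueError("need n >= 3 points")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    x = rng.integers(x_range[0], x_range[1] + 1, size=n)
    y = slope * x + intercept + rng.normal(0.0, noise_sd, size=n)
    y = np.round(np.maximum(y, 0.0)).astype(int)
    return pd.DataFrame({"x": x, "y": y})
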
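"""SASA, buried-area and bond-detection behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import polyqppi as pq
from polyqppi.interface import (
    detect_hydrogen_bonds,
    detect_salt_bridges,
    interface_residues,
    report_to_frame,
    residue_delta_asa,
    shrake_rupley_sasa,
    sphere_points,
)
from .conftest import make_structure


def brute_force_sasa(coords, radii, probe=1.4, n_points=9600):
    """Independent high-density point-sampling oracle (plain O(n^2) loops)."""
    golden = np.pi * (1 + 5**0.5)
    i = np.arange(n_points) + 0.5
    z = 1 - 2 * i / n_points
    rho = np.sqrt(np.maximum(0, 1 - z * z))
    unit = np.column_stack([rho * np.cos(golden * i), rho * np.sin(golden * i), z])
    total = 0.0
    for a in range(len(coords)):
        r = radii[a] + probe
        pts = coords[a] + r * unit
        free = np.ones(n_points, bool)
        for b in range(len(coords)):
            if b == a:
                continue
            rb = radii[b] + probe
            free &= np.sum((pts - coords[b]) ** 2, axis=1) >= rb * rb
        total += free.mean() * 4 * np.pi * r * r
    return total


def test_isolated_carbon_matches_analytic_sphere():
    st_ = make_structure({"A": [(1, "CA", "C", (0, 0, 0))]})
    result = shrake_rupley_sasa(st_)
    analytic = 4 * np.pi * 3.10**2
    assert result.total == pytest.approx(analytic, rel=0.01)


def test_distant_atoms_do_not_occlude():
    st_ = make_structure({"A": [(1, "CA", "C", (0, 0, 0)), (2, "CA", "C", (10.0, 0, 0))]})
    result = shrake_rupley_sasa(st_)
    assert result.total == pytest.approx(2 * 4 * np.pi * 3.10**2, rel=1e-9)


def test_close_pair_matches_high_density_oracle():
    coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
    st_ = make_structure({"A": [(1, "CA", "C", coords[0]), (2, "CA", "C", coords[1])]})
    expected = brute_force_sasa(coords, np.array([1.70, 1.70]))
    assert shrake_rupley_sasa(st_).total == pytest.approx(expected, rel=0.02)


def test_per_residue_areas_sum_to_total():
    spec = pq.ComplexSpec(planted_interface=frozenset({5, 20, 40}), seed=3)
    structure, _ = pq.generate_contact_complex(spec)
    result = shrake_rupley_sasa(structure)
    assert sum(result.per_residue_area.values()) == pytest.approx(result.total, abs=1e-6)
    assert all(v >= 0 for v in result.per_atom_area.values())


def test_sasa_requires_radii(gly_pdb):
    structure = pq.read_pdb(gly_pdb)  # radii not assigned
    with pytest.raises(ValueError, match="vdW radius"):
        shrake_rupley_sasa(structure)


def test_sasa_agrees_with_independent_implementation():
    """Cross-check against biotite's Shrake-Rupley on random atom clouds."""
    import biotite.structure as biotite_struc

    rng = np.random.default_rng(42)
    for trial in range(20):
        n = int(rng.integers(5, 30))
        coords = rng.uniform(0, 12, size=(n, 3))
        elements = rng.choice(["C", "N", "O", "S"], size=n)
        st_ = make_structure(
            {"A": [(i + 1, "X", el, xyz) for i, (el, xyz) in enumerate(zip(elements, coords))]}
        )
        mine = shrake_rupley_sasa(st_, n_points=960).total
        arr = biotite_struc.AtomArray(n)
        arr.coord = coords
        arr.element = elements
        arr.res_id = np.arange(1, n + 1)
        arr.chain_id = np.full(n, "A")
        arr.atom_name = np.full(n, "X")
        arr.res_name = np.full(n, "ALA")
        theirs = float(
            biotite_struc.sasa(arr, probe_radius=1.4, point_number=960, vdw_radii="Single").sum()
        )
        assert mine == pytest.approx(theirs, rel=0.02), f"trial {trial}"


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10**6))
def test_occlusion_monotonicity(seed):
    """Adding an atom never increases the area of the existing atoms."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 8))
    coords = rng.uniform(0, 8, size=(n, 3))
    atoms = [(i + 1, "CA", "C", coords[i]) for i in range(n)]
    base = shrake_rupley_sasa(make_structure({"A": atoms[:-1]}), n_points=240)
    grown = shrake_rupley_sasa(make_structure({"A": atoms}), n_points=240)
    for serial, area in base.per_atom_area.items():
        assert grown.per_atom_area[serial] <= area + 1e-9


def test_sphere_points_unit_norm_and_minimum():
    pts = sphere_points(960)
    assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
    with pytest.raises(ValueError):
        sphere_points(8)


def test_separated_chains_have_no_interface():
    st_ = make_structure(
        {
            "A": [(1, "CA", "C", (0, 0, 0)), (2, "CA", "C", (3.8, 0, 0))],
            "B": [(1, "CA", "C", (0, 100.0, 0))],
        }
    )
    report = residue_delta_asa(st_, "A", "B")
    assert all(v == 0 for v in report.delta_asa.values())
    assert report.interface_area == pytest.approx(0.0, abs=1e-9)
    assert report.n_interface == {"A": 0, "B": 0}
    assert report.pct_interface["A"] == 0.0


def test_conservation_identity_and_planted_recovery():
    spec = pq.ComplexSpec(
        receptor_length=80, planted_interface=frozenset({3, 10, 22, 35, 51, 70}), seed=9
    )
    structure, truth = pq.generate_contact_complex(spec)
    report = residue_delta_asa(structure, "A", "B")
    total_delta = sum(report.delta_asa.values())
    buried = sum(report.chain_sasa_isolated.values()) - (
        report.chain_sasa_isolated["A"]
        + report.chain_sasa_isolated["B"]
        - 2 * report.interface_area
    )
    assert total_delta == pytest.approx(2 * report.interface_area, abs=0.1)
    assert buried == pytest.approx(2 * report.interface_area, abs=1e-6)
    assert report.interface_residue_numbers("A") == truth["receptor_interface"]
    assert report.n_interface["A"] == 6
    assert report.pct_interface["A"] == pytest.approx(7.5)


def test_chain_swap_symmetry():
    spec = pq.ComplexSpec(planted_interface=frozenset({7, 30}), n_hbonds=1, seed=11)
    structure, _ = pq.generate_contact_complex(spec)
    fwd = residue_delta_asa(structure, "A", "B")
    rev = residue_delta_asa(structure, "B", "A")
    assert fwd.interface_residues["A"] == rev.interface_residues["A"]
    assert fwd.interface_residues["B"] == rev.interface_residues["B"]
    assert fwd.interface_area == pytest.approx(rev.interface_area, abs=1e-9)
    assert {frozenset((a.serial, b.serial)) for a, b, _ in fwd.hbonds} == {
        frozenset((a.serial, b.serial)) for a, b, _ in rev.hbonds
    }


def test_interface_threshold_monotone():
    spec = pq.ComplexSpec(planted_interface=frozenset({5, 15, 25}), seed=2)
    structure, _ = pq.generate_contact_complex(spec)
    report = residue_delta_asa(structure, "A", "B")
    sizes = []
    for thr in (0.01, 1.0, 5.0, 1e6):
        sets = interface_residues(report, thr)
        sizes.append(len(sets["A"]) + len(sets["B"]))
    assert sizes == sorted(sizes, reverse=True)
    assert sizes[-1] == 0


def test_missing_chain_errors(gly_pdb):
    structure = pq.assign_vdw_radii(pq.read_pdb(gly_pdb))
    with pytest.raises(KeyError):
        residue_delta_asa(structure, "A", "Z")
    with pytest.raises(ValueError):
        residue_delta_asa(structure, "A", "A")


@pytest.mark.parametrize(
    "dist,expected", [(2.9, 1), (3.6, 0)], ids=["within_cutoff", "beyond_cutoff"]
)
def test_hydrogen_bond_distance_cutoff(dist, expected):
    st_ = make_structure(
        {
            "A": [(1, "N", "N", (0, 0, 0))],
            "B": [(1, "O", "O", (dist, 0, 0))],
        }
    )
    assert len(detect_hydrogen_bonds(st_, "A", "B")) == expected


def test_hydrogen_bond_requires_different_chains():
    st_ = make_structure(
        {
            "A": [(1, "N", "N", (0, 0, 0)), (2, "O", "O", (2.9, 0, 0))],
            "B": [(1, "CA", "C", (50, 0, 0))],
        }
    )
    assert detect_hydrogen_bonds(st_, "A", "B") == []


def test_salt_bridge_detection_rules():
    names = {("A", 1): "LYS", ("B", 1): "GLU", ("A", 2): "LYS", ("B", 2): "LYS"}
    st_ = make_structure(
        {
            "A": [(1, "NZ", "N", (0, 0, 0)), (2, "NZ", "N", (50, 0, 0))],
            "B": [(1, "OE1", "O", (3.5, 0, 0)), (2, "NZ", "N", (53.0, 0, 0))],
        },
        res_names=names,
    )
    bridges = detect_salt_bridges(st_, "A", "B")
    assert len(bridges) == 1 and bridges[0][2] == pytest.approx(3.5)

    far = make_structure(
        {"A": [(1, "NH1", "N", (0, 0, 0))], "B": [(1, "OD2", "O", (4.5, 0, 0))]},
        res_names={("A", 1): "ARG", ("B", 1): "ASP"},
    )
    assert detect_salt_bridges(far, "A", "B") == []


def test_salt_bridge_not_double_counted_as_hbond():
    st_ = make_structure(
        {"A": [(1, "NZ", "N", (0, 0, 0))], "B": [(1, "OE1", "O", (3.4, 0, 0))]},
        res_names={("A", 1): "LYS", ("B", 1): "GLU"},
    )
    assert len(detect_salt_bridges(st_, "A", "B")) == 1
    assert detect_hydrogen_bonds(st_, "A", "B") == []
    assert len(detect_hydrogen_bonds(st_, "A", "B", exclude_salt_bridges=False)) == 1


def test_report_frame_has_residue_rows():
    spec = pq.ComplexSpec(planted_interface=frozenset({5}), n_hbonds=1, seed=4)
    structure, _ = pq.generate_contact_complex(spec)
    report = residue_delta_asa(structure, "A", "B")
    frame = report_to_frame(report)
    assert len(frame) == structure.n_residues
    assert frame.loc[frame.is_interface, "delta_asa"].min() > report.threshold
    assert frame.in_hbond.sum() == 2  # donor and acceptor residue
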
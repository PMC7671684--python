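"""PDB parsing, Kabsch superposition, per-residue RMSD, ruler distances, pores."""

import io

import numpy as np
import pytest

import capsgate as cg
from capsgate.errors import (
    MissingAtomError,
    PairingError,
    ParameterError,
    PDBParseError,
)
from capsgate.pore import pore_profile
from capsgate.structure import (
    BONDI_VDW,
    kabsch,
    make_helix,
    make_ring_stack,
    paired_coords,
)

MINIMAL_PDB = (
    "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00"
    "           C\n"
    "ATOM      2  CA  ALA A   2       4.000   5.000   6.000  1.00  0.00"
    "           C\n"
)

ALTLOC_PDB = (
    "ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.60  0.00"
    "           C\n"
    "ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.40  0.00"
    "           C\n"
)


def rotation(angle_deg, axis="z"):
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    if axis == "z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


class TestReadStructure:
    def test_minimal_two_atoms(self):
        s = cg.read_structure(MINIMAL_PDB)
        assert s.n_atoms == 2
        assert np.allclose(s.coords[0], [1, 2, 3])
        assert np.allclose(s.coords[1], [4, 5, 6])

    def test_altloc_highest_occupancy_kept(self):
        s = cg.read_structure(ALTLOC_PDB)
        assert s.n_atoms == 1
        assert s.coords[0][0] == pytest.approx(1.0)

    def test_truncated_record_reports_line(self):
        bad = MINIMAL_PDB + "ATOM      3  CA  ALA A   3       7.000   8.0\n"
        with pytest.raises(PDBParseError) as exc:
            cg.read_structure(bad)
        assert exc.value.line_number == 3

    def test_malformed_coordinate_reports_line(self):
        bad = MINIMAL_PDB.replace("   4.000", "   4.0x0")
        with pytest.raises(PDBParseError) as exc:
            cg.read_structure(bad)
        assert exc.value.line_number == 2

    def test_empty_input_rejected(self):
        with pytest.raises(PDBParseError):
            cg.read_structure("HEADER    NOTHING\n")

    def test_extra_models_warn(self):
        text = ("MODEL        1\n" + MINIMAL_PDB + "ENDMDL\n"
                "MODEL        2\n" + MINIMAL_PDB + "ENDMDL\n")
        with pytest.warns(UserWarning, match="MODEL"):
            s = cg.read_structure(text)
        assert s.n_atoms == 2

    def test_write_read_round_trip_precision(self):
        h = make_helix(n_res=6)
        back = cg.read_structure(cg.write_structure(h))
        # PDB stores 3 decimals
        assert np.abs(back.coords - h.coords).max() < 5.001e-4


class TestKabsch:
    def test_self_superposition_identity(self):
        h = make_helix(n_res=8)
        sp, _ = cg.superpose_kabsch(h, h)
        assert sp.rmsd < 1e-6
        assert np.allclose(sp.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(sp.translation, 0.0, atol=1e-9)

    def test_rigid_motion_recovery(self):
        h = make_helix(n_res=8)
        moved = h.transformed(rotation(90), (3.0, -7.0, 11.0))
        sp, back = cg.superpose_kabsch(moved, h)
        assert sp.rmsd < 1e-6
        assert np.abs(back.coords - h.coords).max() < 1e-5

    def test_proper_rotation_enforced(self, rng):
        # a mirrored cloud must still yield det(R) = +1
        P = rng.normal(size=(10, 3))
        Q = P.copy()
        Q[:, 0] *= -1
        sp = kabsch(P, Q)
        assert np.linalg.det(sp.rotation) == pytest.approx(1.0)

    def test_collinear_selection_rejected(self):
        P = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(PairingError):
            kabsch(P, P + 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_quaternion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.normal(size=(10, 3))
        Q = (P @ rotation(37.0).T + [1.0, -2.0, 0.5]
             + rng.normal(0, 0.1, size=(10, 3)))
        sp = kabsch(P, Q)
        R_q, t_q, rmsd_q = horn_quaternion(P, Q)
        assert np.abs(sp.apply(P) - (P @ R_q.T + t_q)).max() < 1e-6
        assert sp.rmsd == pytest.approx(rmsd_q, abs=1e-9)
        assert 0.05 < sp.rmsd < 0.2

    def test_agrees_with_library_superimpose(self):
        # cross-check against biotite's independent implementation
        import biotite.structure as struc

        h = make_helix(n_res=10)
        rng = np.random.default_rng(1)
        noisy = h.atoms.copy()
        noisy.coord = noisy.coord + rng.normal(0, 0.2, noisy.coord.shape)
        moved = cg.StructureModel(noisy).transformed(rotation(55), (4, 4, 4))
        sp, _ = cg.superpose_kabsch(moved, h)
        transformed, _ = struc.superimpose(h.atoms, moved.atoms)
        lib_rmsd = struc.rmsd(h.atoms, transformed)
        assert sp.rmsd == pytest.approx(float(lib_rmsd), abs=1e-5)


def horn_quaternion(P, Q):
    """Closed-form quaternion (Horn) absolute-orientation oracle."""
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    M = P0.T @ Q0
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    vals, vecs = np.linalg.eigh(K)
    w, x, y, z = vecs[:, np.argmax(vals)]
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    t = cq - R @ cp
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1))))
    return R, t, rmsd


class TestPerResidueRmsd:
    def test_identical_structures_zero_everywhere(self):
        h = make_helix(n_res=10)
        prof = cg.per_residue_rmsd(h, h, analyze=(1, 10), align=(1, 10))
        assert np.nanmax(prof.rmsd_A) < 1e-9

    def test_uniform_displacement_outside_align_range(self):
        ref = make_helix(n_res=12)
        moved = ref.atoms.copy()
        shift = moved.res_id >= 9
        moved.coord = moved.coord.copy()
        moved.coord[shift] += [1.0, 0.0, 0.0]
        mob = cg.StructureModel(moved)
        prof = cg.per_residue_rmsd(mob, ref, analyze=(1, 12), align=(1, 8))
        assert np.nanmax(prof.rmsd_A[:8]) < 1e-9
        assert np.allclose(prof.rmsd_A[8:], 1.0, atol=1e-9)

    def test_matches_brute_force_oracle(self):
        ref = make_helix(n_res=10, rise_A=3.8)
        rng = np.random.default_rng(8)
        disp = rng.uniform(0, 1.0, size=10)
        moved = ref.atoms.copy()
        moved.coord = moved.coord.copy()
        for rid in range(1, 11):
            moved.coord[moved.res_id == rid] += [0, 0, disp[rid - 1]]
        mob = cg.StructureModel(moved)
        prof = cg.per_residue_rmsd(mob, ref, analyze=(1, 10), align=(1, 10))
        # brute-force recomputation: superpose once, then direct sums
        sp, placed = cg.superpose_kabsch(mob, ref, res_range=(1, 10),
                                         atom_names=("N", "CA", "C", "O"))
        for k, rid in enumerate(range(1, 11)):
            xm, xr = paired_coords(placed, ref, res_ids=[rid],
                                   atom_names=("N", "CA", "C", "O"))
            brute = np.sqrt(np.mean(np.sum((xm - xr) ** 2, axis=1)))
            assert prof.rmsd_A[k] == pytest.approx(brute, abs=1e-12)

    def test_align_range_consistency_with_superposition_rmsd(self):
        ref = make_helix(n_res=10)
        rng = np.random.default_rng(3)
        noisy = ref.atoms.copy()
        noisy.coord = noisy.coord + rng.normal(0, 0.3, noisy.coord.shape)
        mob = cg.StructureModel(noisy)
        prof = cg.per_residue_rmsd(mob, ref, analyze=(1, 10), align=(1, 10))
        # sum-of-squares aggregation of per-residue values = alignment RMSD
        agg = np.sqrt(np.nanmean(prof.rmsd_A ** 2))
        assert agg == pytest.approx(prof.alignment_rmsd, rel=1e-6)

    def test_missing_residues_reported_as_gaps(self):
        ref = make_helix(n_res=10)
        mob = make_helix(n_res=10).subset(res_range=(1, 8))
        prof = cg.per_residue_rmsd(mob, ref, analyze=(1, 10), align=(1, 8))
        assert np.isnan(prof.rmsd_A[8:]).all()
        assert np.nanmax(prof.rmsd_A[:8]) < 1e-9

    def test_rigid_transform_invariance(self):
        ref = make_helix(n_res=10)
        rng = np.random.default_rng(5)
        noisy = ref.atoms.copy()
        noisy.coord = noisy.coord + rng.normal(0, 0.2, noisy.coord.shape)
        mob = cg.StructureModel(noisy)
        p1 = cg.per_residue_rmsd(mob, ref, analyze=(1, 10), align=(1, 10))
        R, t = rotation(123.0), np.array([5.0, -3.0, 2.0])
        p2 = cg.per_residue_rmsd(mob.transformed(R, t),
                                 ref.transformed(R, t),
                                 analyze=(1, 10), align=(1, 10))
        assert np.allclose(p1.rmsd_A, p2.rmsd_A, atol=1e-5)


class TestResidueDistances:
    def test_simple_two_atom_distance(self):
        text = (
            "ATOM      1  OG1 THR A   1       0.000   0.000   0.000  1.00"
            "  0.00           O\n"
            "ATOM      2  OE1 GLU A   2       0.000   0.000   3.000  1.00"
            "  0.00           O\n"
        )
        s = cg.read_structure(text)
        d = cg.residue_min_distance(s, ("A", 1, ("OG1",)), ("A", 2, ("OE1",)))
        assert d["mean"] == pytest.approx(3.0)

    def test_identical_subsets_zero(self):
        s = cg.read_structure(MINIMAL_PDB)
        d = cg.residue_min_distance(s, ("A", 1, ("CA",)), ("A", 1, ("CA",)))
        assert d["mean"] == 0.0

    def test_sidechain_oxygen_defaults(self):
        text = (
            "ATOM      1  OG1 THR A   1       0.000   0.000   0.000  1.00"
            "  0.00           O\n"
            "ATOM      2  CB  THR A   1       1.000   0.000   0.000  1.00"
            "  0.00           C\n"
            "ATOM      3  OE1 GLU A   2       0.000   4.000   0.000  1.00"
            "  0.00           O\n"
            "ATOM      4  OE2 GLU A   2       0.000   2.500   0.000  1.00"
            "  0.00           O\n"
        )
        s = cg.read_structure(text)
        d = cg.residue_min_distance(s, ("A", 1, None), ("A", 2, None))
        # min over sidechain-oxygen pairs: OG1-OE2
        assert d["mean"] == pytest.approx(2.5)

    def test_missing_atom_named_in_error(self):
        s = cg.read_structure(MINIMAL_PDB)
        with pytest.raises(MissingAtomError, match="OG1"):
            cg.residue_min_distance(s, ("A", 1, ("OG1",)), ("A", 2, ("CA",)))

    def test_per_chain_reporting(self):
        lines = []
        n = 1
        for ch, off in (("A", 0.0), ("B", 10.0)):
            lines.append(
                f"ATOM  {n:>5}  OG1 THR {ch}   1       0.000   0.000"
                f"{off + 0.0:>8.3f}  1.00  0.00           O")
            n += 1
            lines.append(
                f"ATOM  {n:>5}  OE1 GLU {ch}   2       0.000   0.000"
                f"{off + 3.0 + (1.0 if ch == 'B' else 0.0):>8.3f}  1.00  0.00"
                "           O")
            n += 1
        s = cg.read_structure("\n".join(lines) + "\n")
        d = cg.residue_min_distance(s, (None, 1, ("OG1",)), (None, 2, ("OE1",)))
        assert d["per_chain"]["A"] == pytest.approx(3.0)
        assert d["per_chain"]["B"] == pytest.approx(4.0)
        assert d["mean"] == pytest.approx(3.5)

    def test_ruler_distance_on_synthetic_pair(self):
        # synthetic apo/bound pair: the pair is 1.3 Å closer in "bound"
        def pair(dz):
            return cg.read_structure(
                "ATOM      1  OG1 THR A 550       0.000   0.000   0.000  1.00"
                "  0.00           O\n"
                "ATOM      2  OE1 GLU A 570       0.000   0.000"
                f"{dz:>8.3f}  1.00  0.00           O\n")
        apo, bound = pair(5.3), pair(4.0)
        d = cg.ruler_distance(apo, bound, res_a=551, res_b=571,
                              numbering_offset=-1)
        assert d["delta_mean_A"] == pytest.approx(1.3, abs=1e-5)
        assert d["residues_structure_numbering"] == (550, 570)


class TestPoreProfile:
    def test_single_ring_analytic(self):
        s = make_ring_stack([(0.0, 6.0, 12)])
        prof = pore_profile(s, z_range=(0.0, 0.0), step_A=0.5)
        assert prof.radius_A[0] == pytest.approx(6.0 - BONDI_VDW["C"], abs=1e-5)

    def test_empty_slice_flagged_unbounded(self):
        s = make_ring_stack([(0.0, 6.0, 12)])
        prof = pore_profile(s, z_range=(50.0, 50.0), step_A=0.5,
                            max_radius_A=10.0)
        assert prof.unbounded[0]

    def test_radius_never_exceeds_center_distance(self):
        s = make_ring_stack([(0.0, 6.0, 10), (3.0, 8.0, 10), (6.0, 5.0, 10)],
                            stagger_deg=18.0)
        prof = pore_profile(s, z_range=(0.0, 6.0), step_A=0.5)
        for z, r in zip(prof.z_A, prof.radius_A):
            dmin = np.linalg.norm(s.coords - [0, 0, z], axis=1).min()
            assert r <= dmin + 1e-9

    def test_matches_brute_force_sphere_search(self):
        # staggered rings with distinct radii vs exhaustive 0.05 Å grid
        s = make_ring_stack([(0.0, 5.0, 9), (2.0, 7.0, 9)], stagger_deg=20.0)
        prof = pore_profile(s, z_range=(0.0, 2.0), step_A=1.0)
        radii = np.array([BONDI_VDW[e.upper()] for e in s.atoms.element])
        for z, r in zip(prof.z_A, prof.radius_A):
            d = np.linalg.norm(s.coords - [0, 0, z], axis=1) - radii
            brute = d.min()  # fixed axis: direct minimum
            assert r == pytest.approx(brute, abs=0.05)

    def test_optimized_center_finds_offset_pore(self):
        # ring displaced 1 Å off axis: moving center recovers full radius
        s = make_ring_stack([(0.0, 6.0, 16)])
        moved = cg.StructureModel(s.atoms.copy())
        moved.atoms.coord = moved.atoms.coord + [1.0, 0.0, 0.0]
        axis = ((0.0, 0.0, 0.0), (0.0, 0.0, 1.0))  # z measured from the first point
        fixed = pore_profile(moved, axis=axis, z_range=(0.0, 0.0), step_A=0.5)
        opt = pore_profile(moved, axis=axis, z_range=(0.0, 0.0), step_A=0.5,
                           mode="optimized_center")
        assert opt.radius_A[0] > fixed.radius_A[0]
        assert opt.radius_A[0] == pytest.approx(6.0 - BONDI_VDW["C"], abs=1e-3)

    def test_optimized_center_vs_brute_grid(self):
        s = make_ring_stack([(0.0, 5.0, 9), (1.5, 6.5, 9)], stagger_deg=15.0)
        radii = np.array([BONDI_VDW[e.upper()] for e in s.atoms.element])
        prof = pore_profile(s, z_range=(0.0, 1.5), step_A=0.75,
                            mode="optimized_center")
        for z, r in zip(prof.z_A, prof.radius_A):
            xs = np.arange(-2.0, 2.0001, 0.05)
            best = -np.inf
            for x in xs:
                for y in xs:
                    d = (np.linalg.norm(s.coords - [x, y, z], axis=1)
                         - radii).min()
                    best = max(best, d)
            assert r == pytest.approx(best, abs=0.05)

    def test_unknown_element_rejected(self):
        s = make_ring_stack([(0.0, 6.0, 8)])
        s.atoms.element = np.array(["XX"] * s.n_atoms)
        with pytest.raises(ParameterError):
            pore_profile(s, z_range=(0.0, 0.0), step_A=0.5)

    def test_principal_axis_mode(self):
        # same stack, rotated so its axis lies along x: principal mode recovers it
        s = make_ring_stack([(z, 6.0, 12) for z in np.arange(0, 30, 2.0)])
        tilted = s.transformed(rotation(90.0, axis="x"), (3.0, 1.0, -2.0))
        prof = pore_profile(tilted, axis="principal", z_range=None, step_A=2.0)
        mid = prof.radius_A[3:-3]
        assert np.allclose(mid, 6.0 - BONDI_VDW["C"], atol=0.01)

    def test_profile_tsv(self, tmp_path):
        s = make_ring_stack([(0.0, 6.0, 12)])
        prof = pore_profile(s, z_range=(0.0, 0.0), step_A=0.5)
        text = prof.to_tsv()
        assert "radius_A" in text and "4.3" in text
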
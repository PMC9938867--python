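import math
import warnings

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from phunlattice import (
    AtomicModel,
    GeometryError,
    ParameterError,
    channel_geometry,
    contact_map,
    expand_lattice_assembly,
    fit_model_in_map,
    inter_assembly_rotation,
    rmsd_on_selection,
    sequence_mass,
    simulate_density,
    superpose_kabsch,
)
from phunlattice.io_formats import Atom, Chain, DensityVolume, Residue

from conftest import make_ca_chain, make_ca_model


def _random_coords(seed, n=25, scale=12.0):
    return np.random.default_rng(seed).normal(size=(n, 3)) * scale


class TestKabsch:
    def test_self_superposition_is_identity(self):
        pts = _random_coords(0)
        tr, rmsd = superpose_kabsch(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(tr.rotation, np.eye(3), atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_known_transform_recovered(self, seed):
        rng = np.random.default_rng(seed)
        pts = _random_coords(seed)
        R = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
        t = rng.normal(size=3) * 10
        tr, rmsd = superpose_kabsch(pts, pts @ R.T + t)
        assert rmsd < 1e-9

    def test_rmsd_invariant_under_common_rigid_motion(self):
        rng = np.random.default_rng(3)
        a = _random_coords(1)
        b = a + rng.normal(size=a.shape) * 0.5
        _, rmsd0 = superpose_kabsch(a, b)
        R = Rotation.from_rotvec([0.4, -0.2, 0.9]).as_matrix()
        t = np.array([3.0, 4.0, -5.0])
        _, rmsd1 = superpose_kabsch(a @ R.T + t, b @ R.T + t)
        assert rmsd1 == pytest.approx(rmsd0, abs=1e-9)

    def test_collinear_points_rejected(self):
        line = np.outer(np.arange(10.0), [1.0, 0.0, 0.0])
        with pytest.raises(GeometryError):
            superpose_kabsch(line, line)


class TestRmsdOnSelection:
    def test_same_selection_matches_kabsch(self):
        pts = _random_coords(2)
        moved = pts @ Rotation.from_rotvec([0.1, 0.2, 0.3]).as_matrix().T + 4.0
        model = make_ca_model({"A": pts, "B": moved})
        out = rmsd_on_selection(model, ("A", "B"), (1, 25), {"all": (1, 25)})
        _, ref = superpose_kabsch(pts, moved)
        assert out["all"] == pytest.approx(ref, abs=1e-9)

    def test_displaced_loop_increases_reported_rmsd(self):
        pts = _random_coords(3)
        partner = pts.copy()
        partner[20:] += np.array([6.0, 0.0, 0.0])  # displaced tail
        model = make_ca_model({"A": pts, "B": partner})
        out = rmsd_on_selection(
            model, ("A", "B"), (1, 20), {"core": (1, 20), "all": (1, 25)}
        )
        assert out["all"] >= out["core"]

    def test_two_domain_rotation_matches_analytic_value(self):
        """Domain 2 rotated by 10° about a known axis through its centroid:
        the whole-chain RMSD follows from |Rx − x| = 2 sin(θ/2)·d⊥."""
        rng = np.random.default_rng(4)
        dom1 = rng.normal(size=(15, 3)) * 8.0
        dom2 = rng.normal(size=(15, 3)) * 8.0 + np.array([40.0, 0.0, 0.0])
        theta = math.radians(10.0)
        axis = np.array([0.0, 0.0, 1.0])
        c2 = dom2.mean(axis=0)
        R = Rotation.from_rotvec(theta * axis).as_matrix()
        dom2_rot = (dom2 - c2) @ R.T + c2
        chain_a = np.vstack([dom1, dom2])
        chain_b = np.vstack([dom1, dom2_rot])
        model = make_ca_model({"A": chain_a, "B": chain_b})
        out = rmsd_on_selection(
            model, ("A", "B"), (1, 15), {"whole": (1, 30)}
        )
        d = dom2 - c2
        perp = np.sqrt(d[:, 0] ** 2 + d[:, 1] ** 2)  # distance to the z axis
        disp2 = (2.0 * math.sin(theta / 2.0) * perp) ** 2
        expected = math.sqrt(disp2.sum() / 30.0)  # 15 unmoved atoms
        assert out["whole"] == pytest.approx(expected, abs=1e-6)

    def test_empty_selection_rejected(self):
        model = make_ca_model({"A": _random_coords(0), "B": _random_coords(0)})
        with pytest.raises(ParameterError):
            rmsd_on_selection(model, ("A", "B"), (100, 120), {"x": (1, 5)})


class TestSimulateDensity:
    def test_single_atom_peak_and_isotropy(self):
        model = make_ca_model({"A": [[0.0, 0.0, 0.0]]})
        vol = simulate_density(model, resolution=6.0, voxel_size=1.0)
        peak = np.unravel_index(np.argmax(vol.grid), vol.grid.shape)
        pos = np.array(peak[::-1]) * vol.voxel_size + vol.origin
        assert np.allclose(pos, 0.0, atol=1.0)
        nz, ny, nx = vol.grid.shape
        pz = vol.grid[:, peak[1], peak[2]]
        px = vol.grid[peak[0], peak[1], :]
        assert abs(pz.max() - px.max()) < 1e-9

    def test_far_atoms_add_linearly(self):
        m1 = make_ca_model({"A": [[0.0, 0.0, 0.0]]})
        m2 = make_ca_model({"A": [[60.0, 0.0, 0.0]]})
        m12 = make_ca_model({"A": [[0.0, 0.0, 0.0], [60.0, 0.0, 0.0]]})
        kw = dict(resolution=6.0, voxel_size=2.0, pad=12.0)
        s1 = simulate_density(m1, **kw).grid.sum()
        s2 = simulate_density(m2, **kw).grid.sum()
        s12 = simulate_density(m12, **kw).grid.sum()
        assert s12 == pytest.approx(s1 + s2, rel=1e-6)

    def test_width_calibration_half_amplitude_at_resolution(self):
        """The atom kernel's Fourier envelope falls to 0.5 at 1/d."""
        d = 8.0
        model = make_ca_model({"A": [[0.0, 0.0, 0.0]]})
        vol = simulate_density(model, resolution=d, voxel_size=1.0, pad=32.0)
        F = np.abs(np.fft.fftn(vol.grid.astype(float)))
        n = vol.grid.shape[2]
        freqs = np.fft.fftfreq(n, d=1.0)
        target = 1.0 / d
        idx = int(np.argmin(np.abs(freqs - target)))
        ratio = F[0, 0, idx] / F[0, 0, 0]
        assert ratio == pytest.approx(0.5, rel=0.15)

    def test_too_coarse_sampling_rejected(self):
        model = make_ca_model({"A": [[0.0, 0.0, 0.0]]})
        with pytest.raises(ParameterError):
            simulate_density(model, resolution=3.0, voxel_size=2.0)


class TestFitModelInMap:
    def test_identity_fit(self):
        model = make_ca_model({"A": _random_coords(5, n=30)})
        vol = simulate_density(model, 8.0, voxel_size=2.0, pad=14.0)
        fit = fit_model_in_map(model, vol, resolution=8.0)
        assert fit.masked_cc >= 0.99
        assert fit.transform.angle_deg <= 1.0
        assert np.linalg.norm(fit.transform.apply(
            model.all_coords()) - model.all_coords()) / math.sqrt(30) <= 0.5

    def test_displaced_pose_recovered(self):
        pts = _random_coords(6, n=30)
        model = make_ca_model({"A": pts})
        vol = simulate_density(model, 8.0, voxel_size=2.0, pad=16.0)
        axis = np.array([0.2, 0.9, 0.4])
        axis /= np.linalg.norm(axis)
        R = Rotation.from_rotvec(np.radians(15.0) * axis).as_matrix()
        c = pts.mean(axis=0)
        disp = (pts - c) @ R.T + c + np.array([5.0, -4.0, 4.0])
        fit = fit_model_in_map(make_ca_model({"A": disp}), vol,
                               resolution=8.0, global_search=True)
        rec = fit.transform.apply(disp)
        assert np.sqrt(((rec - pts) ** 2).sum(axis=1).mean()) < 0.5
        residual = fit.transform.rotation @ R
        ang = math.degrees(
            math.acos(np.clip((np.trace(residual) - 1) / 2, -1, 1))
        )
        assert ang <= 1.0

    def test_cc_invariant_under_common_axis_rotation(self):
        model = make_ca_model({"A": _random_coords(7, n=20)})
        vol = simulate_density(model, 8.0, voxel_size=2.0, pad=14.0)
        fit0 = fit_model_in_map(model, vol, resolution=8.0)
        # rotate both the map grid and the model by 90° about the grid z axis
        rot_grid = np.rot90(vol.grid, 1, axes=(1, 2))
        nz, ny, nx = vol.grid.shape
        # voxel (ix, iy) -> (iy, nx-1-ix) under rot90 on (y, x) planes
        R = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        def to_idx(x):  # Å -> voxel index coords
            return (x - vol.origin) / vol.voxel_size
        coords = model.all_coords()
        idx = to_idx(coords)
        new_idx = np.stack(
            [idx[:, 1], (nx - 1) - idx[:, 0], idx[:, 2]], axis=1
        )
        new_coords = new_idx * vol.voxel_size + vol.origin
        moved = make_ca_model({"A": new_coords})
        vol_rot = DensityVolume(rot_grid, vol.voxel_size, origin=vol.origin)
        fit1 = fit_model_in_map(moved, vol_rot, resolution=8.0)
        assert fit1.masked_cc == pytest.approx(fit0.masked_cc, abs=1e-3)


class TestLatticeExpansion:
    @staticmethod
    def _tetramer():
        rng = np.random.default_rng(8)
        chains = {}
        for k, cid in enumerate("ABCD"):
            chains[cid] = rng.normal(size=(10, 3)) * 8.0 + k * np.array(
                [18.0, 0.0, 0.0]
            )
        return make_ca_model(chains)

    def test_one_by_one_is_identity_copy(self):
        tet = self._tetramer()
        out = expand_lattice_assembly(tet, [120.0, 0.0], [0.0, 120.0], 1, 1)
        assert out.chain_ids == tet.chain_ids
        assert np.allclose(out.all_coords(), tet.all_coords())

    def test_two_by_two_counts(self):
        tet = self._tetramer()
        out = expand_lattice_assembly(tet, [120.0, 0.0], [-20.8, 118.2], 2, 2)
        assert len(out.chains) == 16
        cents = []
        for i in range(2):
            for j in range(2):
                suffix = "" if (i, j) == (0, 0) else f"_{i}_{j}"
                sub = [c for c in out.chains if c.chain_id.endswith(suffix)]
                assert len(sub) >= 4
        # no two copies share a centroid
        per_copy = np.array(
            [c.atom_coords().mean(axis=0) for c in out.chains]
        ).reshape(4, 4, 3).mean(axis=1)
        d = np.linalg.norm(per_copy[:, None] - per_copy[None], axis=-1)
        assert d[np.triu_indices(4, 1)].min() > 1.0

    def test_centroid_lattice_indexes_back_to_input_basis(self, motif):
        """Rendering the copy centroids of an 8×8 expansion as an image and
        indexing it recovers the input cell within 2%."""
        from phunlattice import MicrographImage, index_lattice
        from phunlattice.synthetic_data import _rasterize_gaussians

        tet = self._tetramer()
        a = np.array([120.0, 0.0])
        b = 120.0 * np.array([math.cos(math.radians(100.0)),
                              math.sin(math.radians(100.0))])
        out = expand_lattice_assembly(tet, a, b, 8, 8)
        cents = np.array(
            [c.atom_coords().mean(axis=0) for c in out.chains]
        ).reshape(64, 4, 3).mean(axis=1)[:, :2]
        canvas = np.zeros((512, 512))
        _rasterize_gaussians(canvas, (cents + 600.0) / 4.0, 1.0, 2.0)
        m = index_lattice(MicrographImage(canvas, 4.0))
        assert m.a_len == pytest.approx(120.0, rel=0.02)
        assert m.b_len == pytest.approx(120.0, rel=0.02)
        assert m.gamma == pytest.approx(100.0, abs=1.5)

    def test_clashing_copies_warn(self):
        tet = self._tetramer()
        with pytest.warns(UserWarning, match="clash"):
            expand_lattice_assembly(tet, [1.0, 0.0], [0.0, 1.0], 2, 2)

    def test_degenerate_basis_rejected(self):
        with pytest.raises(GeometryError):
            expand_lattice_assembly(self._tetramer(), [1.0, 0.0], [2.0, 0.0])


class TestChannelGeometry:
    def test_square_diagonals(self):
        s = 10.0
        model = make_ca_model(
            {"A": [[0, 0, 0]], "B": [[s, 0, 0]], "C": [[s, s, 0]],
             "D": [[0, s, 0]]}
        )
        corners = [("A", (1, 1)), ("B", (1, 1)), ("C", (1, 1)), ("D", (1, 1))]
        d1, d2 = channel_geometry(model, corners)
        assert d1 == pytest.approx(s * math.sqrt(2))
        assert d2 == pytest.approx(s * math.sqrt(2))

    def test_rectangle_diagonals_three_four_five(self):
        model = make_ca_model(
            {"A": [[0, 0, 0]], "B": [[3, 0, 0]], "C": [[3, 4, 0]],
             "D": [[0, 4, 0]]}
        )
        corners = [("A", (1, 1)), ("B", (1, 1)), ("C", (1, 1)), ("D", (1, 1))]
        d1, d2 = channel_geometry(model, corners)
        assert d1 == pytest.approx(5.0)
        assert d2 == pytest.approx(5.0)

    def test_requires_four_corners(self):
        model = make_ca_model({"A": [[0, 0, 0]]})
        with pytest.raises(ParameterError):
            channel_geometry(model, [("A", (1, 1))] * 3)


class TestInterAssemblyRotation:
    @staticmethod
    def _assembly(second_rotation_deg=0.0, axis=(1.0, 0.0, 0.0)):
        rng = np.random.default_rng(9)
        anchor = rng.normal(size=(20, 3)) * 9.0
        probe = rng.normal(size=(20, 3)) * 9.0 + np.array([35.0, 0.0, 0.0])
        if second_rotation_deg:
            ax = np.asarray(axis, dtype=float)
            ax /= np.linalg.norm(ax)
            R = Rotation.from_rotvec(
                np.radians(second_rotation_deg) * ax
            ).as_matrix()
            c = probe.mean(axis=0)
            probe = (probe - c) @ R.T + c
        return make_ca_model({"A": anchor, "B": probe})

    def test_self_rotation_is_zero(self):
        a = self._assembly()
        r = inter_assembly_rotation(a, a, "A", "B")
        assert r.angle == pytest.approx(0.0, abs=1e-9)

    def test_constructed_out_of_plane_rotation_recovered(self):
        a = self._assembly()
        b = self._assembly(second_rotation_deg=30.0, axis=(1.0, 0.0, 0.0))
        r = inter_assembly_rotation(a, b, "A", "B")
        assert r.angle == pytest.approx(30.0, abs=0.1)
        assert r.out_of_plane == pytest.approx(90.0, abs=0.5)

    def test_symmetric_in_assembly_order(self):
        a = self._assembly()
        b = self._assembly(second_rotation_deg=42.0, axis=(0.3, 0.7, 0.2))
        r1 = inter_assembly_rotation(a, b, "A", "B")
        r2 = inter_assembly_rotation(b, a, "A", "B")
        assert r1.angle == pytest.approx(r2.angle, abs=1e-6)


class TestContactMap:
    @staticmethod
    def _pair_model(distance, regions=None):
        ca = Chain("A", [Residue(120, "ALA", "", [Atom("CB", "C",
                   np.array([0.0, 0.0, 0.0]))])])
        cb = Chain("B", [Residue(120, "ALA", "", [Atom("CB", "C",
                   np.array([distance, 0.0, 0.0]))])])
        return AtomicModel(chains=[ca, cb], regions=regions or {})

    def test_contact_inside_cutoff(self):
        contacts = contact_map(self._pair_model(3.0), cutoff=4.5)
        assert len(contacts) == 1
        assert contacts[0].distance == pytest.approx(3.0)

    def test_no_contact_outside_cutoff(self):
        assert contact_map(self._pair_model(5.0), cutoff=4.5) == []

    def test_count_monotone_in_cutoff(self):
        rng = np.random.default_rng(10)
        model = make_ca_model(
            {"A": rng.normal(size=(30, 3)) * 6.0,
             "B": rng.normal(size=(30, 3)) * 6.0 + 4.0}
        )
        counts = [len(contact_map(model, cutoff=c)) for c in (3.0, 4.0, 5.0, 6.0)]
        assert counts == sorted(counts)

    def test_hairpin_contacts_classified_closed(self):
        regions = {"beta_hairpin": (111, 126)}
        contacts = contact_map(
            self._pair_model(3.5, regions=regions), cutoff=4.5
        )
        assert contacts[0].region1 == "beta_hairpin"
        assert contacts[0].interface == "closed_hairpin"

    def test_single_chain_rejected(self):
        model = make_ca_model({"A": _random_coords(0)})
        with pytest.raises(ParameterError):
            contact_map(model)


class TestSequenceMass:
    def test_glycine(self):
        assert sequence_mass("G") == pytest.approx(0.07507, abs=1e-5)

    def test_diglycine(self):
        assert sequence_mass("GG") == pytest.approx(0.13212, abs=1e-5)

    def test_matches_independent_reference(self):
        """Average masses agree with Biopython's molecular_weight."""
        from Bio.SeqUtils import molecular_weight

        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQFEVVHSLAKWKRQTLGQHDFSAGEGLYTHMKALRPDEDRLSPLHSVYVDQWDWE"
        ours = sequence_mass(seq) * 1000.0
        ref = molecular_weight(seq, seq_type="protein", monoisotopic=False)
        assert ours == pytest.approx(ref, rel=2e-4)

    def test_unknown_letter_named(self):
        with pytest.raises(ParameterError, match="X"):
            sequence_mass("GAX")
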
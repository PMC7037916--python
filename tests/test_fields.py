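import numpy as np
import pytest

from duotox import fields as fl
from duotox.errors import ConfigurationError, InputError
from duotox.prepare import FIELD_NAMES, AlignedMolecule


def point_molecule(coords, cid="P", **weight_overrides):
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = len(coords)
    weights = {f: np.ones(n) for f in FIELD_NAMES}
    weights.update({k: np.asarray(v, dtype=float) for k, v in weight_overrides.items()})
    return AlignedMolecule(cid, ["X"] * n, coords, weights)


class TestBuildGrid:
    def test_single_atom_margin4_spacing2(self):
        grid = fl.build_grid([point_molecule([0, 0, 0])], fl.FieldConfig(spacing=2.0, margin=4.0))
        assert grid.shape == (5, 5, 5)
        assert np.allclose(grid.origin, [-4, -4, -4])
        # centered on the atom
        assert np.allclose(grid.points().mean(axis=0), [0, 0, 0], atol=1e-12)

    def test_degenerate_margin0(self):
        grid = fl.build_grid([point_molecule([1, 2, 3])], fl.FieldConfig(spacing=2.0, margin=0.0))
        assert grid.shape == (1, 1, 1)
        assert np.allclose(grid.points(), [[1, 2, 3]])

    def test_covering(self):
        mols = [point_molecule([[0, 0, 0], [3, 1, -2]]), point_molecule([[7, -4, 5]], cid="Q")]
        config = fl.FieldConfig(spacing=2.0, margin=4.0)
        grid = fl.build_grid(mols, config)
        pts = grid.points()
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        for m in mols:
            assert np.all(m.coords >= lo - 1e-9) and np.all(m.coords <= hi + 1e-9)

    def test_empty_input(self):
        with pytest.raises(InputError):
            fl.build_grid([], fl.FieldConfig())


class TestSimilarityIndex:
    def test_single_atom_at_zero_distance(self):
        mol = point_molecule([0, 0, 0])
        config = fl.FieldConfig(attenuation_alpha=0.3)
        assert fl.similarity_index(mol, [0, 0, 0], "S", config) == pytest.approx(-1.0)

    def test_attenuation_limit(self):
        mol = point_molecule([0, 0, 0])
        config = fl.FieldConfig(attenuation_alpha=0.3)
        val = fl.similarity_index(mol, [10, 0, 0], "S", config)
        assert val == pytest.approx(-np.exp(-30.0), abs=1e-15)

    def test_three_atom_brute_force_oracle(self, rng):
        coords = rng.normal(scale=2.0, size=(3, 3))
        w = rng.uniform(0.5, 2.0, 3)
        mol = point_molecule(coords, H=w)
        config = fl.FieldConfig(attenuation_alpha=0.42, probe_weights={"H": 1.7})
        q = np.array([0.3, -1.1, 0.8])
        expected = 0.0
        for i in range(3):
            r2 = float(np.sum((coords[i] - q) ** 2))
            expected += -1.7 * w[i] * np.exp(-0.42 * r2)
        assert fl.similarity_index(mol, q, "H", config) == pytest.approx(expected, rel=1e-12)

    def test_monotone_attenuation(self):
        config = fl.FieldConfig()
        values = [
            abs(fl.similarity_index(point_molecule([d, 0, 0]), [0, 0, 0], "S", config))
            for d in np.linspace(0, 8, 30)
        ]
        assert all(a >= b - 1e-15 for a, b in zip(values, values[1:]))

    def test_sign_convention_nonnegative_weights(self, rng):
        mol = point_molecule(rng.normal(size=(4, 3)), S=rng.uniform(0, 3, 4))
        config = fl.FieldConfig()
        for q in rng.normal(scale=3, size=(10, 3)):
            assert fl.similarity_index(mol, q, "S", config) <= 0.0


class TestAssemble:
    def test_identical_molecules_identical_rows(self):
        mols = [point_molecule([[0, 0, 0], [1, 1, 1]], cid=f"M{i}") for i in range(3)]
        desc = fl.assemble_descriptors(mols, fl.FieldConfig(column_drop_sigma=0.0))
        assert np.array_equal(desc.X[0], desc.X[1])
        assert np.array_equal(desc.X[0], desc.X[2])

    def test_sigma_zero_keeps_all_columns(self, synth_molecules):
        config = fl.FieldConfig(spacing=4.0, margin=2.0, column_drop_sigma=0.0, block_scaling="none")
        desc = fl.assemble_descriptors(synth_molecules[:5], config)
        grid = desc.grid
        assert desc.X.shape[1] == 5 * grid.n_points

    def test_pointwise_oracle(self, synth_molecules):
        mols = synth_molecules[:5]
        config = fl.FieldConfig(spacing=4.0, margin=2.0, column_drop_sigma=0.0, block_scaling="none")
        desc = fl.assemble_descriptors(mols, config)
        pts = desc.grid.points()
        for j in [0, 7, desc.X.shape[1] - 1, desc.X.shape[1] // 2]:
            fname = desc.column_field[j]
            q = pts[desc.column_point[j]]
            for i, mol in enumerate(mols):
                assert desc.X[i, j] == pytest.approx(
                    fl.similarity_index(mol, q, fname, config), rel=1e-10, abs=1e-12
                )

    def test_block_scaling_equalizes_variance(self, synth_molecules):
        desc = fl.assemble_descriptors(synth_molecules, fl.FieldConfig(spacing=4.0, margin=2.0))
        for name in FIELD_NAMES:
            cols = desc.columns_of(name)
            if cols.size:
                total = desc.X[:, cols].var(axis=0, ddof=0).sum()
                assert total == pytest.approx(1.0, rel=1e-9)

    def test_variance_filter_consistent_bookkeeping(self, synth_molecules):
        desc = fl.assemble_descriptors(synth_molecules, fl.FieldConfig(spacing=4.0, margin=2.0))
        assert desc.X.shape[1] == len(desc.column_field) == len(desc.column_point)
        for name in FIELD_NAMES:
            kept = desc.blocks[name].kept_columns
            assert set(desc.column_point[desc.columns_of(name)]) == set(kept.tolist())

    def test_all_columns_dropped_errors(self):
        mols = [point_molecule([[0, 0, 0]], cid=f"M{i}") for i in range(3)]
        with pytest.raises(ConfigurationError):
            fl.assemble_descriptors(mols, fl.FieldConfig(column_drop_sigma=1e9))

    def test_rigid_motion_equivariance(self, synth_molecules):
        # move molecules and grid together: descriptors unchanged
        config = fl.FieldConfig(spacing=4.0, margin=2.0, column_drop_sigma=0.0)
        mols = synth_molecules[:4]
        grid = fl.build_grid(mols, config)
        shift = np.array([3.7, -1.2, 0.4])
        moved = [m.translated(shift) for m in mols]
        for name in ("S", "E"):
            a = fl.field_matrix(mols, grid, name, config)
            b = fl.field_matrix(moved, grid.translated(shift), name, config)
            assert np.max(np.abs(a - b)) < 1e-9


class TestGridExport:
    def test_cube_round_trip_values(self, tmp_path, rng):
        grid = fl.Grid(origin=np.zeros(3), shape=(3, 4, 2), spacing=2.0)
        values = rng.normal(size=grid.n_points)
        path = tmp_path / "f.cube"
        fl.write_cube(grid, values, path)
        lines = path.read_text().splitlines()
        assert int(lines[3].split()[0]) == 3
        flat = [float(tok) for line in lines[6:] for tok in line.split()]
        assert np.allclose(flat, values, atol=1e-4)

    def test_dx_header(self, tmp_path):
        grid = fl.Grid(origin=np.array([1.0, 2.0, 3.0]), shape=(2, 2, 2), spacing=1.5)
        path = tmp_path / "f.dx"
        fl.write_dx(grid, np.zeros(8), path)
        text = path.read_text()
        assert "gridpositions counts 2 2 2" in text
        assert "origin 1.000000 2.000000 3.000000" in text
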
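import math
import warnings

import numpy as np
import pandas as pd
import pytest

import transelect as ts
from transelect.constants import R_KCAL, vdw_radius
from transelect.descriptors import VBUR_RADII_SCALE, VBUR_SPHERE_RADIUS
from transelect.io import QMFeatures, ValidationError


def _random_rigid_transform(rng):
    A = rng.standard_normal((3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    t = rng.uniform(-5, 5, 3)
    return Q, t


class TestSimpleFeaturizations:
    def test_ohe_is_identity_patterned(self):
        table = ts.build_ohe(["a", "b"])
        np.testing.assert_array_equal(table.values, np.eye(2))
        assert ts.build_ohe(["solo"]).values.tolist() == [[1.0]]
        with pytest.raises(ValidationError):
            ts.build_ohe(["a", "a"])

    def test_ohe_unseen_substrate_is_all_zero(self):
        from transelect.descriptors import ohe_row

        table = ts.build_ohe(["a", "b"])
        np.testing.assert_array_equal(ohe_row(table, "a"), [1.0, 0.0])
        np.testing.assert_array_equal(ohe_row(table, "never-seen"), [0.0, 0.0])

    def test_fingerprint_deterministic_and_discriminating(self):
        fp1 = ts.compute_fingerprint("CC(C)=O", 2, 2048)   # acetone
        fp2 = ts.compute_fingerprint("CC(C)=O", 2, 2048)
        fp3 = ts.compute_fingerprint("CCC(C)=O", 2, 2048)  # 2-butanone
        assert fp1.sum() >= 1
        np.testing.assert_array_equal(fp1, fp2)
        assert not np.array_equal(fp1, fp3)
        assert set(np.unique(fp1)) <= {0, 1}
        with pytest.raises(ValueError):
            ts.compute_fingerprint("not-a-smiles", 2, 2048)

    def test_physchem_molwt_against_formula_mass(self):
        # acetone C3H6O: 3*12.011 + 6*1.008 + 15.999
        feats = ts.compute_physchem("CC(C)=O")
        assert feats["MolWt"] == pytest.approx(58.08, abs=0.01)
        assert feats["RingCount"] == 0
        assert ts.compute_physchem("O=C1CCCCC1")["RingCount"] == 1

    def test_phys_table_has_no_nan_or_constant_columns(self):
        subs = [
            ts.SubstrateRecord("S1", "CC(C)=O"),
            ts.SubstrateRecord("S2", "O=C1CCCCC1"),
            ts.SubstrateRecord("S3", "CC(=O)c1ccccc1"),
        ]
        table = ts.build_phys_table(subs)
        assert np.isfinite(table.values).all()
        assert (np.ptp(table.values, axis=0) > 0).all()

    def test_phys_plus_dft_is_column_concatenation(self):
        left = ts.FeatureTable(pd.DataFrame({"a": [1.0, 2.0]}, index=["S1", "S2"]), "phys")
        right = ts.FeatureTable(pd.DataFrame({"b": [3.0, 4.0]}, index=["S1", "S2"]), "DFT")
        both = ts.FeatureTable.concat(left, right, "phys+DFT")
        assert both.feature_names == ["a", "b"]
        np.testing.assert_array_equal(both.values, [[1, 3], [2, 4]])


class TestBoltzmann:
    def test_weights_contract(self):
        np.testing.assert_allclose(ts.boltzmann_weights([0.0, 0.0], 298.15), [0.5, 0.5])
        np.testing.assert_allclose(ts.boltzmann_weights([0.0], 298.15), [1.0])
        for T in (100.0, 298.15, 400.0):
            rt_ln2 = R_KCAL * T * math.log(2)
            np.testing.assert_allclose(
                ts.boltzmann_weights([0.0, rt_ln2], T), [2 / 3, 1 / 3], atol=1e-12
            )
        with pytest.raises(ValueError):
            ts.boltzmann_weights([], 298.15)

    def test_weights_monotone_and_t_to_zero_limit(self):
        energies = [0.0, 0.5, 1.0, 3.0]
        w = ts.boltzmann_weights(energies, 298.15)
        assert np.all(np.diff(w) < 0)
        w_cold = ts.boltzmann_weights(energies, 1e-3)
        assert w_cold[0] == pytest.approx(1.0, abs=1e-12)

    def test_average_equals_direct_summation_oracle(self, rng):
        values = rng.standard_normal((5, 7))
        w = ts.boltzmann_weights(
            np.concatenate([[0.0], np.sort(rng.uniform(0, 2, 4))]), 298.15
        )
        oracle = sum(wi * vi for wi, vi in zip(w, values))
        np.testing.assert_allclose(ts.boltzmann_average(values, w), oracle, atol=1e-12)
        np.testing.assert_allclose(
            ts.boltzmann_average([[2.0], [4.0]], [0.5, 0.5]), [3.0]
        )
        np.testing.assert_allclose(
            ts.boltzmann_average(values[:2], [1.0, 0.0]), values[0]
        )
        with pytest.raises(ValueError):
            ts.boltzmann_average(values, [1.0])


class TestSterimol:
    def test_single_atom_closed_form(self, toy_single_substituent):
        ens, _ = toy_single_substituent
        sv = ts.compute_sterimol(ens.elements, ens.coordinates[0], 0, 1)
        assert sv.L == pytest.approx(1.09 + 1.20, abs=1e-9)
        assert sv.B1 == pytest.approx(1.20, abs=1e-9)
        assert sv.B5 == pytest.approx(1.20, abs=1e-9)

    def test_ethyl_longer_than_methyl_and_b1_le_b5(self, toy_methyl_ketone):
        ens, rec = toy_methyl_ketone
        # methyl side (alpha 3) vs tert-butyl side (alpha 2) of pinacolone
        methyl = ts.compute_sterimol(ens.elements, ens.coordinates[0], 0, 3)
        tbu = ts.compute_sterimol(ens.elements, ens.coordinates[0], 0, 2)
        assert tbu.L > methyl.L
        assert methyl.B1 <= methyl.B5 and tbu.B1 <= tbu.B5

    def test_methyl_against_dense_scan_oracle(self, toy_methyl_ketone):
        """B1/B5 from a 0.01-degree brute-force direction scan agree with the
        1-degree production scan to < 0.1 angstrom; L against direct formula."""
        ens, _ = toy_methyl_ketone
        elements, coords = ens.elements, ens.coordinates[0]
        sv = ts.compute_sterimol(elements, coords, 0, 3)
        # oracle: substituent = the three H atoms of the alpha-methyl (16,17,18)
        sub = [3, 16, 17, 18]
        axis = coords[3] - coords[0]
        axis = axis / np.linalg.norm(axis)
        rel = coords[sub] - coords[0]
        radii = np.array([vdw_radius(elements[a]) for a in sub])
        proj = rel @ axis
        assert sv.L == pytest.approx(np.max(proj + radii), abs=1e-9)
        perp = rel - np.outer(proj, axis)
        e1 = np.array([0.0, 0.0, 1.0])
        e1 = e1 - (e1 @ axis) * axis
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(axis, e1)
        thetas = np.deg2rad(np.arange(0, 360, 0.01))
        dirs = np.outer(np.cos(thetas), e1) + np.outer(np.sin(thetas), e2)
        widths = np.max(dirs @ perp.T + radii[None, :], axis=1)
        assert sv.B1 == pytest.approx(widths.min(), abs=0.1)
        assert sv.B5 == pytest.approx(widths.max(), abs=0.1)

    def test_rigid_motion_invariance(self, toy_methyl_ketone, rng):
        ens, _ = toy_methyl_ketone
        ref = ts.compute_sterimol(ens.elements, ens.coordinates[0], 0, 2)
        for _ in range(5):
            Q, t = _random_rigid_transform(rng)
            moved = ens.coordinates[0] @ Q.T + t
            sv = ts.compute_sterimol(ens.elements, moved, 0, 2)
            assert sv.L == pytest.approx(ref.L, abs=1e-6)
            assert sv.B1 == pytest.approx(ref.B1, abs=1e-6)
            assert sv.B5 == pytest.approx(ref.B5, abs=1e-6)

    def test_empty_substituent_rejected(self):
        # two bonded atoms, dummy on the far side: fine; unbonded pair: error
        elements = ("C", "H")
        coords = np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]])
        with pytest.raises(ValueError):
            ts.compute_sterimol(elements, coords, 0, 1)


class TestBuriedVolume:
    def test_empty_environment_is_zero_with_warning(self):
        elements = ("C", "H")
        coords = np.array([[0.0, 0.0, 0.0], [50.0, 0.0, 0.0]])
        with pytest.warns(UserWarning, match="V_bur = 0"):
            assert ts.compute_buried_volume(elements, coords, 0) == 0.0

    def test_fully_contained_atom_matches_analytic_ratio(self):
        """A single sphere of radius r centered at the probe center buries
        exactly (r/R)^3; grid agrees with a 1e6-point Monte-Carlo oracle."""
        elements = ("C", "H")
        coords = np.zeros((2, 3))  # H sphere centered at the probe center
        r = vdw_radius("H") * VBUR_RADII_SCALE
        R = VBUR_SPHERE_RADIUS
        got = ts.compute_buried_volume(elements, coords, 0)
        assert got == pytest.approx((r / R) ** 3, abs=0.005)

        rng = np.random.default_rng(4)
        pts = rng.uniform(-R, R, size=(4_000_000, 3))
        pts = pts[np.einsum("ij,ij->i", pts, pts) <= R * R][:1_000_000]
        mc = np.mean(np.einsum("ij,ij->i", pts, pts) <= r * r)
        assert got == pytest.approx(mc, abs=0.005)

    def test_grid_refinement_stable(self):
        elements = ("C", "H", "C")
        coords = np.array([[0.0, 0.0, 0.0], [1.0, 0.2, -0.3], [2.0, 1.0, 0.5]])
        coarse = ts.compute_buried_volume(elements, coords, 0, grid_step=0.05)
        fine = ts.compute_buried_volume(elements, coords, 0, grid_step=0.025)
        assert abs(coarse - fine) < 0.005

    def test_in_unit_interval_and_monotone_under_added_atom(self, rng):
        elements = ["C"] + ["C"] * 4
        coords = np.vstack([np.zeros(3), rng.uniform(-2.5, 2.5, (4, 3))])
        partial = ts.compute_buried_volume(elements[:4], coords[:4], 0)
        full = ts.compute_buried_volume(elements, coords, 0)
        assert 0.0 <= partial <= full <= 1.0


class TestAlphaRoles:
    def test_bulky_side_is_large(self, toy_methyl_ketone):
        ens, rec = toy_methyl_ketone
        assignment = ts.assign_alpha_roles(rec, ens)
        assert assignment.large_alpha_index == 2   # tert-butyl carbon
        assert assignment.small_alpha_index == 3   # methyl carbon
        assert assignment.vbur_large > assignment.vbur_small

    def test_symmetric_tie_breaks_to_lower_index_with_warning(
        self, toy_symmetric_ketone
    ):
        ens, rec = toy_symmetric_ketone
        with pytest.warns(UserWarning, match="tie"):
            assignment = ts.assign_alpha_roles(rec, ens)
        assert assignment.large_alpha_index == min(rec.alpha_atom_indices)
        assert assignment.vbur_large == pytest.approx(assignment.vbur_small, abs=1e-9)

    def test_alpha_order_permutation_invariance(self, toy_methyl_ketone):
        ens, rec = toy_methyl_ketone
        import dataclasses

        swapped = dataclasses.replace(
            rec, alpha_atom_indices=rec.alpha_atom_indices[::-1]
        )
        a = ts.assign_alpha_roles(rec, ens)
        b = ts.assign_alpha_roles(swapped, ens)
        assert (a.large_alpha_index, a.small_alpha_index) == (
            b.large_alpha_index,
            b.small_alpha_index,
        )

    def test_missing_alpha_indices_rejected(self, toy_single_substituent):
        ens, rec = toy_single_substituent
        with pytest.raises(ValueError):
            ts.assign_alpha_roles(rec, ens)


class TestAssembleDft:
    @staticmethod
    def _toy_inputs(swap_alpha=False):
        subs = [
            ts.SubstrateRecord("S1", "CC(C)=O", carbonyl_atom_index=0,
                               alpha_atom_indices=(2, 3) if not swap_alpha else (3, 2)),
            ts.SubstrateRecord("S2", "CCC(C)=O", carbonyl_atom_index=0,
                               alpha_atom_indices=(2, 3) if not swap_alpha else (3, 2)),
        ]
        qm = {}
        rng = np.random.default_rng(9)
        for sid in ("S1", "S2"):
            qm[sid] = QMFeatures(
                molecule={f"m{j}": rng.normal() for j in range(3)},
                atoms={a: {f"q{j}": rng.normal() for j in range(4)} for a in (0, 2, 3)},
            )
        assignments = {
            sid: ts.AlphaRoleAssignment(2, 3, 0.5, 0.3) for sid in ("S1", "S2")
        }
        sterimol = {
            sid: {
                role: ts.SterimolValues(
                    L=2.0 + rng.uniform(), B1=1.0 + rng.uniform() / 10,
                    B5=2.5 + rng.uniform()
                )
                for role in ("large", "small")
            }
            for sid in ("S1", "S2")
        }
        return subs, qm, assignments, sterimol

    def test_column_arithmetic(self):
        subs, qm, assignments, sterimol = self._toy_inputs()
        table = ts.assemble_dft_features(qm, subs, assignments, sterimol)
        # 3 molecule + 3x4 atom (carbonyl, large, small) + 2x3 Sterimol = 21
        assert len(table.feature_names) == 21
        assert table.substrate_ids == ["S1", "S2"]
        assert table.tag == "DFT"

    def test_alpha_swap_leaves_table_unchanged(self):
        subs, qm, assignments, sterimol = self._toy_inputs()
        subs_sw, _, _, _ = self._toy_inputs(swap_alpha=True)
        a = ts.assemble_dft_features(qm, subs, assignments, sterimol)
        b = ts.assemble_dft_features(qm, subs_sw, assignments, sterimol)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_missing_reaction_site_features_named(self):
        subs, qm, assignments, sterimol = self._toy_inputs()
        del qm["S2"].atoms[3]
        with pytest.raises(ValidationError, match="S2"):
            ts.assemble_dft_features(qm, subs, assignments, sterimol)

    def test_single_conformer_average_is_identity(self, toy_symmetric_ketone):
        ens, rec = toy_symmetric_ketone
        sv_avg = ts.boltzmann_averaged_sterimol(rec, ens, rec.alpha_atom_indices[0])
        sv_raw = ts.compute_sterimol(
            ens.elements, ens.coordinates[0], rec.carbonyl_atom_index,
            rec.alpha_atom_indices[0],
        )
        assert (sv_avg.L, sv_avg.B1, sv_avg.B5) == pytest.approx(
            (sv_raw.L, sv_raw.B1, sv_raw.B5), abs=1e-12
        )
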
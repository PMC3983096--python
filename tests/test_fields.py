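"""Grid construction, CoMFA/CoMSIA field values and the descriptor matrix."""

import math

import numpy as np
import pytest

from qsar3d import (build_descriptor_matrix, build_grid, comfa_field,
                    comsia_field, default_scenario, generate_set)
from qsar3d.dataset import Atom, CompoundRecord
from qsar3d.fields import GridSpec
from qsar3d.params import COULOMB_CONSTANT, lj_params, vdw_radius


def atom(element="C", xyz=(0, 0, 0), charge=0.0, hydro=0.0,
         donor=False, acceptor=False):
    return Atom(element=element, coords=np.array(xyz, dtype=float),
                charge=charge, radius=vdw_radius(element),
                hydrophobicity=hydro, donor=donor, acceptor=acceptor)


def compound(atoms, cid="x"):
    return CompoundRecord(id=cid, atoms=list(atoms))


class TestBuildGrid:
    def test_box_plus_margin_discretised(self):
        c = compound([atom(xyz=(0, 0, 0)), atom(xyz=(4, 4, 4))])
        spec = build_grid([c], spacing=2.0, margin=4.0)
        assert spec.dims == (7, 7, 7)
        assert spec.origin == (-4.0, -4.0, -4.0)

    def test_single_atom(self):
        spec = build_grid([compound([atom()])], spacing=2.0, margin=2.0)
        assert spec.dims == (3, 3, 3)

    def test_zero_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            build_grid([compound([atom()])], spacing=0.0)

    def test_shared_grid_encloses_every_compound(self):
        comps, _, _ = generate_set(default_scenario(n_compounds=20, seed=3))
        spec = build_grid(comps, spacing=2.0, margin=4.0)
        hi = np.array(spec.origin) + spec.spacing * (np.array(spec.dims) - 1)
        for c in comps:
            assert np.all(c.coords >= np.array(spec.origin) - 1e-9)
            assert np.all(c.coords <= hi + 1e-9)


def point_grid(xyz):
    """1-point grid centred at xyz (probes a single location)."""
    return GridSpec(origin=tuple(float(v) for v in xyz), spacing=1.0,
                    dims=(1, 1, 1))


class TestComfaField:
    def test_lj_decays_to_zero_far_away(self):
        f = comfa_field(compound([atom()]), point_grid((50, 0, 0)), kind="steric")
        assert abs(f.values[0]) < 1e-6

    def test_truncation_at_atom_centre(self):
        f = comfa_field(compound([atom()]), point_grid((0, 0, 0)), kind="steric")
        assert f.values[0] == 30.0

    def test_lj_minimum_depth_at_equilibrium_distance(self):
        rstar_c, eps_c = lj_params("C")
        f = comfa_field(compound([atom()]), point_grid((2 * rstar_c, 0, 0)),
                        kind="steric")
        assert f.values[0] == pytest.approx(-eps_c, rel=1e-10)

    def test_zero_charges_give_zero_electrostatics(self):
        c = compound([atom(xyz=(0, 0, 0)), atom(xyz=(2, 0, 0))])
        spec = build_grid([c], spacing=2.0, margin=2.0)
        f = comfa_field(c, spec, kind="electrostatic")
        np.testing.assert_array_equal(f.values, 0.0)

    def test_coulomb_with_distance_dielectric(self):
        c = compound([atom(charge=-0.5)])
        f = comfa_field(c, point_grid((4, 0, 0)), kind="electrostatic")
        assert f.values[0] == pytest.approx(COULOMB_CONSTANT * -0.5 / 16, rel=1e-12)

    def test_truncation_bounds_everywhere(self):
        comps, _, _ = generate_set(default_scenario(n_compounds=10, seed=9))
        spec = build_grid(comps, spacing=1.0, margin=2.0)
        for c in comps:
            for kind in ("steric", "electrostatic"):
                f = comfa_field(c, spec, kind=kind)
                assert np.all(np.abs(f.values) <= 30.0)


class TestComsiaField:
    def test_minus_one_at_atom_centre(self):
        # unit property, probe weight +1, exp(0) = 1, leading minus sign
        c = compound([atom(charge=1.0)])
        f = comsia_field(c, point_grid((0, 0, 0)), prop="electrostatic")
        assert f.values[0] == pytest.approx(-1.0, abs=1e-12)

    def test_gaussian_at_one_angstrom(self):
        c = compound([atom(charge=1.0)])
        f = comsia_field(c, point_grid((1, 0, 0)), prop="electrostatic")
        assert f.values[0] == pytest.approx(-math.exp(-0.3), abs=1e-10)

    def test_negligible_at_ten_angstrom(self):
        c = compound([atom(charge=1.0)])
        f = comsia_field(c, point_grid((10, 0, 0)), prop="electrostatic")
        assert f.values[0] == pytest.approx(-math.exp(-30.0), rel=1e-9)
        assert abs(f.values[0]) < 1e-12

    def test_steric_property_is_radius_cubed(self):
        c = compound([atom("O")])
        f = comsia_field(c, point_grid((0, 0, 0)), prop="steric")
        assert f.values[0] == pytest.approx(-vdw_radius("O") ** 3, rel=1e-12)

    def test_donor_acceptor_indicator_weights(self):
        c = compound([atom("N", donor=True, acceptor=False)])
        at0 = point_grid((0, 0, 0))
        assert comsia_field(c, at0, prop="donor").values[0] == -1.0
        assert comsia_field(c, at0, prop="acceptor").values[0] == 0.0

    def test_bad_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            comsia_field(compound([atom()]), point_grid((0, 0, 0)), alpha=0.0)

    def test_magnitude_decreases_with_distance(self):
        c = compound([atom(charge=0.7)])
        dists = np.linspace(0, 8, 30)
        vals = [abs(comsia_field(c, point_grid((d, 0, 0)),
                                 prop="electrostatic").values[0]) for d in dists]
        assert all(a >= b - 1e-15 for a, b in zip(vals, vals[1:]))

    def test_finite_everywhere_on_dense_grid(self):
        comps, _, _ = generate_set(default_scenario(n_compounds=10, seed=11))
        spec = build_grid(comps, spacing=0.71, margin=1.0)
        for prop in ("steric", "electrostatic", "hydrophobic", "donor", "acceptor"):
            v = comsia_field(comps[0], spec, prop=prop).values
            assert np.all(np.isfinite(v))


class TestAgainstNaiveOracle:
    """Vectorised fields must agree with a plain double loop."""

    @staticmethod
    def _two_atom_compound():
        return compound([atom("C", (0.3, -0.2, 0.5), charge=0.25, hydro=0.4),
                         atom("O", (1.1, 0.8, -0.4), charge=-0.40, hydro=-0.3,
                              donor=True, acceptor=True)])

    @staticmethod
    def _grid27():
        return GridSpec(origin=(-2.0, -2.0, -2.0), spacing=2.0, dims=(3, 3, 3))

    def test_comfa_steric_matches_double_loop(self):
        c, spec = self._two_atom_compound(), self._grid27()
        got = comfa_field(c, spec, kind="steric").values
        rstar_p, eps_p = lj_params("C")
        expected = []
        for p in spec.points():
            e = 0.0
            for a in c.atoms:
                r = math.dist(p, a.coords)
                rstar_i, eps_i = lj_params(a.element)
                ratio = (rstar_i + rstar_p) / r
                e += math.sqrt(eps_i * eps_p) * (ratio ** 12 - 2 * ratio ** 6)
            expected.append(min(max(e, -30.0), 30.0))
        np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_comfa_electrostatic_matches_double_loop(self):
        c, spec = self._two_atom_compound(), self._grid27()
        got = comfa_field(c, spec, kind="electrostatic").values
        expected = []
        for p in spec.points():
            e = 0.0
            for a in c.atoms:
                r = math.dist(p, a.coords)
                e += COULOMB_CONSTANT * a.charge * 1.0 / (r * r)
            expected.append(min(max(e, -30.0), 30.0))
        np.testing.assert_allclose(got, expected, atol=1e-8)

    @pytest.mark.parametrize("prop, getter", [
        ("steric", lambda a: a.radius ** 3),
        ("electrostatic", lambda a: a.charge),
        ("hydrophobic", lambda a: a.hydrophobicity),
        ("donor", lambda a: 1.0 if a.donor else 0.0),
        ("acceptor", lambda a: 1.0 if a.acceptor else 0.0)])
    def test_comsia_matches_double_loop(self, prop, getter):
        c, spec = self._two_atom_compound(), self._grid27()
        got = comsia_field(c, spec, prop=prop).values
        expected = []
        for p in spec.points():
            s = 0.0
            for a in c.atoms:
                r2 = math.dist(p, a.coords) ** 2
                s -= 1.0 * getter(a) * math.exp(-0.3 * r2)
            expected.append(s)
        np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_joint_translation_invariance(self):
        c, spec = self._two_atom_compound(), self._grid27()
        shift = np.array([3.7, -1.2, 9.9])
        moved = c.with_coords(c.coords + shift)
        spec2 = GridSpec(origin=tuple(np.array(spec.origin) + shift),
                         spacing=spec.spacing, dims=spec.dims)
        for kind in ("steric", "electrostatic"):
            np.testing.assert_allclose(
                comfa_field(c, spec, kind=kind).values,
                comfa_field(moved, spec2, kind=kind).values, atol=1e-10)
        for prop in ("steric", "hydrophobic"):
            np.testing.assert_allclose(
                comsia_field(c, spec, prop=prop).values,
                comsia_field(moved, spec2, prop=prop).values, atol=1e-10)


class TestDescriptorMatrix:
    @staticmethod
    def _set(n=10, seed=21):
        comps, _, _ = generate_set(default_scenario(n_compounds=n, seed=seed))
        spec = build_grid(comps, spacing=2.0, margin=2.0)
        return comps, spec

    def test_column_budget_before_filtering(self):
        comps, _ = self._set()
        spec = GridSpec(origin=(-4, -4, -4), spacing=4.0, dims=(3, 3, 3))
        X = build_descriptor_matrix(comps, spec, fields="comfa",
                                    filter_sigma={"comfa_steric": 0.0,
                                                  "comfa_electrostatic": 0.0})
        assert X.n_columns + len(X.dropped) == 54  # 27 points x 2 fields

    def test_constant_columns_always_dropped(self):
        comps, spec = self._set()
        X = build_descriptor_matrix(comps, spec, fields="comsia")
        assert X.X.std(axis=0).min() > 0
        for kind, point, std in X.dropped:
            assert std == pytest.approx(0.0, abs=1e-30)

    def test_comfa_sigma_filter_enforced(self):
        comps, spec = self._set()
        X = build_descriptor_matrix(comps, spec, fields="comfa", scaling="none")
        assert X.X.std(axis=0, ddof=1).min() >= 2.0

    def test_deterministic_rows_for_identical_input(self):
        comps, spec = self._set()
        X1 = build_descriptor_matrix(comps, spec, fields="comsia")
        X2 = build_descriptor_matrix(comps, spec, fields="comsia")
        np.testing.assert_array_equal(X1.X, X2.X)

    def test_block_scaling_equalises_block_variance(self):
        comps, spec = self._set()
        X = build_descriptor_matrix(comps, spec, fields="comsia",
                                    scaling="block-standard")
        totals = [X.X[:, X.block_columns(k)].var(axis=0, ddof=1).sum()
                  for k in X.calculator.kinds]
        np.testing.assert_allclose(totals, 1.0, rtol=1e-10)

    def test_overly_strict_filter_raises(self):
        comps, spec = self._set()
        with pytest.raises(ValueError, match="filter_sigma"):
            build_descriptor_matrix(comps, spec, fields="comsia",
                                    filter_sigma={k: 1e9 for k in
                                                  ("comsia_steric",
                                                   "comsia_electrostatic",
                                                   "comsia_hydrophobic",
                                                   "comsia_donor",
                                                   "comsia_acceptor")})

    def test_transform_reproduces_training_rows(self):
        comps, spec = self._set()
        X = build_descriptor_matrix(comps, spec, fields="comsia")
        np.testing.assert_allclose(X.transform(comps), X.X, atol=1e-12)
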
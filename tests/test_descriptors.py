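import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import solvscreen as sv
from solvscreen.core_data import Category, T_AMBIENT
from solvscreen.descriptors import (FEATURE_NAMES, component_descriptor,
                                    feature_frame, mixture_descriptor,
                                    relative_contributions)

finite_e = st.floats(-4.0, 4.0)


def _comp(name, triple):
    return sv.Component(name, *triple)


class TestRelativeContributions:
    @pytest.mark.parametrize("triple,expected", [
        ((-2.0, -1.0, -1.0), (0.5, 0.25, 0.25)),
        ((-1.0, 0.0, 0.0), (1.0, 0.0, 0.0)),
    ])
    def test_forced_arithmetic(self, triple, expected):
        assert relative_contributions(_comp("c", triple)) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=60)
    @given(e1=finite_e, e2=finite_e, e3=finite_e)
    def test_sum_to_one(self, e1, e2, e3):
        if abs(e1 + e2 + e3) < 1e-6:
            return
        rel = relative_contributions(_comp("c", (e1, e2, e3)))
        assert sum(rel) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            relative_contributions(_comp("c", (1.0, -0.5, -0.5)))


class TestMixtureDescriptor:
    def test_single_component_identity(self):
        c = _comp("a", (1.0, -2.0, -1.5))
        sys_ = sv.SolventSystem([(c, 1.0)], Category.NEAT)
        assert np.allclose(mixture_descriptor(sys_).as_array(),
                           component_descriptor(c, T_AMBIENT).as_array())

    def test_equimolar_midpoint(self):
        a = _comp("a", (-0.2, -1.0, -1.0))
        b = _comp("b", (-0.4, -1.0, -1.0))
        sys_ = sv.SolventSystem([(a, 0.5), (b, 0.5)], Category.BINARY)
        assert mixture_descriptor(sys_).e_misfit_abs == pytest.approx(-0.3)

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(0, 10_000), st.floats(0.05, 0.95))
    def test_linear_in_composition(self, seed, f):
        rng = np.random.RandomState(seed)
        trip = lambda: tuple(rng.uniform(-3, -0.5, 3))
        a, b = _comp("a", trip()), _comp("b", trip())
        sys_ = sv.SolventSystem([(a, f), (b, 1.0 - f)], Category.BINARY)
        da = component_descriptor(a, T_AMBIENT).as_array()
        db = component_descriptor(b, T_AMBIENT).as_array()
        assert np.allclose(mixture_descriptor(sys_).as_array(),
                           f * da + (1.0 - f) * db, atol=1e-12)

    def test_mixture_rel_descriptors_sum_to_one(self, world):
        for rec in world["records"][::13]:
            d = mixture_descriptor(rec.system)
            assert d.e_misfit_rel + d.e_hb_rel + d.e_vdw_rel == pytest.approx(1.0, abs=1e-9)

    def test_recompute_mode_differs_but_normalized(self):
        # totals differ (-2.0 vs -2.5); with equal totals the two modes coincide
        a = _comp("a", (2.0, -3.0, -1.0))
        b = _comp("b", (0.5, -0.5, -2.5))
        sys_ = sv.SolventSystem([(a, 0.3), (b, 0.7)], Category.BINARY)
        lin = mixture_descriptor(sys_, mixing="linear")
        rec = mixture_descriptor(sys_, mixing="recompute")
        assert rec.e_misfit_rel + rec.e_hb_rel + rec.e_vdw_rel == pytest.approx(1.0)
        assert lin.e_misfit_rel != pytest.approx(rec.e_misfit_rel)

    def test_bad_fraction_sum_rejected(self):
        a, b = _comp("a", (1, -2, -1)), _comp("b", (1, -2, -1))
        with pytest.raises(ValueError, match="sum to 1"):
            mixture_descriptor([(a, 0.4), (b, 0.4)], temperature=298.15)


class TestFeatureMatrix:
    def test_shape_and_targets(self, world):
        x, y = world["x"], world["y"]
        assert x.shape == (160, 7)
        assert np.allclose(10.0 ** y,
                           [r.x_solute for r in world["records"]])

    def test_temperature_column(self, world):
        # the one cold-water record carries its own temperature
        temps = x7 = world["x"][:, 6]
        assert np.isclose(temps, 287.65).sum() == 1
        assert np.isclose(temps, 298.15).sum() == 159

    def test_shuffle_permutes_rows(self, world):
        rng = np.random.RandomState(0)
        perm = rng.permutation(len(world["records"]))
        x2, y2 = sv.build_feature_matrix([world["records"][i] for i in perm])
        assert np.allclose(x2, world["x"][perm])
        assert np.allclose(y2, world["y"][perm])

    def test_missing_energies_reported(self):
        bare = sv.Component("mystery")  # all-zero triple == missing
        sys_ = sv.SolventSystem([(bare, 1.0)], Category.NEAT)
        rec = sv.SolubilityRecord(sys_, 1e-3)
        with pytest.raises(ValueError, match="mystery"):
            sv.build_feature_matrix([rec])

    def test_feature_frame_columns(self, world):
        df = feature_frame(world["records"][:5])
        assert list(df.columns) == FEATURE_NAMES + ["log10_x"]
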
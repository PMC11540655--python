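"""Kinematic insertion rule, stiffening operators and procedure orchestration."""

import numpy as np
import pytest

import brachysim as bs
from brachysim.constitutive import MaterialField
from brachysim.errors import InputError
from brachysim.insertion import (InsertionConfig, SolverConfig, _SolverContext,
                                 advance_needle, apply_anchor_stiffening,
                                 apply_catheter_stiffening, bore_nodes,
                                 run_procedure, tip_influence)
from brachysim.phantom import REGION_PROSTATE, REGION_SURROUNDING, Needle


@pytest.fixture(scope="module")
def needle():
    return Needle(entry_point=(10.0, 10.0, 0.0), direction=(0, 0, 1),
                  insertion_depth=20.0, radius=0.75, kind="catheter", order_index=0)


@pytest.fixture(scope="module")
def cfg():
    return InsertionConfig()  # R_inf = 3 mm, linear decay, factor 30


@pytest.fixture(scope="module")
def tiny_domain():
    return bs.generate_phantom(bs.PhantomSpec(
        prostate_semi_axes=(12.0, 9.0, 9.0), block_dims=(33, 33, 33),
        nodal_spacing=3.0))


class TestTipInfluence:
    def test_zero_beyond_influence_radius(self, needle, cfg):
        w = tip_influence(np.array([[14.0, 10.0, 10.0]]), needle, 15.0, cfg)
        assert w[0] == 0.0

    def test_full_weight_on_axis_near_tip(self, needle, cfg):
        # on the axis, inside the trailing tip window
        w = tip_influence(np.array([[10.0, 10.0, 14.0]]), needle, 15.0, cfg)
        assert w[0] == 1.0

    def test_zero_on_axis_far_behind_tip(self, needle, cfg):
        # penetrated long ago; the tip has moved on
        w = tip_influence(np.array([[10.0, 10.0, 2.0]]), needle, 15.0, cfg)
        assert w[0] == 0.0

    def test_linear_radial_profile(self, needle, cfg):
        tip_depth = 15.0
        radii = np.linspace(0.1, 3.5, 20)
        pts = np.column_stack([10.0 + radii, np.full(20, 10.0),
                               np.full(20, tip_depth)])
        w = tip_influence(pts, needle, tip_depth, cfg)
        R, a = cfg.influence_radius, needle.radius
        expected = np.clip((R - radii) / (R - a), 0.0, 1.0)
        expected[radii > R] = 0.0
        assert np.allclose(w, expected)
        assert np.all(np.diff(w) <= 1e-12)  # non-increasing in r

    def test_exponential_profile_monotone(self, needle):
        cfg = InsertionConfig(decay="exponential")
        radii = np.linspace(0.8, 3.0, 15)
        pts = np.column_stack([10.0 + radii, np.full(15, 10.0), np.full(15, 10.0)])
        w = tip_influence(pts, needle, 10.0, cfg)
        assert np.all(np.diff(w) <= 1e-12)
        assert w[0] <= 1.0 and w[-1] >= 0.0

    def test_invalid_parameters_rejected(self, needle, cfg):
        with pytest.raises(InputError):
            tip_influence(np.zeros((1, 3)), needle, 25.0, cfg)  # beyond full depth
        with pytest.raises(InputError):
            InsertionConfig(increment=-1.0)
        with pytest.raises(InputError):
            InsertionConfig(decay="cubic")
        thick = Needle((0, 0, 0), (0, 0, 1), 10.0, 5.0, "catheter", 0)
        with pytest.raises(InputError):
            tip_influence(np.zeros((1, 3)), thick, 5.0, cfg)


class TestStiffening:
    def test_anchor_stiffening_gates_on_region_and_halfspace(self, tiny_domain, cfg):
        field = MaterialField.from_domain(tiny_domain)
        anchors = [Needle((15.0, 15.0, 0.0), (0, 0, 1), 18.0, 0.5, "anchor", 0),
                   Needle((18.0, 15.0, 0.0), (0, 0, 1), 18.0, 0.5, "anchor", 1)]
        apply_anchor_stiffening(field, anchors, tiny_domain, cfg)
        z = tiny_domain.ip_coords[:, 2]
        distal_surround = (z > 18.0) & (tiny_domain.ip_region == REGION_SURROUNDING)
        assert np.all(field.scale[distal_surround] == 30.0)
        # prostate points and proximal points are never modified
        assert np.all(field.scale[tiny_domain.ip_region == REGION_PROSTATE] == 1.0)
        assert np.all(field.scale[z <= 18.0] == 1.0)

    def test_anchor_stiffening_idempotent(self, tiny_domain, cfg):
        field = MaterialField.from_domain(tiny_domain)
        anchors = [Needle((15.0, 15.0, 0.0), (0, 0, 1), 18.0, 0.5, "anchor", 0)]
        apply_anchor_stiffening(field, anchors, tiny_domain, cfg)
        snap = field.scale.copy()
        apply_anchor_stiffening(field, anchors, tiny_domain, cfg)
        assert np.array_equal(field.scale, snap)

    def test_catheter_stiffening_tube_and_max_composition(self, tiny_domain, cfg):
        field = MaterialField.from_domain(tiny_domain)
        c1 = Needle((15.0, 15.0, 0.0), (0, 0, 1), 28.0, 0.75, "catheter", 0)
        c2 = Needle((16.5, 15.0, 0.0), (0, 0, 1), 28.0, 0.75, "catheter", 1)
        apply_catheter_stiffening(field, c1, tiny_domain, cfg)
        n1 = int((field.scale > 1).sum())
        apply_catheter_stiffening(field, c2, tiny_domain, cfg)
        n2 = int((field.scale > 1).sum())
        assert n2 >= n1  # stiffened set grows monotonically
        # overlapping tubes saturate at 30, never 900
        assert field.scale.max() == 30.0
        # points far from both paths unchanged
        r1 = np.linalg.norm(tiny_domain.ip_coords[:, :2] - [15.0, 15.0], axis=1)
        far = r1 > 10.0
        assert np.all(field.scale[far] == 1.0)


class TestAdvanceNeedle:
    def test_zero_advance_is_identity(self, tiny_domain, cfg, needle):
        st = bs.build_shape_table(tiny_domain)
        field = MaterialField.from_domain(tiny_domain)
        ctx = _SolverContext(tiny_domain, st, field, SolverConfig()).refresh()
        state = bs.SimState.zeros(tiny_domain.n_nodes,
                                  fixed=tiny_domain.boundary_sets["fixed_external"])
        full = Needle((15.0, 15.0, 0.0), (0, 0, 1), 10.0, 0.75, "catheter", 0)
        out, rep, depth = advance_needle(state, full, 10.0, 2.0, cfg, ctx, {})
        assert depth == 10.0
        assert rep.converged and rep.iterations == 0
        assert np.abs(out.u).max() == 0.0

    def test_bore_nodes_stay_prescribed_after_advance(self, tiny_domain, cfg):
        st = bs.build_shape_table(tiny_domain)
        field = MaterialField.from_domain(tiny_domain)
        ctx = _SolverContext(tiny_domain, st, field,
                             SolverConfig(max_iter=500)).refresh()
        state = bs.SimState.zeros(tiny_domain.n_nodes,
                                  fixed=tiny_domain.boundary_sets["fixed_external"])
        ndl = Needle((15.0, 15.0, 0.0), (0, 0, 1), 12.0, 0.75, "catheter", 0)
        bore = {}
        state, _, depth = advance_needle(state, ndl, 0.0, 4.0, cfg, ctx, bore)
        expected = set(bore_nodes(tiny_domain, ndl, depth).tolist()) - set(
            tiny_domain.boundary_sets["fixed_external"].tolist())
        assert expected <= set(state.prescribed_idx.tolist())
        assert set(bore) == expected


class TestRunProcedure:
    def test_empty_plan_gives_initial_snapshot_only(self, tiny_domain, cfg):
        plan = bs.NeedlePlan([])
        res = run_procedure(tiny_domain, plan, cfg, SolverConfig(max_iter=200))
        assert len(res.snapshots) == 1
        assert np.abs(res.snapshots[0].u).max() == 0.0

    def test_small_procedure_snapshot_bookkeeping(self, tiny_domain):
        plan = bs.generate_needle_plan(tiny_domain, n_anchor=1, n_catheter=1,
                                       template_pitch=4.0)
        cfg = InsertionConfig(increment=3.0)
        res = run_procedure(tiny_domain, plan, cfg, SolverConfig(max_iter=1000))
        assert res.errors == []
        assert len(res.snapshots) == len(plan) + 1
        assert res.labels() == ["initial", "anchor_1", "catheter_1"]
        # displacement accumulates and the peak sits near a needle path
        assert np.abs(res.final.u).max() > 0.5
        # anchor stiffening applied after the single anchor
        assert res.material_field.scale.max() == 30.0
        with pytest.raises(KeyError):
            res.snapshot("catheter_9")
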
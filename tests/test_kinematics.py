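"""Texture estimators, the deformation-rate balance and patch machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from epimorph.cellgraph import Lineage, build_adjacency
from epimorph.kinematics import (
    geometric_rate,
    lagrangian_patches,
    measure_interframe,
    patch_weights,
    reciprocal_condition,
    shape_rate,
    sliding_time_average,
    stress_weights,
    texture,
    topological_rate,
)
from epimorph.tensors import tensor_norm
from tests.conftest import block_grid, trivial_lineage_df


def star_links(angles, lengths=1.0):
    angles = np.asarray(angles, dtype=float)
    lengths = np.broadcast_to(lengths, angles.shape)
    return np.stack([lengths * np.cos(angles), lengths * np.sin(angles)], 1)


class TestTexture:
    def test_isotropic_star_has_unit_reciprocal_condition(self):
        m, n = texture(star_links([0, np.pi / 3, 2 * np.pi / 3]))
        assert n == 3
        assert reciprocal_condition(m) == pytest.approx(1.0)

    def test_parallel_links_are_degenerate(self):
        m, _ = texture(star_links([0.4, 0.4, 0.4]))
        assert reciprocal_condition(m) == pytest.approx(0.0, abs=1e-12)

    def test_two_orthogonal_links(self):
        m, _ = texture(np.array([[2.0, 0.0], [0.0, 1.0]]))
        assert np.allclose(m, np.diag([2.0, 0.5]))

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            texture(np.empty((0, 2)))


class TestGeometricRate:
    def test_affine_map_recovered_in_cayley_form(self):
        rng = np.random.default_rng(0)
        l0 = rng.normal(size=(40, 2))
        f = np.array([[1.03, 0.01], [0.02, 0.98]])
        l1 = l0 @ f.T
        dt = 0.25
        g, om = geometric_rate(l0, l1, dt)
        L = 2.0 * (f - np.eye(2)) @ np.linalg.inv(f + np.eye(2)) / dt
        assert np.allclose(g.as_matrix(), 0.5 * (L + L.T), atol=1e-12)
        assert om == pytest.approx(0.5 * (L[1, 0] - L[0, 1]), abs=1e-12)

    def test_constant_rate_map_recovered_to_third_order(self):
        rng = np.random.default_rng(1)
        l0 = rng.normal(size=(40, 2))
        L = np.array([[0.02, 0.005], [0.005, -0.013]])
        dt = 1.0
        l1 = l0 @ expm(L * dt).T
        g, _ = geometric_rate(l0, l1, dt)
        # Cayley vs exponential discretization differ at O((L dt)^3 / 12)
        assert np.allclose(g.as_matrix(), L, atol=3e-6)

    def test_pure_rotation_gives_omega_and_no_strain(self):
        l0 = star_links(np.linspace(0, np.pi, 9, endpoint=False), 2.0)
        phi = 0.05
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        g, om = geometric_rate(l0, l0 @ rot.T, dt=1.0)
        assert tensor_norm(g) == pytest.approx(0.0, abs=1e-14)
        assert om == pytest.approx(phi, abs=phi**3)

    def test_degenerate_links_give_missing(self):
        l0 = star_links([0.2, 0.2])
        g, om = geometric_rate(l0, l0, dt=1.0)
        assert g is None and om is None


class TestShapeRate:
    def test_static_textures_give_zero(self):
        m, _ = texture(star_links([0, 1, 2], 1.5))
        s = shape_rate(m, m, dt=1.0)
        assert tensor_norm(s) == pytest.approx(0.0, abs=1e-14)

    def test_affine_equals_geometric_rate_to_machine_precision(self):
        # a stretch that does not commute with the (anisotropic) texture
        rng = np.random.default_rng(2)
        l0 = rng.normal(size=(30, 2)) @ np.diag([2.0, 0.7])
        f = np.array([[1.05, 0.02], [0.02, 0.96]])
        l1 = l0 @ f.T
        dt = 0.5
        g, _ = geometric_rate(l0, l1, dt)
        m0, _ = texture(l0)
        m1, _ = texture(l1)
        s = shape_rate(m0, m1, dt)
        assert np.allclose(s.as_matrix(), g.as_matrix(), atol=1e-12)

    def test_degenerate_texture_gives_missing(self):
        m, _ = texture(star_links([0.3, 0.3]))
        assert shape_rate(m, m, 1.0) is None


class TestTopologicalRate:
    def test_no_events_give_zero(self):
        m = np.eye(2)
        p = topological_rate(np.empty((0, 2)), np.empty((0, 2)), 10, 10, m, 1.0)
        assert tensor_norm(p) == pytest.approx(0.0, abs=1e-14)

    def test_symmetric_t1_elongates_along_disappeared_axis(self):
        # a T1 quartet extends along the axis of the disappearing link:
        # link along y disappears, link along x appears
        m = 1.0 * np.eye(2)
        app = np.array([[np.sqrt(2), 0.0], [-np.sqrt(2), 0.0]])
        dis = np.array([[0.0, np.sqrt(2)], [0.0, -np.sqrt(2)]])
        r = topological_rate(app, dis, 20, 20, m, 1.0)
        assert r.trace == pytest.approx(0.0, abs=1e-12)
        assert r.yy > 0 > r.xx
        assert r.xy == pytest.approx(0.0, abs=1e-12)

    def test_pure_link_loss_has_negative_trace(self):
        # delamination-like: the dying cell's last links are shorter than
        # the typical link (texture M = identity <-> |l|^2 = 2)
        m = np.eye(2)
        dis = star_links(np.linspace(0, np.pi, 6, endpoint=False), 1.0)
        a = topological_rate(np.empty((0, 2)), dis, 20, 14, m, 1.0)
        assert a.trace < 0

    def test_pure_link_gain_has_positive_trace(self):
        # integration-like: a newly inserted small cell brings short links
        m = np.eye(2)
        app = star_links(np.linspace(0, np.pi, 6, endpoint=False), 1.0)
        n = topological_rate(app, np.empty((0, 2)), 14, 20, m, 1.0)
        assert n.trace > 0

    def test_singular_texture_gives_missing(self):
        m = np.array([[1.0, 0.0], [0.0, 0.0]])
        assert topological_rate(np.ones((1, 2)), np.empty((0, 2)), 5, 6, m, 1.0) is None


class TestUnits:
    def test_rates_scale_inversely_with_dt(self):
        rng = np.random.default_rng(3)
        l0 = rng.normal(size=(25, 2))
        l1 = l0 @ np.diag([1.04, 0.97])
        g1, o1 = geometric_rate(l0, l1, dt=1.0)
        g3, o3 = geometric_rate(l0, l1, dt=3.0)
        assert np.allclose(g1.as_matrix(), 3.0 * g3.as_matrix())
        assert o1 == pytest.approx(3.0 * o3)
        m0, _ = texture(l0)
        m1, _ = texture(l1)
        assert np.allclose(
            shape_rate(m0, m1, 1.0).as_matrix(),
            3.0 * shape_rate(m0, m1, 3.0).as_matrix(),
        )


class TestBalanceOnFixtures:
    def test_affine_interframe_balances_exactly(self):
        """No topology: residual = G - S vanishes to machine precision."""
        rng = np.random.default_rng(4)
        n = 30
        l0 = rng.normal(size=(n, 2))
        f = np.diag([1.02, 0.99])
        l1 = l0 @ f.T
        mk = lambda frame, links: pd.DataFrame({
            "frame": frame, "c": np.arange(n), "k": np.arange(n) + 100,
            "lx": links[:, 0], "ly": links[:, 1],
            "category": "conserved", "fourfold": False, "sister": False,
        })
        rates = measure_interframe(mk(0, l0), mk(1, l1), dt=1.0)
        assert rates.residual is not None
        assert tensor_norm(rates.residual) == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(rates.G.as_matrix(), rates.S.as_matrix(), atol=1e-12)


class TestWeights:
    def test_bulk_box_weight_is_one(self):
        wa = patch_weights(np.array([1.0, 0.5, 0.0]),
                           np.array([0.8, 0.8, 0.0]),
                           np.array([True, False, False]))
        assert wa[0] == pytest.approx(1.0)
        assert wa[1] == pytest.approx(0.25)
        assert wa[2] == 0.0

    def test_no_bulk_raises(self):
        with pytest.raises(ValueError):
            patch_weights(np.ones(3), np.ones(3), np.zeros(3, bool))

    def test_stress_weights_use_area_only(self):
        w = stress_weights(np.array([1.0, 0.5]), np.array([True, False]))
        assert w[0] == pytest.approx(1.0)
        assert w[1] == pytest.approx(0.25)


class TestPatches:
    def test_static_membership_and_overlap(self):
        img = block_grid()
        g0 = build_adjacency(img, frame=0)
        lin = Lineage(trivial_lineage_df(range(1, 26), last_frame=3))
        patches = lagrangian_patches(g0, lin, n_frames=4, box_px=12, overlap=0.5)
        # 50% overlap: each interior cell belongs to up to 4 boxes
        counts = {}
        for p in patches:
            for c in p.members[0]:
                counts[c] = counts.get(c, 0) + 1
        assert max(counts.values()) == 4
        for p in patches:
            assert p.members[0] == p.members[3]

    def test_daughters_inherit_patch(self):
        img = block_grid()
        g0 = build_adjacency(img, frame=0)
        df = trivial_lineage_df([c for c in range(1, 26) if c != 13],
                                last_frame=2)
        df = pd.concat([df, pd.DataFrame([
            dict(cell_id=13, mother_id=-1, first_frame=0, last_frame=0,
                 fate="divides", fate_partner=-1),
            dict(cell_id=26, mother_id=13, first_frame=1, last_frame=2,
                 fate="survives", fate_partner=-1),
            dict(cell_id=27, mother_id=13, first_frame=1, last_frame=2,
                 fate="survives", fate_partner=-1),
        ])], ignore_index=True)
        lin = Lineage(df)
        patches = lagrangian_patches(g0, lin, n_frames=3, box_px=60, overlap=0.0)
        p = next(p for p in patches if 13 in p.members[0])
        assert {26, 27} <= p.members[1]
        assert 13 not in p.members[1]


class TestSlidingAverage:
    def _rates(self, values, weights):
        return pd.DataFrame({
            "m": 0, "n": 0, "frame": np.arange(len(values)),
            "G_xx": values, "wa": weights,
        })

    def test_equal_weights_plain_mean(self):
        out = sliding_time_average(self._rates([1.0, 3.0], [1.0, 1.0]),
                                   window_h=2.0, dt_min=60.0)
        assert out["G_xx"].iloc[0] == pytest.approx(2.0)

    def test_weighted_mean(self):
        out = sliding_time_average(self._rates([1.0, 3.0], [1.0, 3.0]),
                                   window_h=2.0, dt_min=60.0)
        assert out["G_xx"].iloc[0] == pytest.approx(2.5)

    def test_constant_rate_unchanged(self):
        out = sliding_time_average(self._rates([2.0] * 10, [0.5] * 10),
                                   window_h=2.0, dt_min=5.0)
        assert np.allclose(out["G_xx"], 2.0)

    def test_all_zero_weights_missing(self):
        out = sliding_time_average(self._rates([1.0, 2.0], [0.0, 0.0]),
                                   window_h=2.0, dt_min=60.0)
        assert out["G_xx"].isna().all()
        assert np.allclose(out["Wa"], 0.0)
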
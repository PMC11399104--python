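import numpy as np
import pytest

from smdol.colocalization import (
    coloc_curve,
    degree_of_colocalization,
    match_one_to_one,
    pool_curves,
    rotate_for_null,
    unspecific_density,
)
from smdol.io import LocalizationSet
from smdol.segmentation import CellMask


def _locs(xy, ids=None):
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    if xy.size == 0:
        return LocalizationSet.empty()
    return LocalizationSet.from_arrays(xy[:, 0], xy[:, 1], 150.0, 100.0, ids=ids)


def brute_force_assignment(ref_xy, tgt_xy, tol):
    """Exhaustive oracle: maximize pair count, then minimize total
    distance, by recursion over all one-to-one assignments."""
    nr, nt = len(ref_xy), len(tgt_xy)
    best = [-1, np.inf]

    def rec(i, used, cnt, total):
        if i == nr:
            if cnt > best[0] or (cnt == best[0] and total < best[1] - 1e-12):
                best[0], best[1] = cnt, total
            return
        rec(i + 1, used, cnt, total)
        for j in range(nt):
            if used[j]:
                continue
            d = float(np.hypot(*(ref_xy[i] - tgt_xy[j])))
            if d <= tol:
                used[j] = True
                rec(i + 1, used, cnt + 1, total + d)
                used[j] = False

    rec(0, [False] * nt, 0, 0.0)
    return best[0], best[1]


class TestMatchOneToOne:
    def test_far_apart_sets_no_pairs(self):
        m = match_one_to_one(_locs([(0, 0)]), _locs([(1e6, 1e6)]), 100.0)
        assert len(m) == 0
        assert m.unmatched_ref_ids == [0] and m.unmatched_target_ids == [0]

    def test_identical_sets_perfect_matching(self):
        pts = np.random.default_rng(0).uniform(0, 1000, (20, 2))
        m = match_one_to_one(_locs(pts), _locs(pts), 50.0)
        assert len(m) == 20
        assert np.allclose(m.distances_nm, 0.0)

    def test_one_to_one_discipline(self):
        # two refs compete for one target: only one pair allowed
        m = match_one_to_one(_locs([(0, 0), (10, 0)]), _locs([(5, 0)]), 100.0)
        assert len(m) == 1

    def test_crossing_configuration_matches_oracle(self):
        # hand-built crossing: nearest-neighbour greed would pick the
        # short middle pair and strand a ref; the optimum pairs both
        ref = np.array([(0.0, 0.0), (10.0, 0.0)])
        tgt = np.array([(9.0, 0.0), (11.0, 0.0)])
        m = match_one_to_one(_locs(ref), _locs(tgt), 9.5)
        cnt, total = brute_force_assignment(ref, tgt, 9.5)
        assert len(m) == cnt == 2
        assert sum(d for _, _, d in m.pairs) == pytest.approx(total)

    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            nr, nt = rng.integers(1, 9, size=2)
            ref = rng.random((nr, 2)) * 100
            tgt = rng.random((nt, 2)) * 100
            tol = rng.uniform(10, 60)
            m = match_one_to_one(_locs(ref), _locs(tgt), tol)
            cnt, total = brute_force_assignment(ref, tgt, tol)
            assert len(m) == cnt
            assert sum(d for _, _, d in m.pairs) == pytest.approx(total, abs=1e-9)


class TestRotateForNull:
    FRAME = (40960.0, 40960.0)

    def test_four_rotations_identity(self):
        pts = np.random.default_rng(1).uniform(0, 40960, (30, 2))
        locs = _locs(pts)
        for _ in range(4):
            locs = rotate_for_null(locs, self.FRAME)
        assert np.allclose(locs.xy, pts, atol=1e-6)

    def test_center_fixed_point(self):
        c = (self.FRAME[0] / 2, self.FRAME[1] / 2)
        out = rotate_for_null(_locs([c]), self.FRAME)
        assert np.allclose(out.xy[0], c)

    def test_quarter_point_maps_by_rotation_matrix(self):
        w, h = self.FRAME
        p = np.array([w / 4, h / 2])
        out = rotate_for_null(_locs([p]), self.FRAME)
        center = np.array([w / 2, h / 2])
        rot = np.array([[0.0, -1.0], [1.0, 0.0]])  # +90 deg, y-down frame
        expected = center + rot @ (p - center)
        assert np.allclose(out.xy[0], expected, atol=1e-9)

    def test_count_preserved_square_frame(self):
        pts = np.random.default_rng(2).uniform(0, 40960, (50, 2))
        assert len(rotate_for_null(_locs(pts), self.FRAME)) == 50

    def test_nonsquare_out_of_frame_discarded(self):
        frame = (60000.0, 30000.0)
        out = rotate_for_null(_locs([(59000.0, 15000.0)]), frame)
        assert len(out) == 0


class TestColocCurve:
    GRID = np.arange(0.0, 501.0, 10.0)
    FRAME = (40960.0, 40960.0)

    def test_copy_target_jumps_at_zero(self):
        pts = np.random.default_rng(3).uniform(5000, 35000, (40, 2))
        curve = coloc_curve(_locs(pts), _locs(pts), self.GRID, self.FRAME)
        assert curve.f_c[0] == pytest.approx(1.0)
        assert curve.T_nm == 0.0
        assert curve.z[0] == max(curve.z)

    def test_unrelated_target_z_near_zero(self):
        rng = np.random.default_rng(4)
        ref = rng.uniform(0, 40960, (300, 2))
        tgt = rng.uniform(0, 40960, (300, 2))
        curve = coloc_curve(_locs(ref), _locs(tgt), self.GRID, self.FRAME)
        se = np.sqrt(
            np.maximum(curve.f_c * (1 - curve.f_c) + curve.f_r * (1 - curve.f_r), 1e-12)
            / curve.n_ref_total
        )
        assert (np.abs(curve.z) <= np.maximum(3 * se, 3.0 / curve.n_ref_total)).all()

    def test_subset_target_fraction_exact(self):
        rng = np.random.default_rng(5)
        ref = rng.uniform(5000, 35000, (50, 2))
        target = ref[:20]
        curve = coloc_curve(_locs(ref), _locs(target), self.GRID, self.FRAME)
        assert curve.f_c[-1] == pytest.approx(20 / 50)

    def test_monotone_fractions(self):
        rng = np.random.default_rng(6)
        ref = rng.uniform(0, 40960, (100, 2))
        tgt = ref + rng.normal(0, 120, size=ref.shape)
        curve = coloc_curve(_locs(ref), _locs(tgt), self.GRID, self.FRAME)
        assert (np.diff(curve.f_c) >= -1e-12).all()
        assert (np.diff(curve.f_r) >= -1e-12).all()
        assert curve.T_nm in curve.t_grid_nm
        assert curve.z.max() == pytest.approx(curve.z[list(curve.t_grid_nm).index(curve.T_nm)])

    def test_T_invariant_under_common_rigid_transform(self):
        from smdol.registration import AffineTransform2D, apply_transform

        rng = np.random.default_rng(7)
        ref = rng.uniform(10000, 30000, (150, 2))
        tgt = ref + rng.normal(0, 60, size=ref.shape)
        curve0 = coloc_curve(_locs(ref), _locs(tgt), self.GRID, self.FRAME)
        rigid = AffineTransform2D.from_params(1500.0, -2000.0, 2.0)
        curve1 = coloc_curve(
            apply_transform(_locs(ref), rigid),
            apply_transform(_locs(tgt), rigid),
            self.GRID,
            self.FRAME,
        )
        assert curve0.T_nm == curve1.T_nm

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError):
            coloc_curve(LocalizationSet.empty(), _locs([(0, 0)]), self.GRID, self.FRAME)

    def test_pooled_curve_weights_by_counts(self):
        rng = np.random.default_rng(8)
        curves = []
        for n in (30, 300):
            ref = rng.uniform(5000, 35000, (n, 2))
            tgt = ref + rng.normal(0, 40, size=ref.shape)
            curves.append(coloc_curve(_locs(ref), _locs(tgt), self.GRID, self.FRAME))
        pooled = pool_curves(curves)
        assert pooled.n_ref_total == 330
        expected = (curves[0].cum_c + curves[1].cum_c) / 330
        assert np.allclose(pooled.f_c, expected)


class TestDegreeOfColocalization:
    def test_all_matched(self):
        pts = np.random.default_rng(9).uniform(0, 10000, (25, 2))
        assert degree_of_colocalization(_locs(pts), _locs(pts), 50.0) == 1.0

    def test_no_targets(self):
        pts = np.random.default_rng(10).uniform(0, 10000, (25, 2))
        assert degree_of_colocalization(_locs(pts), LocalizationSet.empty(), 50.0) == 0.0

    def test_partial_ratio(self):
        rng = np.random.default_rng(11)
        ref = rng.uniform(5000, 30000, (100, 2))
        target = ref[:40]
        assert degree_of_colocalization(_locs(ref), _locs(target), 50.0) == pytest.approx(0.4)

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError):
            degree_of_colocalization(LocalizationSet.empty(), _locs([(0, 0)]), 50.0)


class TestUnspecificDensity:
    def _mask(self):
        m = np.zeros((64, 64), dtype=bool)
        m[:, :] = True
        return CellMask(m, 160.0)  # 64*64 px * 0.0256 um^2 = 104.8576 um^2

    def test_no_targets_zero(self):
        assert unspecific_density(LocalizationSet.empty(), self._mask(), mode="control") == 0.0

    def test_control_mode_ratio(self):
        mask = self._mask()
        pts = np.random.default_rng(12).uniform(0, 64 * 160.0, (50, 2))
        dens = unspecific_density(_locs(pts), mask, mode="control")
        assert dens == pytest.approx(50 / mask.area_um2)

    def test_residual_mode_excludes_matched(self):
        mask = self._mask()
        ref = np.random.default_rng(13).uniform(1000, 9000, (20, 2))
        extra = np.random.default_rng(14).uniform(1000, 9000, (10, 2)) + 1000
        target = np.vstack([ref, extra])
        dens = unspecific_density(_locs(target), mask, ref_locs=_locs(ref), T_nm=10.0, mode="residual")
        assert dens == pytest.approx(10 / mask.area_um2)

    def test_zero_area_errors(self):
        empty = CellMask(np.zeros((64, 64), bool), 160.0)
        with pytest.raises(ValueError):
            unspecific_density(_locs([(0, 0)]), empty, mode="control")

    def test_simulated_density_recovery(self, sim_config, analysis_config):
        # tag-free control probe: recover 0.1 signals/um^2 within Poisson 3 sigma
        from smdol.dolreport import prepare_cell
        from smdol.sim import simulate_experiment

        cfg = sim_config.replace(true_dol=0.0, unspec_density_um2=0.1, probe_density_um2=0.2)
        n_tot = 0.0
        area_tot = 0.0
        for cell in simulate_experiment(cfg, 3, seed=77):
            p = prepare_cell(cell.reference, cell.target, analysis_config)
            dens = unspecific_density(p.target_locs, p.mask, mode="control")
            n_tot += dens * p.mask.area_um2
            area_tot += p.mask.area_um2
        expected = 0.1 * area_tot
        assert abs(n_tot - expected) <= 3 * np.sqrt(expected)
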
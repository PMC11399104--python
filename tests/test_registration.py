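import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from smdol.io import LocalizationSet
from smdol.registration import (
    AffineTransform2D,
    RegistrationError,
    apply_transform,
    estimate_affine,
    pool_transforms,
)

PX = 160.0


def _locs(xy):
    xy = np.atleast_2d(xy)
    return LocalizationSet.from_arrays(xy[:, 0], xy[:, 1], 150.0, 100.0, pixel_size_nm=PX)


def _cloud(n, seed, extent=40000.0):
    return np.random.default_rng(seed).uniform(0, extent, size=(n, 2))


class TestAffineTransform2D:
    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        sx=st.floats(-400, 400),
        sy=st.floats(-400, 400),
        rot=st.floats(-5, 5),
        scx=st.floats(0.95, 1.05),
        scy=st.floats(0.95, 1.05),
    )
    def test_decompose_recompose_roundtrip(self, sx, sy, rot, scx, scy):
        t = AffineTransform2D.from_params(sx, sy, rot, scx, scy)
        back = AffineTransform2D.from_params(**t.decompose())
        assert np.allclose(back.matrix, t.matrix, atol=1e-6)

    def test_inverse_is_group_inverse(self):
        t = AffineTransform2D.from_params(100.0, -50.0, 2.0, 1.01, 0.99)
        pts = _cloud(50, 0)
        assert np.allclose(t.invert().apply(t.apply(pts)), pts, atol=1e-6)

    def test_singular_rejected(self):
        with pytest.raises(ValueError):
            AffineTransform2D(np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 2.0]]))


class TestEstimateAffine:
    def test_identical_sets_identity(self):
        pts = _cloud(100, 1)
        t, qc = estimate_affine(_locs(pts), _locs(pts))
        assert qc.accepted
        assert qc.rms_residual_nm < 1e-6
        assert np.allclose(t.matrix, AffineTransform2D.identity().matrix, atol=1e-9)

    def test_known_transform_recovery_with_jitter(self):
        truth = AffineTransform2D.from_params(1.5 * PX, -0.8 * PX, 1.0, 1.01, 1.01)
        ref = _cloud(200, 2)
        rng = np.random.default_rng(3)
        # the target channel sees displaced coordinates; the estimator
        # must recover the map back onto the reference
        target = truth.invert().apply(ref) + rng.normal(0, 10.0, size=(200, 2))
        t, qc = estimate_affine(_locs(ref), _locs(target))
        dec = t.decompose()
        tdec = truth.decompose()
        assert qc.accepted
        assert abs(dec["shift_x_nm"] - tdec["shift_x_nm"]) / PX < 0.1
        assert abs(dec["shift_y_nm"] - tdec["shift_y_nm"]) / PX < 0.1
        assert abs(dec["rotation_deg"] - tdec["rotation_deg"]) < 0.1
        assert abs(dec["scale_x"] - tdec["scale_x"]) < 0.005
        assert abs(dec["scale_y"] - tdec["scale_y"]) < 0.005

    def test_small_set_excluded_by_emitter_gate(self):
        pts = _cloud(30, 4)
        _, qc = estimate_affine(_locs(pts), _locs(pts))
        assert qc.n_emitters == 30
        assert not qc.accepted

    def test_noiseless_equivariance(self):
        # estimate_affine(A(P), P) recovers A exactly for >= 3 points
        a = AffineTransform2D.from_params(200.0, 120.0, 3.0, 1.02, 0.98)
        pts = _cloud(60, 5)
        t, _ = estimate_affine(_locs(a.apply(pts)), _locs(pts))
        assert np.allclose(t.matrix, a.matrix, atol=1e-6)

    @pytest.mark.parametrize(
        "shift_px, rot_deg, scale, accepted",
        [
            (3.0, 0.0, 1.0, True),    # boundary: exactly 3 px passes
            (3.05, 0.0, 1.0, False),  # just beyond the shift gate
            (0.0, 5.0, 1.0, True),    # exactly 5 degrees passes
            (0.0, 5.05, 1.0, False),
            (0.0, 0.0, 1.05, True),   # exactly 5% scale passes
            (0.0, 0.0, 1.055, False),
        ],
    )
    def test_qc_gate_boundaries(self, shift_px, rot_deg, scale, accepted):
        # sparse cloud: inter-point spacing exceeds the largest
        # gate-scale displacement, so correspondence is unambiguous
        truth = AffineTransform2D.from_params(shift_px * PX, 0.0, rot_deg, scale, scale)
        ref = _cloud(60, 6, extent=20000.0)
        target = truth.invert().apply(ref)
        _, qc = estimate_affine(_locs(ref), _locs(target), match_radius_nm=1500.0)
        assert qc.accepted is accepted

    def test_too_few_pairs_not_estimable(self):
        ref = _locs([(0.0, 0.0), (50000.0, 50000.0)])
        target = _locs([(500000.0, 500000.0), (600000.0, 700000.0)])
        _, qc = estimate_affine(ref, target, match_radius_nm=100.0)
        assert not qc.accepted
        assert qc.n_pairs < 3


class TestPoolTransforms:
    def _qc(self, transform, accepted=True):
        from smdol.registration import RegistrationQC

        return RegistrationQC(
            n_pairs=100,
            n_emitters=100,
            shift_px=0.0,
            rotation_deg=0.0,
            scale_dev=0.0,
            rms_residual_nm=0.0,
            accepted=accepted,
            transform=transform,
        )

    def test_single_accepted_returns_itself(self):
        t = AffineTransform2D.from_params(100.0, 0.0, 1.0, 1.01, 1.0)
        pooled = pool_transforms([self._qc(t)])
        assert np.allclose(pooled.matrix, t.matrix, atol=1e-9)

    def test_mean_of_shifts(self):
        t1 = AffineTransform2D.from_params(1.0 * PX, 0.0)
        t2 = AffineTransform2D.from_params(3.0 * PX, 0.0)
        pooled = pool_transforms([self._qc(t1), self._qc(t2)])
        assert pooled.decompose()["shift_x_nm"] == pytest.approx(2.0 * PX)

    def test_rejected_transforms_ignored(self):
        good = AffineTransform2D.from_params(1.0 * PX, 0.0)
        bad = AffineTransform2D.from_params(50.0 * PX, 0.0)
        pooled = pool_transforms([self._qc(good), self._qc(bad, accepted=False)])
        assert pooled.decompose()["shift_x_nm"] == pytest.approx(1.0 * PX)

    def test_zero_accepted_raises(self):
        t = AffineTransform2D.identity()
        with pytest.raises(RegistrationError, match="identity"):
            pool_transforms([self._qc(t, accepted=False)])

    def test_pooling_beats_median_single_estimate(self):
        truth = AffineTransform2D.from_params(1.2 * PX, -0.6 * PX, 0.5, 1.005, 1.005)
        wins = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            qcs = []
            errs = []
            for rep in range(10):
                ref = rng.uniform(0, 40000, size=(80, 2))
                target = truth.invert().apply(ref) + rng.normal(0, 15.0, size=(80, 2))
                t, qc = estimate_affine(_locs(ref), _locs(target))
                qcs.append(qc)
                errs.append(np.abs(t.matrix - truth.matrix).max())
            pooled_err = np.abs(pool_transforms(qcs).matrix - truth.matrix).max()
            if pooled_err <= np.median(errs):
                wins += 1
        assert wins / n_seeds >= 0.8


class TestApplyTransform:
    def test_identity(self):
        locs = _locs(_cloud(20, 7))
        out = apply_transform(locs, AffineTransform2D.identity())
        assert np.allclose(out.xy, locs.xy)

    def test_pure_shift(self):
        locs = _locs(_cloud(20, 8))
        out = apply_transform(locs, AffineTransform2D.from_params(100.0, -50.0))
        assert np.allclose(out.x_nm, locs.x_nm + 100.0)
        assert np.allclose(out.y_nm, locs.y_nm - 50.0)

    def test_fields_preserved(self):
        locs = _locs(_cloud(20, 9))
        out = apply_transform(locs, AffineTransform2D.from_params(10.0, 20.0, 1.0))
        assert np.array_equal(out.table["sigma_nm"], locs.table["sigma_nm"])
        assert np.array_equal(out.table["id"], locs.table["id"])

    def test_transform_then_inverse(self):
        locs = _locs(_cloud(20, 10))
        t = AffineTransform2D.from_params(123.0, -45.0, 2.0, 1.02, 0.99)
        back = apply_transform(apply_transform(locs, t), t.invert())
        assert np.allclose(back.xy, locs.xy, atol=1e-6)
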
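"""Chromatic channel registration on localization point sets.

The target channel is imaged through a different optical path than the
reference channel, so its localizations are displaced by a smooth,
well-approximated-as-affine chromatic transform.  This module estimates
that transform per image by iterative mutual-nearest-neighbour matching
plus a least-squares affine fit, applies the field's standard QC gates
(minimum emitter count, maximum shift / rotation / scale deviation) and
pools the surviving per-image estimates into one global transform per
experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .io import LocalizationSet

__all__ = [
    "AffineTransform2D",
    "RegistrationQC",
    "RegistrationError",
    "estimate_affine",
    "pool_transforms",
    "apply_transform",
]


class RegistrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class AffineTransform2D:
    """2D affine map on nm coordinates: x' = A @ x + t.

    ``matrix`` is the 2x3 array ``[A | t]``.  The shift/rotation/scale
    decomposition assumes zero shear (A = R(theta) @ diag(sx, sy)), which
    holds exactly for chromatic transforms and to high accuracy for fitted
    ones; recomposition after :meth:`decompose` round-trips within 1e-6
    for shear-free transforms.
    """

    matrix: np.ndarray  # shape (2, 3)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise ValueError(f"affine matrix must be 2x3, got {m.shape}")
        if abs(np.linalg.det(m[:, :2])) < 1e-12:
            raise ValueError("affine transform is singular")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    @classmethod
    def from_params(
        cls,
        shift_x_nm: float = 0.0,
        shift_y_nm: float = 0.0,
        rotation_deg: float = 0.0,
        scale_x: float = 1.0,
        scale_y: float = 1.0,
    ) -> "AffineTransform2D":
        th = math.radians(rotation_deg)
        a = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        a = a @ np.diag([scale_x, scale_y])
        return cls(np.column_stack([a, [shift_x_nm, shift_y_nm]]))

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :2]

    @property
    def translation_nm(self) -> np.ndarray:
        return self.matrix[:, 2]

    def apply(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return xy @ self.linear.T + self.translation_nm

    def invert(self) -> "AffineTransform2D":
        a_inv = np.linalg.inv(self.linear)
        return AffineTransform2D(np.column_stack([a_inv, -a_inv @ self.translation_nm]))

    def compose(self, other: "AffineTransform2D") -> "AffineTransform2D":
        """self after other: (self o other)(x) = self(other(x))."""
        a = self.linear @ other.linear
        t = self.linear @ other.translation_nm + self.translation_nm
        return AffineTransform2D(np.column_stack([a, t]))

    def decompose(self) -> dict:
        (a, b, tx), (c, d, ty) = self.matrix
        # For A = R(th) @ diag(sx, sy): a+d = (sx+sy) cos th, c-b = (sx+sy) sin th
        theta = math.atan2(c - b, a + d)
        return {
            "shift_x_nm": tx,
            "shift_y_nm": ty,
            "rotation_deg": math.degrees(theta),
            "scale_x": math.hypot(a, c),
            "scale_y": math.hypot(b, d),
        }


@dataclass
class RegistrationQC:
    """Quality gates for one per-image registration.

    ``accepted`` is true iff the input had at least ``min_emitters``
    localizations in both channels and the fitted transform stays within
    the shift / rotation / scale gates.  Exclusion is strict: a shift of
    exactly 3 px passes a 3 px gate.
    """

    n_pairs: int
    n_emitters: int
    shift_px: float
    rotation_deg: float
    scale_dev: float
    rms_residual_nm: float
    accepted: bool
    transform: AffineTransform2D = field(default_factory=AffineTransform2D.identity)


def _mutual_pairs(ref_xy: np.ndarray, tgt_xy: np.ndarray, radius_nm: float):
    """Mutual-nearest-neighbour pairs within radius; suppresses false pairs
    at moderate density."""
    tree_ref = cKDTree(ref_xy)
    tree_tgt = cKDTree(tgt_xy)
    d_t, nn_of_tgt = tree_ref.query(tgt_xy, k=1)
    _, nn_of_ref = tree_tgt.query(ref_xy, k=1)
    j = np.arange(len(tgt_xy))
    mutual = (nn_of_ref[nn_of_tgt] == j) & (d_t <= radius_nm)
    return nn_of_tgt[mutual], j[mutual]


def _fit_affine(src_xy: np.ndarray, dst_xy: np.ndarray) -> AffineTransform2D:
    # centre both clouds before solving: raw nm coordinates (~1e4-1e5)
    # make the normal equations ill-conditioned enough to cost several
    # digits on the translation
    src_c = src_xy.mean(axis=0)
    dst_c = dst_xy.mean(axis=0)
    design = np.column_stack([src_xy - src_c, np.ones(len(src_xy))])
    coef, *_ = np.linalg.lstsq(design, dst_xy - dst_c, rcond=None)
    linear = coef[:2].T
    translation = coef[2] + dst_c - linear @ src_c
    return AffineTransform2D(np.column_stack([linear, translation]))


def estimate_affine(
    ref_locs: LocalizationSet,
    target_locs: LocalizationSet,
    match_radius_nm: float = 500.0,
    n_iterations: int = 5,
    min_emitters: int = 50,
    max_shift_px: float = 3.0,
    max_rotation_deg: float = 5.0,
    max_scale_dev: float = 0.05,
    pixel_size_nm: float | None = None,
) -> tuple[AffineTransform2D, RegistrationQC]:
    """Estimate the affine transform mapping target coordinates onto the
    reference frame.

    Iterative closest-point style: mutual-nearest pairs within
    ``match_radius_nm`` -> least-squares affine -> re-match with the
    transformed target; stops after ``n_iterations`` or when the update
    moves parameters by less than 1e-3 px.  Returns the transform together
    with its QC record; if fewer than 3 pairs are found at any iteration
    the result is the identity with ``accepted=False``.
    """
    if pixel_size_nm is None:
        pixel_size_nm = ref_locs.pixel_size_nm
    if not np.isfinite(pixel_size_nm) or pixel_size_nm <= 0:
        raise ValueError("pixel_size_nm must be known to express QC gates in px")

    ref_xy = ref_locs.xy
    tgt_xy = target_locs.xy
    n_emitters = min(len(ref_xy), len(tgt_xy))

    def _rejected(n_pairs: int = 0) -> tuple[AffineTransform2D, RegistrationQC]:
        ident = AffineTransform2D.identity()
        return ident, RegistrationQC(
            n_pairs=n_pairs,
            n_emitters=n_emitters,
            shift_px=float("nan"),
            rotation_deg=float("nan"),
            scale_dev=float("nan"),
            rms_residual_nm=float("nan"),
            accepted=False,
            transform=ident,
        )

    if n_emitters == 0:
        raise ValueError("both localization sets must be non-empty")

    # Coarse-to-fine matching: the QC gates admit transforms that move
    # far-from-centre points by several microns (5 deg over a 40 um
    # field), so the first iterations match within a generous radius and
    # anneal down to match_radius_nm; each fit is trimmed of residual
    # outliers once (chance mutual pairs between unrelated molecules).
    n_iter = max(1, n_iterations)
    start_radius = max(match_radius_nm, 25.0 * pixel_size_nm)
    radii = np.geomspace(start_radius, match_radius_nm, n_iter)
    radii = np.concatenate([radii, np.full(3, match_radius_nm)])

    transform = AffineTransform2D.identity()
    pairs = (np.array([], dtype=int), np.array([], dtype=int))
    for radius in radii:
        moved = transform.apply(tgt_xy)
        i_ref, j_tgt = _mutual_pairs(ref_xy, moved, radius)
        if len(i_ref) < 3:
            return _rejected(len(i_ref))
        new = _fit_affine(tgt_xy[j_tgt], ref_xy[i_ref])
        res = np.linalg.norm(new.apply(tgt_xy[j_tgt]) - ref_xy[i_ref], axis=1)
        cut = max(3.0 * np.median(res), 1e-3 * pixel_size_nm)
        keep = res <= cut
        if keep.sum() >= 3 and not keep.all():
            i_ref, j_tgt = i_ref[keep], j_tgt[keep]
            new = _fit_affine(tgt_xy[j_tgt], ref_xy[i_ref])
        delta_px = np.max(np.abs(new.matrix - transform.matrix)) / pixel_size_nm
        transform, pairs = new, (i_ref, j_tgt)
        if radius <= match_radius_nm and delta_px < 1e-3:
            break

    i_ref, j_tgt = pairs
    residuals = transform.apply(tgt_xy[j_tgt]) - ref_xy[i_ref]
    rms = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    dec = transform.decompose()
    shift_px = float(math.hypot(dec["shift_x_nm"], dec["shift_y_nm"]) / pixel_size_nm)
    scale_dev = float(max(abs(dec["scale_x"] - 1.0), abs(dec["scale_y"] - 1.0)))
    # exclusion is strict ("exceeds the gate"): a result at exactly the
    # threshold passes; the 1e-9 guard keeps boundary cases from being
    # decided by floating-point round-off
    eps = 1e-9
    accepted = (
        n_emitters >= min_emitters
        and shift_px <= max_shift_px + eps
        and abs(dec["rotation_deg"]) <= max_rotation_deg + eps
        and scale_dev <= max_scale_dev + eps
    )
    qc = RegistrationQC(
        n_pairs=int(len(i_ref)),
        n_emitters=n_emitters,
        shift_px=shift_px,
        rotation_deg=float(dec["rotation_deg"]),
        scale_dev=scale_dev,
        rms_residual_nm=rms,
        accepted=bool(accepted),
        transform=transform,
    )
    return transform, qc


def pool_transforms(qc_list: list[RegistrationQC]) -> AffineTransform2D:
    """Average accepted per-image transforms into one global transform.

    The decomposed parameters (shift, rotation, scales) are averaged
    arithmetically and recomposed.  Averaging the rotation as a plane
    angle is safe because the QC gate caps |rotation| at 5 degrees.

    Raises :class:`RegistrationError` when no transform was accepted; the
    caller should then fall back to the identity (and flag the cells).
    """
    accepted = [qc for qc in qc_list if qc.accepted]
    if not accepted:
        raise RegistrationError(
            "no registration passed QC; fall back to the identity transform "
            "and flag affected cells"
        )
    params = [qc.transform.decompose() for qc in accepted]
    mean = {k: float(np.mean([p[k] for p in params])) for k in params[0]}
    return AffineTransform2D.from_params(**mean)


def apply_transform(locs: LocalizationSet, transform: AffineTransform2D) -> LocalizationSet:
    """Map coordinates through ``transform``; all other fields preserved."""
    if len(locs) == 0:
        return locs
    xy = transform.apply(locs.xy)
    return locs.with_xy(xy[:, 0], xy[:, 1])
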
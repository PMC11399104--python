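"""Per-cell analysis orchestration and experiment-level aggregation.

One experiment = a set of dual-channel images acquired under one
labeling condition.  The stages per cell are: segment the reference
channel, localize both channels with the PSF-width filter, keep only
in-mask localizations, estimate the chromatic transform, and compute
colocalization statistics.  The chromatic transform and the distance
cutoff T are experiment-level quantities: per-cell transforms passing QC
are averaged into one global transform, and per-cell colocalization
curves are pooled (pair counts, not fractions) before T is read off.
The per-cell degree of colocalization is finally converted to a degree
of labeling via the density-dependent recall calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import colocalization as coloc
from . import registration as reg
from .calibration import DensityCalibration, config_hash, correct_dol
from .io import AnalysisConfig, Image2D, LocalizationSet
from .localization import localize_image
from .segmentation import CellMask, mask_filter, segment_with_settings

__all__ = [
    "CellDOLResult",
    "ExperimentSummary",
    "PreparedCell",
    "prepare_cell",
    "analyze_cell",
    "analyze_experiment",
    "summarize",
    "results_table",
]

#: qc_flags vocabulary.  Segmentation failure and low counts exclude a
#: cell from summaries; the registration-fallback flag is informational
#: (the data-driven cutoff T widens to absorb an uncorrected chromatic
#: shift, so those cells remain interpretable).
FLAG_SEGMENTATION = "segmentation_failed"
FLAG_LOW_COUNTS = "low_counts"
FLAG_REG_FALLBACK = "registration_fallback"
EXCLUDING_FLAGS = {FLAG_SEGMENTATION, FLAG_LOW_COUNTS}


@dataclass
class PreparedCell:
    """Stage 1-3 output for one cell: mask plus filtered localizations."""

    mask: CellMask
    ref_locs: LocalizationSet
    target_locs: LocalizationSet
    qc_flags: list[str]
    frame_size_nm: tuple[float, float]


@dataclass
class CellDOLResult:
    cell_id: str
    n_reference: int
    n_target: int
    n_colocalized: int
    density_measured_um2: float
    degree_of_colocalization: float
    #: fraction of references matched by chance at the same cutoff,
    #: measured on the 90-degree-rotated target set; the labeling-degree
    #: correction uses the specific part (DOC minus this)
    random_coloc_fraction: float
    dol: float
    unspec_density_um2: float
    qc_flags: list[str] = field(default_factory=list)

    @property
    def specific_colocalization(self) -> float:
        return max(self.degree_of_colocalization - self.random_coloc_fraction, 0.0)

    @property
    def usable(self) -> bool:
        return not (set(self.qc_flags) & EXCLUDING_FLAGS)


@dataclass
class ExperimentSummary:
    condition: str
    n_cells: int
    dol_median: float
    dol_mean: float
    dol_sd: float
    unspec_median: float
    T_nm: float
    calibration_provenance: str = ""


def prepare_cell(
    ref_image: Image2D, target_image: Image2D, config: AnalysisConfig
) -> PreparedCell:
    """Segment, localize (both channels), sigma-filter and mask-filter."""
    flags: list[str] = []
    mask = segment_with_settings(ref_image, config.segmentation)
    ref_locs = localize_image(ref_image, config.detection)
    target_locs = localize_image(target_image, config.detection)
    if not mask.found:
        flags.append(FLAG_SEGMENTATION)
    else:
        ref_locs = mask_filter(ref_locs, mask)
        target_locs = mask_filter(target_locs, mask)
    if len(ref_locs) < config.report.min_reference_locs:
        flags.append(FLAG_LOW_COUNTS)
    return PreparedCell(
        mask=mask,
        ref_locs=ref_locs,
        target_locs=target_locs,
        qc_flags=flags,
        frame_size_nm=ref_image.frame_size_nm,
    )


def _cell_result(
    prepared: PreparedCell,
    transform: reg.AffineTransform2D,
    T_nm: float,
    calibration: DensityCalibration | None,
    config: AnalysisConfig,
    cell_id: str,
    extra_flags: list[str] | None = None,
) -> CellDOLResult:
    flags = list(prepared.qc_flags) + list(extra_flags or [])
    target = reg.apply_transform(prepared.target_locs, transform)
    n_ref = len(prepared.ref_locs)
    n_tgt = len(target)
    if flags and (FLAG_SEGMENTATION in flags or n_ref == 0):
        return CellDOLResult(
            cell_id=cell_id,
            n_reference=n_ref,
            n_target=n_tgt,
            n_colocalized=0,
            density_measured_um2=float("nan"),
            degree_of_colocalization=float("nan"),
            random_coloc_fraction=float("nan"),
            dol=float("nan"),
            unspec_density_um2=float("nan"),
            qc_flags=flags,
        )
    matched = coloc.match_one_to_one(prepared.ref_locs, target, T_nm)
    doc = len(matched) / n_ref
    # chance colocalization at the same cutoff, from the rotated null:
    # subtracted before the recall correction so that conditions with
    # many unlabeled references (where chance matches inflate DOC most)
    # and conditions with few are treated consistently
    rotated = coloc.rotate_for_null(target, prepared.frame_size_nm)
    f_r = len(coloc.match_one_to_one(prepared.ref_locs, rotated, T_nm)) / n_ref
    density = n_ref / prepared.mask.area_um2
    unspec = coloc.unspecific_density(
        target,
        prepared.mask,
        ref_locs=prepared.ref_locs,
        T_nm=T_nm,
        mode=config.report.unspec_mode,
    )
    if calibration is not None:
        dol = correct_dol(max(doc - f_r, 0.0), density, calibration)
    else:
        dol = float("nan")
    return CellDOLResult(
        cell_id=cell_id,
        n_reference=n_ref,
        n_target=n_tgt,
        n_colocalized=len(matched),
        density_measured_um2=density,
        degree_of_colocalization=doc,
        random_coloc_fraction=f_r,
        dol=dol,
        unspec_density_um2=unspec,
        qc_flags=flags,
    )


def analyze_cell(
    ref_image: Image2D,
    target_image: Image2D,
    config: AnalysisConfig,
    transform: reg.AffineTransform2D,
    T_nm: float,
    calibration: DensityCalibration | None = None,
    cell_id: str = "cell",
) -> CellDOLResult:
    """Full per-cell analysis with experiment-level transform and T given."""
    prepared = prepare_cell(ref_image, target_image, config)
    return _cell_result(prepared, transform, T_nm, calibration, config, cell_id)


def _pooled_registration(cells: list[PreparedCell], config: AnalysisConfig):
    """One affine estimate from localizations concatenated across cells."""
    if not cells:
        return None
    ref_xy = np.concatenate([p.ref_locs.xy for p in cells], axis=0)
    tgt_xy = np.concatenate([p.target_locs.xy for p in cells], axis=0)
    ref = LocalizationSet.from_arrays(
        ref_xy[:, 0], ref_xy[:, 1], pixel_size_nm=config.pixel_size_nm
    )
    tgt = LocalizationSet.from_arrays(
        tgt_xy[:, 0], tgt_xy[:, 1], pixel_size_nm=config.pixel_size_nm
    )
    rs = config.registration
    try:
        _, qc = reg.estimate_affine(
            ref,
            tgt,
            match_radius_nm=rs.match_radius_nm,
            n_iterations=rs.n_iterations,
            min_emitters=rs.min_emitters,
            max_shift_px=rs.max_shift_px,
            max_rotation_deg=rs.max_rotation_deg,
            max_scale_dev=rs.max_scale_dev,
            pixel_size_nm=config.pixel_size_nm,
        )
    except ValueError:
        return None
    return qc


@dataclass
class ExperimentContext:
    """Experiment-level quantities shared by all cells."""

    transform: reg.AffineTransform2D
    registration_fallback: bool
    curve: coloc.ColocCurve | None
    T_nm: float


def analyze_experiment(
    image_pairs: list[tuple[Image2D, Image2D]],
    config: AnalysisConfig,
    calibration: DensityCalibration | None = None,
    cell_ids: list[str] | None = None,
) -> tuple[list[CellDOLResult], ExperimentContext]:
    """Analyse all cells of one condition.

    Pipeline: prepare each cell; estimate a per-cell affine transform and
    pool those passing QC into one global transform (identity fallback,
    flagged, if none passes); pool per-cell colocalization curves into
    the experiment cutoff T; then score each cell at (transform, T).
    """
    if calibration is not None and calibration.settings_hash:
        if calibration.settings_hash != config_hash(config):
            warnings.warn(
                "calibration was produced under different analysis settings; "
                "the recall correction factors are fitter-specific"
            )
    if cell_ids is None:
        cell_ids = [f"cell{k:03d}" for k in range(len(image_pairs))]

    prepared = [prepare_cell(r, t, config) for r, t in image_pairs]

    rs = config.registration
    usable_cells = [
        p
        for p in prepared
        if not (set(p.qc_flags) & EXCLUDING_FLAGS)
        and len(p.ref_locs) >= 3
        and len(p.target_locs) >= 3
    ]
    qcs = []
    for p in usable_cells:
        _, qc = reg.estimate_affine(
            p.ref_locs,
            p.target_locs,
            match_radius_nm=rs.match_radius_nm,
            n_iterations=rs.n_iterations,
            min_emitters=rs.min_emitters,
            max_shift_px=rs.max_shift_px,
            max_rotation_deg=rs.max_rotation_deg,
            max_scale_dev=rs.max_scale_dev,
            pixel_size_nm=config.pixel_size_nm,
        )
        qcs.append(qc)
    fallback = False
    try:
        transform = reg.pool_transforms(qcs)
    except reg.RegistrationError:
        # Sparse condition: no single image reaches the emitter gate.
        # Pool localizations across all cells (same optical path, so one
        # chromatic transform) and re-apply the same QC gates to the
        # pooled estimate before giving up.
        pooled_qc = _pooled_registration(usable_cells, config)
        if pooled_qc is not None and pooled_qc.accepted:
            transform = pooled_qc.transform
        else:
            warnings.warn("no registration passed QC; using identity transform")
            transform = reg.AffineTransform2D.identity()
            fallback = True

    t_grid = config.coloc.t_grid_nm
    curves = []
    for p in prepared:
        if set(p.qc_flags) & EXCLUDING_FLAGS:
            continue
        target = reg.apply_transform(p.target_locs, transform)
        curves.append(
            coloc.coloc_curve(
                p.ref_locs,
                target,
                t_grid,
                p.frame_size_nm,
                normalization=config.coloc.normalization,
            )
        )
    if curves:
        if config.coloc.cutoff_scope == "per_experiment":
            pooled = coloc.pool_curves(curves)
            T_nm = pooled.T_nm
        else:
            pooled = None
            T_nm = float(np.median([c.T_nm for c in curves]))
    else:
        pooled, T_nm = None, float("nan")

    extra = [FLAG_REG_FALLBACK] if fallback else None
    results = []
    for p, cid in zip(prepared, cell_ids):
        if np.isnan(T_nm):
            res = _cell_result(p, transform, 0.0, calibration, config, cid, extra_flags=extra)
            res.qc_flags = list(set(res.qc_flags) | {FLAG_LOW_COUNTS})
        else:
            res = _cell_result(p, transform, T_nm, calibration, config, cid, extra_flags=extra)
        results.append(res)
    return results, ExperimentContext(
        transform=transform, registration_fallback=fallback, curve=pooled, T_nm=T_nm
    )


def summarize(
    cell_results: list[CellDOLResult],
    condition: str = "",
    T_nm: float = float("nan"),
    calibration: DensityCalibration | None = None,
    statistic: str = "dol",
) -> ExperimentSummary:
    """Experiment summary over unflagged cells (median +/- s.d. headline).

    Flagged cells never contribute.  ``statistic`` selects ``dol`` or the
    uncorrected ``degree_of_colocalization``.
    """
    usable = [r for r in cell_results if r.usable]
    if not usable:
        raise ValueError("no unflagged cells to summarize")
    vals = np.array([getattr(r, statistic) for r in usable], dtype=float)
    unspec = np.array([r.unspec_density_um2 for r in usable], dtype=float)
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return ExperimentSummary(
        condition=condition,
        n_cells=len(usable),
        dol_median=float(np.median(vals)),
        dol_mean=float(np.mean(vals)),
        dol_sd=sd,
        unspec_median=float(np.median(unspec)),
        T_nm=T_nm,
        calibration_provenance=calibration.provenance if calibration else "",
    )


def results_table(cell_results: list[CellDOLResult]) -> pd.DataFrame:
    """Per-cell results as a flat DataFrame (qc_flags joined with ';')."""
    rows = []
    for r in cell_results:
        row = {
            "cell_id": r.cell_id,
            "n_reference": r.n_reference,
            "n_target": r.n_target,
            "n_colocalized": r.n_colocalized,
            "density_measured_um2": r.density_measured_um2,
            "degree_of_colocalization": r.degree_of_colocalization,
            "random_coloc_fraction": r.random_coloc_fraction,
            "dol": r.dol,
            "unspec_density_um2": r.unspec_density_um2,
            "qc_flags": ";".join(r.qc_flags),
        }
        rows.append(row)
    return pd.DataFrame(rows)
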
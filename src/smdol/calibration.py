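"""Density-dependent recall calibration and the labeling-degree correction.

At finite emitter density the pipeline misses a density-dependent
fraction of colocalization events (overlapping PSFs, missed or merged
localizations, mis-assignment near the cutoff).  Over the experimentally
relevant range the measured degree of colocalization divided by the true
labeling fraction — the recall — falls linearly with emitter density, so
the correction is a straight line fitted on simulated data processed
with exactly the same settings as real data:

    DOL = degree_of_colocalization / (cf_slope * density + cf_offset)

The correction factors are fitter-specific by construction: a
calibration is stamped with a hash of the analysis settings that
produced it, and applying it under different settings raises a warning.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DensityCalibration",
    "CalibrationError",
    "calibrate_recall",
    "correct_dol",
    "config_hash",
    "write_calibration",
    "read_calibration",
]


class CalibrationError(RuntimeError):
    pass


def config_hash(config) -> str:
    """Stable short hash of the analysis settings a calibration is keyed to."""
    payload = repr(config.to_dict() if hasattr(config, "to_dict") else config)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class DensityCalibration:
    """Recall-vs-density line: recall(rho) = cf_slope * rho + cf_offset."""

    cf_slope: float
    cf_offset: float
    density_range_um2: tuple[float, float]
    r_squared: float
    provenance: str = ""
    settings_hash: str = ""
    points: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (0 < self.cf_offset <= 1.05):
            raise CalibrationError(
                f"cf_offset {self.cf_offset:.3f} outside (0, 1.05]: calibration rejected"
            )
        lo, hi = self.density_range_um2
        for rho in (lo, hi):
            if self.cf_slope * rho + self.cf_offset <= 0:
                raise CalibrationError(
                    "correction denominator non-positive inside the validity range"
                )

    @classmethod
    def identity(cls) -> "DensityCalibration":
        """No-op calibration (recall 1 at every density)."""
        return cls(0.0, 1.0, (0.0, np.inf), 1.0, provenance="identity")


def calibrate_recall(
    sim_config,
    analysis_config,
    density_grid_um2=(0.05, 0.125, 0.2, 0.35, 0.5),
    true_dol: float = 0.5,
    n_replicates: int = 4,
    seed: int = 0,
) -> DensityCalibration:
    """Fit the recall-vs-density line from end-to-end simulations.

    For each density on the grid, ``n_replicates`` cells are simulated
    and pushed through the full pipeline (segmentation -> localization ->
    registration -> colocalization) with the supplied analysis settings;
    per-cell recall = degree of colocalization / ``true_dol`` is then
    regressed (OLS) on the per-cell measured reference density.  The
    measured density — reference localizations per um^2 of cell mask — is
    the regressor because it is also the quantity available on real data.
    """
    from .dolreport import analyze_experiment
    from .sim import simulate_experiment

    density_grid = tuple(density_grid_um2)
    if len(density_grid) < 3:
        raise ValueError("density grid needs at least 3 points")
    if not (0 < true_dol <= 1):
        raise ValueError("true_dol must be in (0, 1]")

    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=len(density_grid))

    rows = []
    for rho, s in zip(density_grid, sub_seeds):
        cfg = sim_config.replace(probe_density_um2=float(rho), true_dol=float(true_dol))
        cells = simulate_experiment(cfg, n_replicates, int(s))
        results, _ = analyze_experiment(
            [(c.reference, c.target) for c in cells], analysis_config
        )
        for cell, r in zip(cells, results):
            if not r.usable:
                continue
            # recall against the cell's *realized* labeled fraction (the
            # simulation's ground truth), not the nominal one: at low
            # probe counts the binomial draw noise would otherwise
            # propagate straight into the fitted intercept
            probes = cell.ground_truth.probes
            realized = float(probes["has_target"].mean()) if len(probes) else float("nan")
            if not np.isfinite(realized) or realized <= 0:
                continue
            rows.append(
                {
                    "density_true_um2": rho,
                    "density_measured_um2": r.density_measured_um2,
                    # specific (chance-subtracted) colocalization, the
                    # same quantity the correction is applied to
                    "recall": r.specific_colocalization / realized,
                    "n_reference": r.n_reference,
                }
            )
    points = pd.DataFrame(rows)
    if len(points) < 3:
        raise CalibrationError("too few usable simulated cells for calibration")

    x = points["density_measured_um2"].to_numpy()
    y = points["recall"].to_numpy()
    # weight cells by their reference count: each localization is one
    # Bernoulli trial of the colocalization fraction, so sparse cells
    # carry proportionally less information about the line
    wts = np.sqrt(points["n_reference"].to_numpy(dtype=float))
    slope, offset = np.polyfit(x, y, 1, w=wts)
    pred = slope * x + offset
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    provenance = hashlib.sha1(
        (repr(sim_config) + repr(density_grid) + repr(true_dol) + repr(seed)).encode()
    ).hexdigest()[:12]
    return DensityCalibration(
        cf_slope=float(slope),
        cf_offset=float(offset),
        density_range_um2=(float(x.min()), float(x.max())),
        r_squared=r2,
        provenance=provenance,
        settings_hash=config_hash(analysis_config),
        points=points,
    )


def correct_dol(
    degree_of_colocalization: float,
    density_measured_um2: float,
    calibration: DensityCalibration,
) -> float:
    """Density-corrected degree of labeling.

    The quotient is clipped to [0, 1.5]; values above 1 trigger an
    out-of-range warning (they indicate a miscalibration or a density far
    outside the validity range).
    """
    lo, hi = calibration.density_range_um2
    if not (lo <= density_measured_um2 <= hi):
        warnings.warn(
            f"measured density {density_measured_um2:.3g}/um^2 outside the "
            f"calibration range [{lo:.3g}, {hi:.3g}]"
        )
    denom = calibration.cf_slope * density_measured_um2 + calibration.cf_offset
    if denom <= 0:
        raise CalibrationError("correction denominator <= 0 at the measured density")
    dol = degree_of_colocalization / denom
    if dol > 1.0:
        warnings.warn(f"corrected DOL {dol:.3f} exceeds 1; clipping to [0, 1.5]")
    return float(np.clip(dol, 0.0, 1.5))


def write_calibration(calibration: DensityCalibration, path) -> None:
    pd.DataFrame(
        [
            {
                "cf_slope": calibration.cf_slope,
                "cf_offset": calibration.cf_offset,
                "density_min_um2": calibration.density_range_um2[0],
                "density_max_um2": calibration.density_range_um2[1],
                "r_squared": calibration.r_squared,
                "provenance": calibration.provenance,
                "settings_hash": calibration.settings_hash,
            }
        ]
    ).to_csv(path, index=False, float_format="%.8g")


def read_calibration(path) -> DensityCalibration:
    row = pd.read_csv(path).iloc[0]
    return DensityCalibration(
        cf_slope=float(row["cf_slope"]),
        cf_offset=float(row["cf_offset"]),
        density_range_um2=(float(row["density_min_um2"]), float(row["density_max_um2"])),
        r_squared=float(row["r_squared"]),
        provenance=str(row.get("provenance", "")),
        settings_hash=str(row.get("settings_hash", "")),
    )
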
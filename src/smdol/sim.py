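"""Synthetic dual-channel single-molecule image generation.

Emulates the measurement this package analyses: membrane-anchored probes
carrying an always-present reference fluorophore (eGFP-like) and, with
probability equal to the true degree of labeling, a target-tag label.
Probes sit inside an irregular cell footprint at 0.01-1 emitters/um^2;
unspecific target-only emitters are Poisson-distributed over the whole
frame.  Each channel is rendered as the average of several
diffraction-limited camera frames with two-state blinking, permanent
bleaching, Poisson shot noise and an emCCD-style gain/offset/read-noise
model.  The target channel is displaced by a configurable chromatic
affine transform, which the analysis pipeline must estimate and undo.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import erf

from .io import Image2D, write_image
from .registration import AffineTransform2D

__all__ = [
    "Photophysics",
    "CameraModel",
    "SimulationGroundTruth",
    "SimConfig",
    "CellSim",
    "make_cell_region",
    "place_probes",
    "render_channel",
    "simulate_experiment",
    "write_experiment",
]


@dataclass(frozen=True)
class Photophysics:
    """Fluorophore kinetics for one channel.

    ``on_time`` and ``off_time`` are unitless mean dwell times; only their
    ratio matters because per-frame visibility is modelled as a Bernoulli
    draw with p = on/(on+off) (frames are averaged downstream, so temporal
    correlation of the telegraph process is immaterial to the averaged
    image).  ``bleach_constant`` is the probability that a fluorophore
    bleaches during the whole acquisition; ``photons_per_s`` the emission
    rate while on.
    """

    on_time: float = 0.025
    off_time: float = 0.01
    bleach_constant: float = 0.2
    photons_per_s: float = 350.0
    labels_per_epitope: int = 1

    def __post_init__(self) -> None:
        if self.on_time <= 0 or self.off_time < 0:
            raise ValueError("on_time must be > 0 and off_time >= 0")
        if not (0 <= self.bleach_constant < 1):
            raise ValueError("bleach_constant must be in [0, 1)")
        if self.photons_per_s <= 0:
            raise ValueError("photons_per_s must be positive")
        if self.labels_per_epitope < 1:
            raise ValueError("labels_per_epitope must be >= 1")

    @property
    def duty_cycle(self) -> float:
        return self.on_time / (self.on_time + self.off_time)


#: Reference-channel kinetics: eGFP imaged as a nearly background-free,
#: non-blinking marker (duty cycle 1, no bleaching within the short stack).
REFERENCE_PHOTOPHYSICS = Photophysics(on_time=1.0, off_time=0.0, bleach_constant=0.0, photons_per_s=350.0)


@dataclass(frozen=True)
class CameraModel:
    """emCCD-style camera: counts = gain * Poisson(qe * photons) + offset + read noise."""

    pixel_size_nm: float = 160.0
    gain: float = 1.0
    offset: float = 100.0
    read_noise: float = 1.5
    qe: float = 0.9
    exposure_s: float = 1.0

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0 or self.gain <= 0 or self.exposure_s <= 0:
            raise ValueError("pixel_size_nm, gain and exposure_s must be positive")
        if not (0 < self.qe <= 1):
            raise ValueError("qe must be in (0, 1]")


@dataclass
class SimulationGroundTruth:
    """True emitter configuration for one simulated cell.

    ``probes`` holds one row per membrane probe (x_nm, y_nm,
    has_reference, has_target); ``unspecific`` holds target-only emitters.
    Coordinates are true physical positions; the chromatic transform is
    applied to target-channel coordinates only at render time.
    """

    frame_size_px: tuple[int, int]
    pixel_size_nm: float
    cell_mask: np.ndarray
    probes: pd.DataFrame
    unspecific: pd.DataFrame
    true_dol: float
    true_unspec_density: float
    chromatic_transform: AffineTransform2D
    seed: int

    @property
    def cell_area_um2(self) -> float:
        return float(self.cell_mask.sum()) * (self.pixel_size_nm / 1000.0) ** 2

    @property
    def frame_area_um2(self) -> float:
        r, c = self.frame_size_px
        return r * c * (self.pixel_size_nm / 1000.0) ** 2

    def channel_positions(self, channel: str, apply_chromatic: bool = True) -> np.ndarray:
        """True (x_nm, y_nm) of emitters visible in a channel.

        For the target channel the chromatic transform is applied (these
        are the apparent positions in the target image).
        """
        if channel == "reference":
            sel = self.probes[self.probes["has_reference"]]
            return sel[["x_nm", "y_nm"]].to_numpy(dtype=float)
        if channel == "target":
            sel = self.probes[self.probes["has_target"]]
            xy = np.concatenate(
                [
                    sel[["x_nm", "y_nm"]].to_numpy(dtype=float),
                    self.unspecific[["x_nm", "y_nm"]].to_numpy(dtype=float),
                ],
                axis=0,
            )
            if apply_chromatic and len(xy):
                xy = self.chromatic_transform.apply(xy)
            return xy
        raise ValueError(f"unknown channel {channel!r}")

    def to_table(self) -> pd.DataFrame:
        probes = self.probes.copy()
        probes["species"] = "probe"
        unspec = self.unspecific.copy()
        unspec["has_reference"] = False
        unspec["has_target"] = True
        unspec["species"] = "unspecific"
        return pd.concat([probes, unspec], ignore_index=True)


def make_cell_region(
    frame_size_px: tuple[int, int],
    target_area_fraction: float,
    seed: int,
) -> np.ndarray:
    """Generate an irregular, simply connected cell footprint.

    The region is star-convex around the frame centre with a smooth
    random-Fourier boundary, so it is guaranteed connected and hole-free.
    Its radius is bisected until the achieved area fraction is within 2%
    of the target (before clipping at the frame edge).
    """
    rows, cols = frame_size_px
    if min(rows, cols) < 16:
        raise ValueError(f"frame too small: {frame_size_px} (min dimension 16 px)")
    if not (0 < target_area_fraction <= 1):
        raise ValueError("target_area_fraction must be in (0, 1]")
    if target_area_fraction == 1.0:
        return np.ones((rows, cols), dtype=bool)

    rng = np.random.default_rng(seed)
    n_harmonics = 4
    amps = rng.uniform(0.03, 0.12, size=n_harmonics)
    phases = rng.uniform(0, 2 * np.pi, size=n_harmonics)
    orders = np.arange(2, 2 + n_harmonics)

    rr, cc = np.mgrid[0:rows, 0:cols]
    dy = rr + 0.5 - rows / 2.0
    dx = cc + 0.5 - cols / 2.0
    radius = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    boundary_shape = 1.0 + sum(
        a * np.cos(k * theta + p) for a, k, p in zip(amps, orders, phases)
    )

    total = rows * cols
    lo, hi = 1.0, float(max(rows, cols))
    mask = None
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        mask = radius <= mid * boundary_shape
        frac = mask.sum() / total
        if abs(frac - target_area_fraction) < 0.02 * target_area_fraction:
            break
        if frac < target_area_fraction:
            lo = mid
        else:
            hi = mid
    return mask


def place_probes(
    cell_mask: np.ndarray,
    probe_density_um2: float,
    true_dol: float,
    unspec_density_um2: float,
    pixel_size_nm: float,
    seed: int,
    ref_dark_fraction: float = 0.0,
    chromatic_transform: AffineTransform2D | None = None,
) -> SimulationGroundTruth:
    """Draw a ground-truth probe configuration.

    Probe count is Poisson(density x mask area); positions are uniform
    over the mask region; each probe independently carries a target label
    with probability ``true_dol``.  All probes carry the reference marker
    unless ``ref_dark_fraction`` > 0 (immature eGFP).  Unspecific emitters
    are uniform over the full frame at ``unspec_density_um2``.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if probe_density_um2 < 0 or unspec_density_um2 < 0:
        raise ValueError("densities must be >= 0")
    if not (0 <= true_dol <= 1):
        raise ValueError("true_dol must be in [0, 1]")
    if not cell_mask.any():
        raise ValueError("cell mask is empty: no cell to populate")

    rng = np.random.default_rng(seed)
    px_um = pixel_size_nm / 1000.0
    mask_area_um2 = cell_mask.sum() * px_um**2
    rows, cols = cell_mask.shape

    n_probes = rng.poisson(probe_density_um2 * mask_area_um2)
    mask_r, mask_c = np.nonzero(cell_mask)
    pick = rng.integers(0, len(mask_r), size=n_probes)
    x_nm = (mask_c[pick] + rng.random(n_probes)) * pixel_size_nm
    y_nm = (mask_r[pick] + rng.random(n_probes)) * pixel_size_nm
    has_target = rng.random(n_probes) < true_dol
    has_reference = rng.random(n_probes) >= ref_dark_fraction
    probes = pd.DataFrame(
        {"x_nm": x_nm, "y_nm": y_nm, "has_reference": has_reference, "has_target": has_target}
    )

    frame_area_um2 = rows * cols * px_um**2
    n_unspec = rng.poisson(unspec_density_um2 * frame_area_um2)
    unspecific = pd.DataFrame(
        {
            "x_nm": rng.random(n_unspec) * cols * pixel_size_nm,
            "y_nm": rng.random(n_unspec) * rows * pixel_size_nm,
        }
    )

    return SimulationGroundTruth(
        frame_size_px=(rows, cols),
        pixel_size_nm=pixel_size_nm,
        cell_mask=cell_mask,
        probes=probes,
        unspecific=unspecific,
        true_dol=float(true_dol),
        true_unspec_density=float(unspec_density_um2),
        chromatic_transform=chromatic_transform or AffineTransform2D.identity(),
        seed=int(seed),
    )


def _pixel_integrated_psf(xy_nm: np.ndarray, shape, pixel_size_nm, psf_sigma_nm):
    """Per-emitter unit-photon pixel stamps (erf-integrated Gaussian).

    Returns a list of ((row_slice, col_slice), stamp) pairs; emitters
    outside the frame contribute only whatever tail overlaps it.
    """
    rows, cols = shape
    half_px = int(np.ceil(4.0 * psf_sigma_nm / pixel_size_nm)) + 1
    stamps = []
    s = psf_sigma_nm * np.sqrt(2.0)
    for x_nm, y_nm in xy_nm:
        c0 = int(np.floor(x_nm / pixel_size_nm))
        r0 = int(np.floor(y_nm / pixel_size_nm))
        c_lo, c_hi = max(0, c0 - half_px), min(cols, c0 + half_px + 1)
        r_lo, r_hi = max(0, r0 - half_px), min(rows, r0 + half_px + 1)
        if c_lo >= c_hi or r_lo >= r_hi:
            stamps.append(None)
            continue
        edges_x = np.arange(c_lo, c_hi + 1) * pixel_size_nm
        edges_y = np.arange(r_lo, r_hi + 1) * pixel_size_nm
        fx = 0.5 * (erf((edges_x[1:] - x_nm) / s) - erf((edges_x[:-1] - x_nm) / s))
        fy = 0.5 * (erf((edges_y[1:] - y_nm) / s) - erf((edges_y[:-1] - y_nm) / s))
        stamps.append(((slice(r_lo, r_hi), slice(c_lo, c_hi)), np.outer(fy, fx)))
    return stamps


def render_channel(
    ground_truth: SimulationGroundTruth,
    channel: str,
    photophysics: Photophysics,
    camera: CameraModel,
    psf_sigma_nm: float,
    n_frames: int,
    background_level: float,
    seed: int,
    cell_background_level: float = 0.0,
) -> Image2D:
    """Render one channel as the average of ``n_frames`` camera frames.

    ``background_level`` is the mean detected background in
    photons/pixel/frame over the whole frame; ``cell_background_level``
    adds diffuse cellular fluorescence inside the cell footprint.  Each
    fluorophore is on in a frame with probability equal to its duty cycle
    and bleaches permanently with per-frame hazard
    ``bleach_constant / n_frames`` (so the configured constant refers to
    the whole acquisition).
    """
    if psf_sigma_nm <= 0:
        raise ValueError("psf_sigma_nm must be positive")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")

    rng = np.random.default_rng(seed)
    shape = ground_truth.frame_size_px
    xy = ground_truth.channel_positions(channel)
    n_emitters = len(xy)
    n_labels = photophysics.labels_per_epitope

    stamps = _pixel_integrated_psf(xy, shape, camera.pixel_size_nm, psf_sigma_nm)

    duty = photophysics.duty_cycle
    hazard = photophysics.bleach_constant / n_frames
    photons_frame = photophysics.photons_per_s * camera.exposure_s

    # (n_frames, n_emitters) expected detected photons per emitter per frame
    if n_emitters:
        alive = np.ones((n_frames, n_emitters, n_labels), dtype=bool)
        if hazard > 0:
            bleach_draw = rng.random((n_frames, n_emitters, n_labels)) < hazard
            dead = np.cumsum(bleach_draw, axis=0) > 0
            # a label that bleaches in frame k is dark from frame k on
            alive = ~dead
        on = rng.random((n_frames, n_emitters, n_labels)) < duty
        emitting = (alive & on).sum(axis=2)  # number of emitting labels
        expected = emitting * photons_frame * camera.qe
    else:
        expected = np.zeros((n_frames, 0))

    background = np.full(shape, background_level, dtype=float)
    if cell_background_level:
        background = background + cell_background_level * ground_truth.cell_mask

    acc = np.zeros(shape, dtype=float)
    for k in range(n_frames):
        lam = background.copy()
        for e in range(n_emitters):
            if stamps[e] is None or expected[k, e] == 0:
                continue
            sl, stamp = stamps[e]
            lam[sl] += expected[k, e] * stamp
        frame = rng.poisson(lam).astype(float) * camera.gain + camera.offset
        if camera.read_noise > 0:
            frame += rng.normal(0.0, camera.read_noise, size=shape)
        acc += frame
    acc /= n_frames

    return Image2D(
        acc,
        pixel_size_nm=camera.pixel_size_nm,
        channel_name=channel,
        n_frames_averaged=n_frames,
    )


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated experiment.

    Defaults reflect a typical TIRF degree-of-labeling measurement:
    256x256 px frames at 160 nm pixel pitch, a cell covering ~35% of the
    frame, 10-20 averaged frames, target-dye blinking with duty cycle
    0.025/0.035 and a whole-acquisition bleaching probability of 0.2 at
    350 emitted photons per second, and a sub-pixel chromatic offset
    between channels.
    """

    frame_size_px: tuple[int, int] = (256, 256)
    cell_area_fraction: float = 0.35
    probe_density_um2: float = 0.2
    true_dol: float = 0.5
    unspec_density_um2: float = 0.03
    ref_dark_fraction: float = 0.0
    camera: CameraModel = field(default_factory=CameraModel)
    reference_photophysics: Photophysics = REFERENCE_PHOTOPHYSICS
    target_photophysics: Photophysics = field(default_factory=Photophysics)
    ref_psf_sigma_nm: float = 140.0
    target_psf_sigma_nm: float = 170.0
    n_frames: int = 15
    background_level: float = 5.0
    cell_background_level: float = 3.0
    chromatic_shift_x_nm: float = 110.0
    chromatic_shift_y_nm: float = -70.0
    chromatic_rotation_deg: float = 0.15
    chromatic_scale: float = 1.002

    @property
    def pixel_size_nm(self) -> float:
        return self.camera.pixel_size_nm

    @property
    def chromatic_transform(self) -> AffineTransform2D:
        return AffineTransform2D.from_params(
            shift_x_nm=self.chromatic_shift_x_nm,
            shift_y_nm=self.chromatic_shift_y_nm,
            rotation_deg=self.chromatic_rotation_deg,
            scale_x=self.chromatic_scale,
            scale_y=self.chromatic_scale,
        )

    def replace(self, **changes) -> "SimConfig":
        return dataclasses.replace(self, **changes)


@dataclass
class CellSim:
    reference: Image2D
    target: Image2D
    ground_truth: SimulationGroundTruth


def simulate_experiment(config: SimConfig, n_cells: int, seed: int) -> list[CellSim]:
    """Simulate ``n_cells`` dual-channel measurements under one condition.

    Per-cell seeds are derived deterministically from the master seed, so
    the experiment is a pure function of (config, n_cells, seed).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    master = np.random.default_rng(seed)
    cell_seeds = master.integers(0, 2**31 - 1, size=(n_cells, 4))
    cells = []
    for k in range(n_cells):
        s_mask, s_place, s_ref, s_tgt = (int(v) for v in cell_seeds[k])
        mask = make_cell_region(config.frame_size_px, config.cell_area_fraction, s_mask)
        gt = place_probes(
            mask,
            config.probe_density_um2,
            config.true_dol,
            config.unspec_density_um2,
            config.pixel_size_nm,
            s_place,
            ref_dark_fraction=config.ref_dark_fraction,
            chromatic_transform=config.chromatic_transform,
        )
        ref_img = render_channel(
            gt,
            "reference",
            config.reference_photophysics,
            config.camera,
            config.ref_psf_sigma_nm,
            config.n_frames,
            config.background_level,
            s_ref,
            cell_background_level=config.cell_background_level,
        )
        tgt_img = render_channel(
            gt,
            "target",
            config.target_photophysics,
            config.camera,
            config.target_psf_sigma_nm,
            config.n_frames,
            config.background_level,
            s_tgt,
            cell_background_level=0.3 * config.cell_background_level,
        )
        cells.append(CellSim(reference=ref_img, target=tgt_img, ground_truth=gt))
    return cells


def write_experiment(cells: list[CellSim], out_dir, config: SimConfig | None = None) -> None:
    """Write per-cell channel TIFFs, ground-truth CSVs and a config echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for k, cell in enumerate(cells):
        stem = f"cell{k:03d}"
        write_image(cell.reference, out / f"{stem}_reference.tif")
        write_image(cell.target, out / f"{stem}_target.tif")
        cell.ground_truth.to_table().to_csv(out / f"{stem}_groundtruth.csv", index=False)
    if config is not None:
        import yaml

        payload = dataclasses.asdict(config)
        with open(out / "sim_config.yaml", "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
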
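"""Synthetic time-lapse well plates with known ground truth.

Emulates what the imaging rig sees: per well and per imaging day, a Z-stack
of grayscale planes showing dark, roughly circular tumouroids on a bright
noisy background.  Each object sits at one focal plane; on other planes it
is blurred by an isotropic Gaussian whose width grows linearly with the
defocus distance, which is what makes best-focus selection meaningful.
Disk edges are anti-aliased (partial-coverage intensity at boundary
pixels), so threshold placement has realistic sub-pixel consequences.

The growth model is exponential in radius: r(t) = r0·exp(g·t) for an
unperturbed object.  Drug exposure scales the growth rate by (1 − i(c))
during the exposure window, where i(c) = c^h / (c^h + IC50^h) is a Hill
inhibition curve; the default timeline (treatment from day 2, for 7 days)
mirrors a two-week ex vivo drug screen.  Everything the pipeline should
recover — object geometry per day, per-well union area, the IC50 — is
recorded as ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .projection import ZStack


class PlacementError(RuntimeError):
    """An object could not be placed inside the frame under the constraints."""


@dataclass(frozen=True)
class SimConfig:
    """Scenario parameters for one simulated plate.

    Defaults describe a two-week screen on a 24-well plate imaged at low
    magnification: a 5-step, 10-fold dose ladder from 0.1 to 1000 nM plus
    vehicle, tumouroids seeded from a 40–200 µm size fraction, treatment
    from day 2 for 7 days.
    """

    image_size: tuple[int, int] = (512, 512)  # (H, W) pixels
    n_planes: int = 5
    plane_spacing: float = 50.0  # µm between planes
    pixel_size: float = 2.0  # µm/pixel
    n_objects: int = 20  # objects per well
    radius_range: tuple[float, float] = (25.0, 80.0)  # µm at day 0
    growth_rate: float = 0.08  # relative radius growth per day
    days: tuple[int, ...] = tuple(range(1, 15))  # imaging days
    doses: tuple[float, ...] = (0.0, 0.1, 1.0, 10.0, 100.0, 1000.0)  # nM, 0 = vehicle
    ic50_true: float = 10.0  # nM
    hill_true: float = 1.0
    treatment_start_day: float = 2.0
    treatment_duration: float = 7.0  # days of drug exposure
    background_level: float = 0.85  # intensities in [0, 1]
    object_level: float = 0.35
    noise_sd: float = 0.01
    blur_per_um_defocus: float = 0.04  # PSF sigma in px per µm of defocus
    min_separation: float | None = None  # µm between object centers, optional
    polarity: str = "dark_objects"
    sample_id: str = "S1"
    drug: str = "SN-38"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_range[0] <= 0 or self.radius_range[1] < self.radius_range[0]:
            raise ValueError("radius_range must satisfy 0 < min <= max")
        if not (0.0 <= self.object_level < self.background_level <= 1.0):
            raise ValueError("need 0 <= object_level < background_level <= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValueError("days must be strictly increasing")
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be non-negative")
        if self.polarity not in ("dark_objects", "bright_objects"):
            raise ValueError(f"unknown polarity: {self.polarity!r}")
        if self.n_objects < 0 or self.n_planes < 1:
            raise ValueError("n_objects must be >= 0 and n_planes >= 1")


@dataclass
class SimObject:
    object_id: int
    center: tuple[float, float]  # (row, col) pixels
    z_plane: int
    radius_by_day: dict[int, float]  # µm, keyed by imaging day


@dataclass
class WellTruth:
    """Ground truth for one well: geometry per day plus condition metadata."""

    well_id: str
    well_index: int
    sample_id: str
    dose: float  # nM; 0 = vehicle
    replicate: int
    is_vehicle: bool
    objects: list[SimObject]
    total_area_by_day: dict[int, float] = field(default_factory=dict)  # µm², union


@dataclass
class SimulatedPlate:
    config: SimConfig
    wells: list[WellTruth]
    plate_map: pd.DataFrame
    stacks: dict[tuple[str, int], ZStack] = field(default_factory=dict)

    def ground_truth_frame(self) -> pd.DataFrame:
        rows = []
        for well in self.wells:
            for obj in well.objects:
                for day, r in obj.radius_by_day.items():
                    rows.append(
                        {
                            "object_id": obj.object_id,
                            "well_id": well.well_id,
                            "day": day,
                            "cx_px": obj.center[1],
                            "cy_px": obj.center[0],
                            "z_plane": obj.z_plane,
                            "radius_um": r,
                        }
                    )
        return pd.DataFrame(
            rows,
            columns=["object_id", "well_id", "day", "cx_px", "cy_px", "z_plane", "radius_um"],
        )


def inhibition_fraction(c: float, ic50: float, h: float) -> float:
    """Hill inhibition i(c) = c^h / (c^h + IC50^h), in [0, 1]."""
    if ic50 <= 0 or h <= 0:
        raise ValueError("ic50 and h must be positive")
    if c < 0:
        raise ValueError("concentration must be non-negative")
    if c == 0:
        return 0.0
    # work in log space for numerical safety at extreme ratios
    z = h * (np.log(c) - np.log(ic50))
    return float(1.0 / (1.0 + np.exp(-z)))


def grow_radius(r0: float, g: float, inhibition: float, t: float) -> float:
    """Radius after ``t`` days of growth at rate g·(1 − inhibition)."""
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    if t < 0:
        raise ValueError("t must be non-negative")
    if not 0.0 <= inhibition <= 1.0:
        raise ValueError("inhibition must be in [0, 1]")
    return float(r0 * np.exp(g * (1.0 - inhibition) * t))


def _radius_at(r0: float, config: SimConfig, inhibition: float, t: float) -> float:
    """Radius at day ``t`` with inhibition active only during drug exposure."""
    t0 = config.treatment_start_day
    exposure = float(np.clip(min(t, t0 + config.treatment_duration) - t0, 0.0, None))
    free = t - exposure
    r = grow_radius(r0, config.growth_rate, 0.0, free)
    if exposure > 0:
        r = grow_radius(r, config.growth_rate, inhibition, exposure)
    return r


def _union_area(objects: list[SimObject], day: int, config: SimConfig) -> float:
    """Pixel area of the union of the (sharp) disks, in µm²."""
    h, w = config.image_size
    mask = np.zeros((h, w), dtype=bool)
    yy, xx = np.ogrid[:h, :w]
    for obj in objects:
        r_px = obj.radius_by_day[day] / config.pixel_size
        cy, cx = obj.center
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
    return float(mask.sum()) * config.pixel_size**2


def _place_objects(well: WellTruth, config: SimConfig, rng: np.random.Generator) -> None:
    """Draw object geometry for one well and fill in per-day ground truth.

    The caller seeds ``rng`` by replicate index, not well index, so wells of
    the same replicate share layouts across doses — a paired design under
    which the dose effect on true area is exactly monotone.  Placement
    margins use the uninhibited final radius, so objects stay inside the
    frame at every dose.
    """
    h, w = config.image_size
    inh = inhibition_fraction(well.dose, config.ic50_true, config.hill_true) if well.dose > 0 else 0.0
    final_day = max(config.days)
    centers: list[tuple[float, float]] = []
    for i in range(config.n_objects):
        r0 = float(rng.uniform(*config.radius_range))
        z = int(rng.integers(0, config.n_planes))
        r_final_px = _radius_at(r0, config, 0.0, final_day) / config.pixel_size
        margin = r_final_px + 1.0
        if 2 * margin >= min(h, w):
            raise PlacementError(
                f"object radius {r_final_px:.0f} px at day {final_day} does not fit the frame"
            )
        for _ in range(2000):
            cy = float(rng.uniform(margin, h - margin))
            cx = float(rng.uniform(margin, w - margin))
            if config.min_separation is not None:
                sep_px = config.min_separation / config.pixel_size
                if any((cy - y) ** 2 + (cx - x) ** 2 < sep_px**2 for y, x in centers):
                    continue
            break
        else:
            raise PlacementError("could not satisfy min_separation after 2000 attempts")
        centers.append((cy, cx))
        radius_by_day = {day: _radius_at(r0, config, inh, day) for day in config.days}
        well.objects.append(
            SimObject(object_id=i + 1, center=(cy, cx), z_plane=z, radius_by_day=radius_by_day)
        )
    for day in config.days:
        well.total_area_by_day[day] = _union_area(well.objects, day, config)


def render_zstack(well: WellTruth, day: int, config: SimConfig) -> ZStack:
    """Render the Z-stack for one well on one imaging day.

    Each plane shows every object as an anti-aliased disk, blurred by a
    Gaussian PSF of sigma = |plane − z| · plane_spacing · blur_per_um_defocus
    pixels; overlapping attenuations combine by maximum, so intensities stay
    within [object_level, background_level] before noise.  Noise is seeded
    from (rng_seed, well_index, day) so any stack is reproducible in
    isolation, independent of rendering order.
    """
    if day not in config.days:
        raise ValueError(f"day {day} is not an imaging day of this scenario")
    h, w = config.image_size
    contrast = config.background_level - config.object_level
    planes = np.empty((config.n_planes, h, w), dtype=np.float64)
    for p in range(config.n_planes):
        att = np.zeros((h, w), dtype=np.float64)
        for obj in well.objects:
            r_px = obj.radius_by_day[day] / config.pixel_size
            sigma = abs(p - obj.z_plane) * config.plane_spacing * config.blur_per_um_defocus
            pad = int(np.ceil(r_px + 0.5 + 4.0 * sigma + 2.0))
            cy, cx = obj.center
            r0_, r1_ = max(0, int(cy) - pad), min(h, int(cy) + pad + 1)
            c0_, c1_ = max(0, int(cx) - pad), min(w, int(cx) + pad + 1)
            if r0_ >= r1_ or c0_ >= c1_:
                continue
            yy, xx = np.ogrid[r0_:r1_, c0_:c1_]
            dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
            cov = np.clip(r_px + 0.5 - dist, 0.0, 1.0)
            if sigma > 0:
                cov = ndimage.gaussian_filter(cov, sigma, truncate=4.0)
            region = att[r0_:r1_, c0_:c1_]
            np.maximum(region, cov, out=region)
        if config.polarity == "dark_objects":
            plane = config.background_level - contrast * att
        else:
            plane = config.background_level + contrast * att
        if config.noise_sd > 0:
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=config.rng_seed, spawn_key=(1, well.well_index, day, p))
            )
            plane = plane + rng.normal(0.0, config.noise_sd, size=plane.shape)
        planes[p] = np.clip(plane, 0.0, 1.0)
    return ZStack(
        planes=planes,
        pixel_size=config.pixel_size,
        plane_spacing=config.plane_spacing,
        well_id=well.well_id,
        day=day,
    )


def simulate_plate(config: SimConfig, n_replicates: int = 4, render: bool = True) -> SimulatedPlate:
    """Simulate one plate: one well per (dose, replicate).

    Returns ground truth, a plate map matching the pipeline's schema and,
    when ``render`` is true, the Z-stacks themselves.  Identical configs
    (including the seed) give bit-identical outputs.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    wells: list[WellTruth] = []
    rows = []
    idx = 0
    for d_i, dose in enumerate(config.doses):
        for rep in range(1, n_replicates + 1):
            well_id = f"{chr(ord('A') + rep - 1)}{d_i + 1:02d}"
            well = WellTruth(
                well_id=well_id,
                well_index=idx,
                sample_id=config.sample_id,
                dose=float(dose),
                replicate=rep,
                is_vehicle=dose == 0,
                objects=[],
            )
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=config.rng_seed, spawn_key=(0, rep))
            )
            _place_objects(well, config, rng)
            wells.append(well)
            rows.append(
                {
                    "well_id": well_id,
                    "sample_id": config.sample_id,
                    "drug": config.drug if dose > 0 else "vehicle",
                    "concentration_nM": float(dose),
                    "replicate": rep,
                    "is_vehicle": dose == 0,
                }
            )
            idx += 1
    plate_map = pd.DataFrame(
        rows, columns=["well_id", "sample_id", "drug", "concentration_nM", "replicate", "is_vehicle"]
    )
    plate = SimulatedPlate(config=config, wells=wells, plate_map=plate_map)
    if render:
        for well in wells:
            for day in config.days:
                plate.stacks[(well.well_id, day)] = render_zstack(well, day, config)
    return plate


def write_plate(plate: SimulatedPlate, outdir: str | Path) -> None:
    """Write the plate to disk: one 16-bit multi-page TIFF per (well, day),
    a plate-map CSV and a ground-truth CSV."""
    outdir = Path(outdir)
    stacks_dir = outdir / "stacks"
    stacks_dir.mkdir(parents=True, exist_ok=True)
    for (well_id, day), stack in sorted(plate.stacks.items()):
        data = np.round(np.clip(stack.planes, 0.0, 1.0) * 65535.0).astype(np.uint16)
        tifffile.imwrite(
            stacks_dir / f"{well_id}_d{day}.tif",
            data,
            photometric="minisblack",
            software=False,
        )
    plate.plate_map.to_csv(outdir / "plate_map.csv", index=False)
    plate.ground_truth_frame().to_csv(outdir / "ground_truth.csv", index=False)
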
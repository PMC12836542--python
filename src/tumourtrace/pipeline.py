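"""End-to-end pipeline commands: simulate, quantify, fit, report.

Each command is a plain function taking a :class:`~tumourtrace.config.RunConfig`
and writing text outputs (CSV/JSON) into ``output_dir``, plus the verbatim
configuration for provenance.  Outputs are deterministic: the same inputs,
configuration and seed give byte-identical files.  Every well in the plate
map is accounted for either in the outputs or in the exclusion log.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import dose_response as dr
from . import readouts as ro
from . import segmentation as seg
from .config import RunConfig
from .projection import ZStack, best_focus_project
from .simulate import SimConfig, simulate_plate, write_plate

logger = logging.getLogger(__name__)

WELL_CSV_META = ["well_id", "sample_id", "drug", "concentration_nM", "replicate", "is_vehicle"]


class PipelineError(RuntimeError):
    pass


def _sim_config(config: RunConfig) -> SimConfig:
    return SimConfig(
        image_size=(config.sim_image_height, config.sim_image_width),
        n_planes=config.sim_n_planes,
        plane_spacing=config.sim_plane_spacing,
        pixel_size=config.pixel_size,
        n_objects=config.sim_n_objects,
        radius_range=(config.sim_radius_min, config.sim_radius_max),
        growth_rate=config.sim_growth_rate,
        days=config.sim_days,
        doses=config.sim_doses,
        ic50_true=config.sim_ic50,
        hill_true=config.sim_hill,
        treatment_start_day=config.sim_treatment_start,
        treatment_duration=config.sim_treatment_duration,
        background_level=config.sim_background_level,
        object_level=config.sim_object_level,
        noise_sd=config.sim_noise_sd,
        blur_per_um_defocus=config.sim_blur_per_um,
        min_separation=config.sim_min_separation,
        polarity=config.polarity,
        sample_id=config.sim_sample_id,
        drug=config.sim_drug,
        rng_seed=config.seed,
    )


def cmd_simulate(config: RunConfig) -> Path:
    """Simulate a plate and write stacks, plate map and ground truth."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    plate = simulate_plate(_sim_config(config), n_replicates=config.sim_replicates)
    write_plate(plate, outdir)
    config.write(outdir / "config.txt")
    return outdir


_STACK_RE = re.compile(r"^(?P<well>.+)_d(?P<day>\d+)\.tif$")


def _discover_stacks(input_dir: Path) -> dict[str, dict[int, Path]]:
    found: dict[str, dict[int, Path]] = {}
    for path in sorted(input_dir.glob("*.tif")):
        m = _STACK_RE.match(path.name)
        if m:
            found.setdefault(m.group("well"), {})[int(m.group("day"))] = path
    return found


def quantify_stack(stack: ZStack, config: RunConfig) -> list[seg.TumouroidObject]:
    """Project, threshold, binarize and measure one Z-stack."""
    projected = best_focus_project(stack, tile_size=config.tile_size)
    threshold = seg.select_threshold(projected, polarity=config.polarity, k=config.threshold_k)
    mask = seg.binarize(projected, threshold)
    return seg.label_and_filter(
        mask,
        pixel_size=config.pixel_size,
        min_area=config.min_area_um2,
        max_area=config.max_area_um2,
        exclude_border=config.exclude_border,
    )


def cmd_quantify(config: RunConfig) -> Path:
    """Run projection → segmentation → readouts over a plate on disk.

    Writes ``objects.csv`` (one row per segmented object), ``wells.csv``
    (one row per well/day with the seven readouts) and ``exclusions.csv``
    recording every (well, day) skipped and why.
    """
    input_dir = Path(config.input_dir)
    plate_map = pd.read_csv(config.plate_map)
    stacks = _discover_stacks(input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    object_rows: list[dict] = []
    well_rows: list[dict] = []
    exclusions: list[dict] = []
    for rec in plate_map.to_dict("records"):
        well_id = rec["well_id"]
        days = stacks.get(well_id, {})
        if not days:
            exclusions.append({"well_id": well_id, "day": -1, "reason": "no stack files found"})
            continue
        objects_by_day: dict[int, list[seg.TumouroidObject]] = {}
        for day, path in sorted(days.items()):
            try:
                planes = tifffile.imread(path)
                if np.issubdtype(planes.dtype, np.integer):
                    planes = planes.astype(np.float64) / np.iinfo(planes.dtype).max
                stack = ZStack(
                    planes=planes,
                    pixel_size=config.pixel_size,
                    well_id=well_id,
                    day=day,
                )
                objs = quantify_stack(stack, config)
            except Exception as exc:  # unreadable/degenerate stack: skip day, keep going
                logger.warning("skipping %s day %s: %s", well_id, day, exc)
                exclusions.append({"well_id": well_id, "day": day, "reason": str(exc)})
                continue
            objects_by_day[day] = objs
            for obj in objs:
                object_rows.append(
                    {
                        "well_id": well_id,
                        "day": day,
                        "label": obj.label,
                        "area_um2": obj.area,
                        "perimeter_um": obj.perimeter,
                        "diameter_um": obj.equivalent_diameter,
                        "circularity": obj.circularity,
                        "cx": obj.centroid[1],
                        "cy": obj.centroid[0],
                        "touches_border": obj.touches_border,
                    }
                )
        if not objects_by_day:
            exclusions.append({"well_id": well_id, "day": -1, "reason": "no usable days"})
            continue
        series = ro.well_readouts(
            objects_by_day,
            well_id=well_id,
            sample_id=rec["sample_id"],
            drug=rec["drug"],
            concentration_nM=float(rec["concentration_nM"]),
            replicate=int(rec["replicate"]),
            is_vehicle=bool(rec["is_vehicle"]),
        )
        if series.exclusion_reason:
            exclusions.append({"well_id": well_id, "day": series.anchor_day,
                               "reason": series.exclusion_reason})
        for day, row in series.data.iterrows():
            well_rows.append(
                {
                    **{k: rec[k] for k in WELL_CSV_META},
                    "day": day,
                    "anchor_day": series.anchor_day,
                    **{r: row[r] for r in ro.READOUTS},
                }
            )

    pd.DataFrame(
        object_rows,
        columns=["well_id", "day", "label", "area_um2", "perimeter_um", "diameter_um",
                 "circularity", "cx", "cy", "touches_border"],
    ).to_csv(outdir / "objects.csv", index=False)
    pd.DataFrame(
        well_rows, columns=WELL_CSV_META + ["day", "anchor_day"] + ro.READOUTS
    ).to_csv(outdir / "wells.csv", index=False)
    pd.DataFrame(exclusions, columns=["well_id", "day", "reason"]).to_csv(
        outdir / "exclusions.csv", index=False
    )
    config.write(outdir / "config.txt")
    return outdir


def load_well_series(wells_csv: str | Path) -> list[ro.WellTimeSeries]:
    """Rebuild per-well time series from a quantify-stage wells.csv."""
    table = pd.read_csv(wells_csv)
    out = []
    for well_id, group in table.groupby("well_id", sort=True):
        group = group.sort_values("day")
        meta = group.iloc[0]
        out.append(
            ro.WellTimeSeries(
                well_id=well_id,
                sample_id=str(meta["sample_id"]),
                drug=str(meta["drug"]),
                concentration_nM=float(meta["concentration_nM"]),
                replicate=int(meta["replicate"]),
                is_vehicle=bool(meta["is_vehicle"]),
                data=group.set_index("day")[ro.READOUTS],
                anchor_day=int(meta["anchor_day"]),
            )
        )
    return out


def fit_records(
    wells: list[ro.WellTimeSeries],
    readouts_to_fit,
    fit_days=(),
) -> tuple[list[dr.LL5Results], list[dict]]:
    """Fit one 5PL per (sample, day, readout) and collect serialisable records."""
    treated = [w for w in wells if not w.is_vehicle]
    if not treated:
        raise PipelineError("no treated wells")
    fits: list[dr.LL5Results] = []
    records: list[dict] = []
    samples = sorted({w.sample_id for w in wells})
    for sample in samples:
        s_wells = [w for w in wells if w.sample_id == sample]
        s_vehicle = [w for w in s_wells if w.is_vehicle]
        s_treated = [w for w in s_wells if not w.is_vehicle]
        days = sorted({int(d) for w in s_treated for d in w.data.index})
        if fit_days:
            days = [d for d in days if d in set(fit_days)]
        for day in days:
            for readout in readouts_to_fit:
                try:
                    points = dr.normalize_to_control(s_treated, s_vehicle, readout, day)
                    fit = dr.fit_ll5(points)
                except (ValueError, dr.DegenerateFitError) as exc:
                    logger.warning("fit skipped for %s day %s %s: %s", sample, day, readout, exc)
                    records.append(
                        {"sample_id": sample, "day": day, "readout": readout,
                         "error": str(exc)}
                    )
                    continue
                fits.append(fit)
                records.append(
                    {
                        "sample_id": sample,
                        "day": day,
                        "readout": readout,
                        "b": fit.b, "c": fit.c, "d": fit.d, "e": fit.e, "f": fit.f,
                        "ed50": fit.ed50,
                        "gi50": fit.gi50,
                        "converged": fit.converged,
                        "rss": fit.rss,
                        "n_points": fit.n_points,
                        "f_fixed": fit.f_fixed or fit.fallback_f1,
                        "ill_conditioned": fit.ill_conditioned,
                        "bse": fit.bse,
                    }
                )
    return fits, records


def cmd_fit(config: RunConfig) -> Path:
    """Fit dose–response models from a quantify-stage wells.csv.

    Writes ``fits.json`` (one record per sample/day/readout), ``curves.csv``
    (fitted responses on a dense log-dose grid for plotting) and
    ``ranking.csv`` (per day/readout sensitivity ranks when ≥2 samples).
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    wells_csv = Path(config.input_dir) / "wells.csv"
    if not wells_csv.exists():
        raise PipelineError(f"wells.csv not found in {config.input_dir}")
    wells = load_well_series(wells_csv)
    fits, records = fit_records(wells, config.readouts_to_fit, config.fit_days)

    with open(outdir / "fits.json", "w") as fh:
        json.dump(records, fh, indent=2, sort_keys=True)
        fh.write("\n")

    grid = np.geomspace(config.dose_min / 10.0, config.dose_max * 10.0, 101)
    curve_rows = []
    for fit in fits:
        if not np.isfinite(fit.b):
            continue
        pred = fit.predict(grid)
        for x, y in zip(grid, pred):
            curve_rows.append(
                {"sample_id": fit.sample_id, "day": fit.day, "readout": fit.readout,
                 "concentration_nM": x, "fitted_response": y}
            )
    pd.DataFrame(
        curve_rows,
        columns=["sample_id", "day", "readout", "concentration_nM", "fitted_response"],
    ).to_csv(outdir / "curves.csv", index=False)

    rank_rows = []
    by_key: dict[tuple, dict[str, dr.LL5Results]] = {}
    for fit in fits:
        by_key.setdefault((fit.day, fit.readout), {})[fit.sample_id] = fit
    for (day, readout), sample_fits in sorted(by_key.items()):
        if len(sample_fits) < 2:
            continue
        report = dr.sensitivity_report(sample_fits)
        for sample_id, row in report.iterrows():
            rank_rows.append({"day": day, "readout": readout, "sample_id": sample_id,
                              **row.to_dict()})
    pd.DataFrame(
        rank_rows,
        columns=["day", "readout", "sample_id", "max_inhibition", "ed50", "gi50",
                 "rank_max_inhibition", "rank_ed50", "rank_gi50"],
    ).to_csv(outdir / "ranking.csv", index=False)
    config.write(outdir / "config.txt")
    return outdir


def cmd_report(config: RunConfig) -> str:
    """Summarise a fit-stage output directory as human-readable text."""
    fits_path = Path(config.input_dir) / "fits.json"
    if not fits_path.exists():
        raise PipelineError(f"fits.json not found in {config.input_dir}")
    records = json.loads(fits_path.read_text())
    ok = [r for r in records if "error" not in r]
    lines = [f"{len(ok)} dose-response fits ({len(records) - len(ok)} skipped)"]
    for rec in ok:
        ed = rec["ed50"]
        gi = rec["gi50"]
        lines.append(
            f"  sample={rec['sample_id']} day={rec['day']} readout={rec['readout']}: "
            f"ED50={ed:.3g} nM" + (f", GI50={gi:.3g} nM" if gi is not None else ", GI50 undefined")
            if ed is not None
            else f"  sample={rec['sample_id']} day={rec['day']} readout={rec['readout']}: flat fit"
        )
    ranking_path = Path(config.input_dir) / "ranking.csv"
    if ranking_path.exists():
        ranking = pd.read_csv(ranking_path)
        if len(ranking):
            last_day = ranking["day"].max()
            sub = ranking[ranking["day"] == last_day]
            lines.append(f"sensitivity ranking at day {last_day} (rank 1 = most sensitive):")
            for _, row in sub.iterrows():
                lines.append(
                    f"  {row['readout']}: {row['sample_id']} "
                    f"rank_ed50={row['rank_ed50']} rank_gi50={row['rank_gi50']} "
                    f"rank_max_inhibition={row['rank_max_inhibition']}"
                )
    text = "\n".join(lines)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.txt").write_text(text + "\n")
    return text
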
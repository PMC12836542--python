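"""Per-well imaging readouts over time and replicate summaries.

Seven readouts are computed per well and imaging day from the segmented
objects: total tumouroid-covered area, relative total area (each well
normalised to its own first imaged day — the primary growth readout,
because it cancels well-to-well variation in seeding density and growth
rate), object count, and the per-object means of size (area), equivalent
diameter, perimeter and circularity.  Note the deliberate naming split:
``total_area`` is the whole-well covered area while ``mean_size`` is the
per-object average area — two different quantities that are easy to
conflate.

Technical replicates of a condition are summarised as mean ± SEM per day
and readout, and readout redundancy is assessed with pairwise Pearson
correlations over (well, day) observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segmentation import TumouroidObject

#: Canonical readout names, in reporting order.
READOUTS = [
    "total_area",
    "relative_total_area",
    "count",
    "mean_size",
    "mean_diameter",
    "mean_perimeter",
    "mean_circularity",
]

#: Per-object readouts averaged across objects of a well (undefined at count 0).
MEAN_READOUTS = ["mean_size", "mean_diameter", "mean_perimeter", "mean_circularity"]


@dataclass
class WellTimeSeries:
    """The seven readouts of one well across imaging days.

    ``data`` is indexed by day with one column per readout; per-object
    means are NaN on days with zero objects.  ``anchor_day`` is the first
    imaged day, to which relative_total_area is normalised.
    """

    well_id: str
    sample_id: str
    drug: str
    concentration_nM: float
    replicate: int
    is_vehicle: bool
    data: pd.DataFrame
    anchor_day: int | None = None
    exclusion_reason: str | None = None

    def value(self, readout: str, day: int) -> float:
        return float(self.data.loc[day, readout])


def relative_total_area(total_area: pd.Series) -> pd.Series:
    """Divide a well's total-area series by its first imaged day's value.

    The first day maps to exactly 1.  A zero first-day area makes the
    normalisation impossible and raises; callers flag the well unusable.
    """
    total_area = total_area.sort_index()
    anchor = float(total_area.iloc[0])
    if anchor <= 0:
        raise ValueError("first-day total area is zero; relative normalisation impossible")
    out = total_area / anchor
    out.iloc[0] = 1.0
    return out


def well_readouts(
    objects_by_day: dict[int, list[TumouroidObject]],
    well_id: str = "",
    sample_id: str = "",
    drug: str = "",
    concentration_nM: float = 0.0,
    replicate: int = 1,
    is_vehicle: bool = False,
) -> WellTimeSeries:
    """Aggregate per-object measurements into the seven per-well readouts."""
    days = sorted(objects_by_day)
    if not days:
        raise ValueError("no imaging days supplied")
    rows = []
    for day in days:
        objs = objects_by_day[day]
        areas = np.array([o.area for o in objs])
        row = {
            "total_area": float(areas.sum()) if len(objs) else 0.0,
            "count": len(objs),
            "mean_size": float(areas.mean()) if len(objs) else np.nan,
            "mean_diameter": float(np.mean([o.equivalent_diameter for o in objs])) if objs else np.nan,
            "mean_perimeter": float(np.mean([o.perimeter for o in objs])) if objs else np.nan,
            "mean_circularity": float(np.mean([o.circularity for o in objs])) if objs else np.nan,
        }
        rows.append(row)
    data = pd.DataFrame(rows, index=pd.Index(days, name="day"))
    exclusion = None
    try:
        data["relative_total_area"] = relative_total_area(data["total_area"])
    except ValueError:
        data["relative_total_area"] = np.nan
        exclusion = "zero total area on anchor day"
    data = data[READOUTS]
    return WellTimeSeries(
        well_id=well_id,
        sample_id=sample_id,
        drug=drug,
        concentration_nM=concentration_nM,
        replicate=replicate,
        is_vehicle=is_vehicle,
        data=data,
        anchor_day=days[0],
        exclusion_reason=exclusion,
    )


def replicate_stats(wells: list[WellTimeSeries]) -> pd.DataFrame:
    """Mean, SEM and n per (day, readout) across technical replicate wells.

    SEM is the sample standard deviation (n − 1 denominator) over √n;
    it is undefined (NaN) for a single replicate.  Wells missing a value
    on a given day are dropped per cell, with n adjusted.
    """
    if not wells:
        raise ValueError("need at least one well")
    stacked = pd.concat([w.data.assign(well_id=w.well_id) for w in wells])
    rows = []
    for day, group in stacked.groupby(level="day"):
        for readout in READOUTS:
            vals = group[readout].dropna().to_numpy(dtype=float)
            n = len(vals)
            rows.append(
                {
                    "day": day,
                    "readout": readout,
                    "mean": vals.mean() if n else np.nan,
                    "sem": float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                    "n": n,
                }
            )
    return pd.DataFrame(rows).set_index(["day", "readout"])


def readout_correlations(
    wells: list[WellTimeSeries], readouts: list[str] | None = None
) -> pd.DataFrame:
    """Pearson correlation matrix between readouts over (well, day) rows.

    Count is excluded by default, matching how readout redundancy is
    usually reported for these assays.  Pairwise-complete observations;
    pairs with fewer than 3 observations or zero variance are NaN.
    """
    if readouts is None:
        readouts = [r for r in READOUTS if r != "count"]
    obs = pd.concat([w.data[readouts] for w in wells], ignore_index=True)
    corr = obs.corr(method="pearson", min_periods=3)
    for r in readouts:  # diagonal is 1 by definition where the readout exists
        if obs[r].notna().any():
            corr.loc[r, r] = 1.0
    return corr
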
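"""Density, total-per-retina and percent-change arithmetic.

Plaque counts are sampled over fields of view (by default 8 fields in each
of the central, midperipheral and peripheral regions, 24 per retina),
averaged per retina, normalized to densities (mm^-2) against the
parenchymal area or the vessel surface area, converted to totals per
retina, and compared across age groups as signed percent changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from math import trunc

import numpy as np
import pandas as pd

from .colocalization import ALL_CLASSES, CONNEXINS, PARENCHYMAL, VASCULAR

REGIONS = ("central", "midperipheral", "peripheral")


@dataclass
class SamplingPlan:
    """How fields of view sample each retina and how retinas form groups."""

    regions: tuple[str, ...] = REGIONS
    fields_per_region: int = 8
    retinas_per_group: int = 4
    age_groups: tuple[int, ...] = (3, 9, 22)

    @property
    def fields_per_retina(self) -> int:
        return len(self.regions) * self.fields_per_region

    def field_keys(self) -> list[tuple[str, int]]:
        return [(r, i) for r in self.regions for i in range(self.fields_per_region)]


class MissingFieldsError(ValueError):
    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"missing fields of view: {self.missing}")


def tabulate_plaques(plaques, mode: str = "class") -> pd.DataFrame:
    """Count plaques per (compartment, key) in one field of view.

    ``mode='class'``: each plaque counts toward exactly one of the 15
    combination classes (the taxonomy used for the aging comparison of
    every combination).  ``mode='connexin'``: each plaque counts toward
    every member connexin's single-isoform tally (the per-connexin plaque
    counts).  Both tabulations include zero rows so field averages are
    well defined.
    """
    if mode == "class":
        keys = [c.label for c in ALL_CLASSES]
    elif mode == "connexin":
        keys = list(CONNEXINS)
    else:
        raise ValueError(f"unknown tabulation mode {mode!r}")
    index = pd.MultiIndex.from_product(
        [[PARENCHYMAL, VASCULAR], keys], names=["compartment", "key"])
    counts = pd.Series(0.0, index=index)
    sizes: dict[tuple[str, str], list[int]] = {}
    for p in plaques:
        if p.compartment is None:
            raise ValueError("plaques must have compartments assigned before tabulation")
        targets = [p.members.label] if mode == "class" else list(p.members)
        for key in targets:
            counts[(p.compartment, key)] += 1
            sizes.setdefault((p.compartment, key), []).append(p.voxel_count)
    mean_size = pd.Series(
        {k: float(np.mean(v)) for k, v in sizes.items()}, dtype=float)
    df = counts.rename("count").to_frame()
    df["mean_size_voxels"] = mean_size.reindex(index)
    return df.reset_index()


def aggregate_fields(field_tables: dict, plan: SamplingPlan) -> pd.DataFrame:
    """Per-retina unweighted mean over all fields of view.

    ``field_tables`` maps ``(region, field_index)`` to the field's
    tabulation (output of :func:`tabulate_plaques`).  Counts are averaged
    over all fields (fields without a class contribute zero); plaque sizes
    are averaged over the fields where the class was seen.
    """
    expected = set(plan.field_keys())
    missing = expected - set(field_tables)
    if missing:
        raise MissingFieldsError(missing)
    frames = []
    for key in sorted(expected):
        df = field_tables[key].copy()
        frames.append(df)
    allf = pd.concat(frames)
    grouped = allf.groupby(["compartment", "key"], sort=False)
    out = grouped.agg(count=("count", "mean"),
                      mean_size_voxels=("mean_size_voxels", "mean")).reset_index()
    return out


@dataclass
class RetinaSummary:
    """Per-retina counts, densities, totals and sizes with the areas used."""

    table: pd.DataFrame              # compartment, key, count, density, total, mean_size
    field_parenchymal_area_mm2: float
    field_vessel_area_mm2: float
    retinal_area_mm2: float
    retina_vessel_area_mm2: float


def summarize_retina(per_field_mean: pd.DataFrame,
                     field_parenchymal_area_mm2: float,
                     field_vessel_area_mm2: float,
                     retinal_area_mm2: float,
                     retina_vessel_area_mm2: float) -> RetinaSummary:
    """Convert per-retina mean field counts into densities and totals.

    Parenchymal counts are normalized to the field's parenchymal (xy)
    area; vascular counts to the vessel surface area sampled by the field.
    Densities are scaled to totals with the whole-retina areas, so
    ``total = density x matching area`` exactly.
    """
    df = per_field_mean.copy()
    area = df["compartment"].map({PARENCHYMAL: field_parenchymal_area_mm2,
                                  VASCULAR: field_vessel_area_mm2})
    total_area = df["compartment"].map({PARENCHYMAL: retinal_area_mm2,
                                        VASCULAR: retina_vessel_area_mm2})
    with np.errstate(divide="ignore", invalid="ignore"):
        df["density_per_mm2"] = np.where(area > 0, df["count"] / area, 0.0)
    df["total_per_retina"] = df["density_per_mm2"] * total_area
    return RetinaSummary(df, field_parenchymal_area_mm2, field_vessel_area_mm2,
                         retinal_area_mm2, retina_vessel_area_mm2)


def summarize_group(retinas: list[RetinaSummary]) -> pd.DataFrame:
    """Mean +/- SEM over the retinas of one age group (n = retinas)."""
    frames = [r.table.assign(retina=i) for i, r in enumerate(retinas)]
    allr = pd.concat(frames)
    n = len(retinas)
    g = allr.groupby(["compartment", "key"], sort=False)
    out = g.agg(
        count=("count", "mean"), count_sem=("count", "sem"),
        density_per_mm2=("density_per_mm2", "mean"),
        total_per_retina=("total_per_retina", "mean"),
        total_sem=("total_per_retina", "sem"),
        mean_size_voxels=("mean_size_voxels", "mean"),
    ).reset_index()
    out["n_retinas"] = n
    return out


def density_to_total(density: float, area_mm2: float) -> float:
    """Convert a density (mm^-2) to a total count via the matching area; exact."""
    return density * area_mm2


def vessel_surface_area(tubes=None, mask: np.ndarray | None = None,
                        voxel_size: tuple[float, float, float] | None = None) -> float:
    """Blood-vessel surface area in mm^2.

    From ``tubes`` (objects with ``p0``, ``p1``, ``radius`` in um): the
    analytic lateral area sum(2 pi r L).  From a binary ``mask``: the
    marching-cubes mesh area of the boundary.  Empty geometry gives 0.
    """
    import logging
    if tubes is not None:
        if not tubes:
            logging.getLogger(__name__).warning("empty vessel geometry: surface area 0")
            return 0.0
        total = 0.0
        for t in tubes:
            length = float(np.linalg.norm(np.asarray(t.p1, float) - np.asarray(t.p0, float)))
            total += 2.0 * np.pi * float(t.radius) * length
        return total * 1e-6
    if mask is None:
        raise ValueError("provide tubes or a mask")
    if not mask.any():
        logging.getLogger(__name__).warning("empty vessel mask: surface area 0")
        return 0.0
    from skimage.measure import marching_cubes, mesh_surface_area
    padded = np.pad(mask.astype(np.uint8), 1)
    verts, faces, *_ = marching_cubes(padded, level=0.5, spacing=voxel_size)
    return float(mesh_surface_area(verts, faces)) * 1e-6


@dataclass(frozen=True)
class PercentChange:
    """Signed percent change; the printed form truncates toward zero."""

    raw: float

    @property
    def truncated(self) -> int:
        return trunc(self.raw)

    def __int__(self) -> int:
        return self.truncated


def percent_change(v_start: float, v_end: float) -> PercentChange:
    """Percent change 100 (v_end - v_start) / v_start.

    The integer form truncates toward zero, matching how the aging
    comparison prints its values (e.g. -52.67 -> -52, 422.96 -> 422); the
    untruncated float is always carried alongside.
    """
    if v_start <= 0:
        raise ValueError(f"undefined baseline: v_start must be > 0, got {v_start}")
    return PercentChange(100.0 * (v_end - v_start) / v_start)


def number_times_size(count, mean_size):
    """Plaque number x mean plaque size product index (elementwise)."""
    return np.asarray(count, dtype=float) * np.asarray(mean_size, dtype=float)


def percent_change_table(start_group: pd.DataFrame, end_group: pd.DataFrame,
                         value: str = "total_per_retina") -> pd.DataFrame:
    """Percent change per (compartment, key) between two age-group summaries."""
    merged = start_group.merge(end_group, on=["compartment", "key"],
                               suffixes=("_start", "_end"))
    rows = []
    for _, r in merged.iterrows():
        v0, v1 = r[f"{value}_start"], r[f"{value}_end"]
        if v0 > 0:
            pc = percent_change(v0, v1)
            raw, tr = pc.raw, pc.truncated
        else:
            raw, tr = np.nan, np.nan
        rows.append({"compartment": r["compartment"], "key": r["key"],
                     "start": v0, "end": v1,
                     "percent_change": raw, "percent_change_printed": tr})
    return pd.DataFrame(rows)


def load_reference_totals() -> pd.DataFrame:
    """Published per-retina totals at 3 and 22 months for the 15 classes.

    Transcribed reference values for the aging comparison: total plaques
    per retina per combination class and compartment, with the percent
    change as printed at source.
    """
    with resources.files("cxplaque.data").joinpath("reference_totals.csv").open() as fh:
        return pd.read_csv(fh)
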
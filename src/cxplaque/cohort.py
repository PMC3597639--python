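"""Synthetic aging-cohort experiment.

Builds a multi-retina, multi-age cohort of synthetic fields with a planted
aging effect (by default a 6-fold increase in homomeric Cx30 plaques at 22
months with Cx43 flat), runs the full measurement pipeline on every field
(render -> unmix -> segment -> colocalize -> quantify), and compares
recovered percent changes and ANOVA outcomes with the planted truth.

The cohort is a deliberately scaled-down stand-in for a real study: fields
are 3 x 192 x 192 voxels with 2 fields per retinal region (6 per retina),
4 retinas per age group.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import quantification
from .colocalization import ALL_CLASSES, PARENCHYMAL, VASCULAR
from .pipeline import RunConfig, process_field
from .quantification import SamplingPlan
from .scene import NoiseSpec, PlaqueSpec, SceneConfig, TubeSpec, build_scene, render_lambda_stack
from .spectral import default_reference_spectra
from .stats import anova_bonferroni, GroupComparison

#: Expected plaque counts per field at baseline (3 months), per class label,
#: as (parenchymal, vascular) pairs.  Homomeric classes dominate; mixed
#: classes are rarer, mirroring the relative abundances seen in wholemounts.
BASELINE_CLASS_MEANS = {
    "Cx26": (10.0, 6.0),
    "Cx30": (30.0, 18.0),
    "Cx43": (12.0, 8.0),
    "Cx45": (8.0, 5.0),
    "Cx26/Cx30": (2.0, 1.0),
    "Cx26/Cx43": (2.0, 1.0),
    "Cx26/Cx45": (2.0, 1.0),
    "Cx30/Cx43": (2.0, 1.0),
    "Cx30/Cx45": (2.0, 1.0),
    "Cx43/Cx45": (2.0, 1.0),
    "Cx26/Cx30/Cx43": (1.0, 0.5),
    "Cx26/Cx30/Cx45": (1.0, 0.5),
    "Cx26/Cx43/Cx45": (1.0, 0.5),
    "Cx30/Cx43/Cx45": (1.0, 0.5),
    "Cx26/Cx30/Cx43/Cx45": (0.5, 0.3),
}

#: Planted fold changes at 22 months relative to 3 months (unlisted: 1.0).
DEFAULT_FOLD_CHANGES = {"Cx30": 6.0}


def _cohort_scene_config(seed: int = 0) -> SceneConfig:
    """Scaled-down field geometry shared by every cohort field."""
    class_means = {
        label: {PARENCHYMAL: par, VASCULAR: vasc}
        for label, (par, vasc) in BASELINE_CLASS_MEANS.items()
    }
    return SceneConfig(
        field_shape=(3, 192, 192),
        voxel_size=(8.2, 0.25, 0.25),
        vessels=[TubeSpec((12.3, 4.0, 4.0), (12.3, 44.0, 44.0), 3.0),
                 TubeSpec((12.3, 4.0, 44.0), (12.3, 44.0, 4.0), 3.0)],
        plaques=PlaqueSpec(class_means=class_means,
                           intensity={cx: 80.0 for cx in
                                      ("Cx26", "Cx30", "Cx43", "Cx45")}),
        noise=NoiseSpec(background=2.0, autofluorescence=0.5,
                        poisson_gain=4.0, read_sd=0.5),
        gfap_intensity=60.0,
        vessel_intensity=60.0,
        seed=seed,
    )


def _run_config() -> RunConfig:
    # fixed manual threshold at half the planted plaque intensity; the flat
    # background column absorbs the background/autofluorescence pedestal
    return RunConfig(scene={}, segmentation={"threshold": 40.0},
                     background_column=True)


@dataclass
class CohortSpec:
    """Study conditions of the synthetic cohort."""

    ages: tuple[int, ...] = (3, 22)
    plan: SamplingPlan = field(default_factory=lambda: SamplingPlan(
        fields_per_region=2, retinas_per_group=4, age_groups=(3, 22)))
    fold_changes: dict = field(default_factory=lambda: dict(DEFAULT_FOLD_CHANGES))
    retinal_area_mm2: float = 52.0
    retina_vessel_area_mm2: float = 15.0


@dataclass
class CohortResult:
    group_summaries: dict            # age -> group summary DataFrame (class mode)
    retina_tables: dict              # age -> list of per-retina RetinaSummary
    planted_counts: dict             # age -> DataFrame of planted per-retina mean counts
    measured_change: pd.DataFrame    # percent change, first vs last age
    planted_change: pd.DataFrame
    anova: pd.DataFrame              # per (compartment, class) ANOVA + Bonferroni

    def percent_change_for(self, compartment: str, label: str,
                           table: str = "measured") -> float:
        df = self.measured_change if table == "measured" else self.planted_change
        row = df[(df["compartment"] == compartment) & (df["key"] == label)]
        return float(row["percent_change"].iloc[0])


def _scene_for(spec: CohortSpec, age: int, seed: int) -> SceneConfig:
    cfg = _cohort_scene_config(seed)
    scaled = copy.deepcopy(cfg.plaques.class_means)
    for label, fold in spec.fold_changes.items():
        if age == spec.ages[-1]:
            for comp in scaled[label]:
                scaled[label][comp] *= fold
        elif age not in (spec.ages[0],):
            # intermediate ages stay at baseline
            pass
    cfg.plaques.class_means = scaled
    cfg.seed = seed
    return cfg


def run_cohort(spec: CohortSpec | None = None, seed: int = 0) -> CohortResult:
    """Simulate and measure the whole cohort; compare with planted truth.

    All randomness derives from ``seed``; per-field seeds are spawned
    deterministically, so the same (spec, seed) reproduces the cohort.
    """
    spec = spec or CohortSpec()
    run_cfg = _run_config()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1000]))
    refs = default_reference_spectra(_cohort_scene_config().bin_centers)

    group_summaries, retina_tables, planted_counts = {}, {}, {}
    per_retina_totals: dict[tuple, pd.DataFrame] = {}
    for age in spec.ages:
        retinas = []
        planted_rows = []
        for retina in range(spec.plan.retinas_per_group):
            field_tables = {}
            planted_field_counts = []
            field_par_area = field_vessel_area = None
            for key in spec.plan.field_keys():
                field_seed = int(rng.integers(2 ** 31))
                scene_cfg = _scene_for(spec, age, field_seed)
                truth = build_scene(scene_cfg)
                stack = render_lambda_stack(truth, refs, scene_cfg)
                plaques, *_ = process_field(stack, run_cfg, refs)
                field_tables[key] = quantification.tabulate_plaques(plaques, mode="class")
                counts = truth.class_counts()
                planted_field_counts.append(pd.DataFrame(
                    [{"compartment": comp, "key": cls.label,
                      "count": counts.get((comp, cls.label), 0)}
                     for comp in (PARENCHYMAL, VASCULAR) for cls in ALL_CLASSES]))
                field_par_area = truth.parenchymal_area_mm2
                field_vessel_area = truth.vessel_surface_area_mm2
            per_field = quantification.aggregate_fields(field_tables, spec.plan)
            summary = quantification.summarize_retina(
                per_field, field_par_area, field_vessel_area,
                spec.retinal_area_mm2, spec.retina_vessel_area_mm2)
            retinas.append(summary)
            planted_mean = (pd.concat(planted_field_counts)
                            .groupby(["compartment", "key"], sort=False)["count"]
                            .mean().rename("count").reset_index())
            planted_rows.append(planted_mean.assign(retina=retina))
        group_summaries[age] = quantification.summarize_group(retinas)
        retina_tables[age] = retinas
        planted_counts[age] = pd.concat(planted_rows)
        for i, r in enumerate(retinas):
            per_retina_totals[(age, i)] = r.table

    first, last = spec.ages[0], spec.ages[-1]
    measured_change = quantification.percent_change_table(
        group_summaries[first], group_summaries[last])
    planted_change = _planted_percent_change(planted_counts, first, last)
    anova_table = _anova_table(per_retina_totals, spec)
    return CohortResult(group_summaries, retina_tables, planted_counts,
                        measured_change, planted_change, anova_table)


def _planted_percent_change(planted_counts, first, last) -> pd.DataFrame:
    rows = []
    g0 = planted_counts[first].groupby(["compartment", "key"], sort=False)["count"].mean()
    g1 = planted_counts[last].groupby(["compartment", "key"], sort=False)["count"].mean()
    for key in g0.index:
        v0, v1 = g0[key], g1[key]
        raw = 100.0 * (v1 - v0) / v0 if v0 > 0 else np.nan
        rows.append({"compartment": key[0], "key": key[1],
                     "start": v0, "end": v1, "percent_change": raw,
                     "percent_change_printed": np.trunc(raw) if np.isfinite(raw) else np.nan})
    return pd.DataFrame(rows)


def _anova_table(per_retina_totals, spec: CohortSpec) -> pd.DataFrame:
    rows = []
    combos = per_retina_totals[(spec.ages[0], 0)][["compartment", "key"]]
    for _, (comp, label) in combos.iterrows():
        groups = []
        for age in spec.ages:
            vals = []
            for r in range(spec.plan.retinas_per_group):
                t = per_retina_totals[(age, r)]
                vals.append(float(t[(t["compartment"] == comp) & (t["key"] == label)]
                                  ["total_per_retina"].iloc[0]))
            groups.append(vals)
        try:
            cmp = anova_bonferroni(groups, labels=spec.ages)
            pair = cmp.pair(spec.ages[0], spec.ages[-1])
            rows.append({"compartment": comp, "key": label,
                         "F": cmp.f_statistic, "p": cmp.p_value,
                         "p_adj_first_last": pair.p_adjusted,
                         "significant": pair.significant})
        except ValueError:
            rows.append({"compartment": comp, "key": label,
                         "F": np.nan, "p": np.nan,
                         "p_adj_first_last": np.nan, "significant": False})
    return pd.DataFrame(rows)


def power_simulation(effect: float = 6.0, baseline: float = 1.0,
                     cv: float = 0.25, n_per_group: int = 4,
                     ages: tuple[int, ...] = (3, 9, 22),
                     n_replicates: int = 500, seed: int = 0) -> float:
    """Fraction of replicates with Bonferroni-adjusted first-vs-last p < 0.05.

    Simulates per-retina totals directly: the first and intermediate ages
    at ``baseline``, the last age at ``baseline * effect``, with
    inter-retina coefficient of variation ``cv`` (moderate biological
    noise), then applies the same ANOVA + Bonferroni procedure used on
    measured cohorts.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2000]))
    hits = 0
    means = [baseline] * (len(ages) - 1) + [baseline * effect]
    for _ in range(n_replicates):
        groups = [np.abs(rng.normal(m, cv * m, size=n_per_group)) for m in means]
        cmp: GroupComparison = anova_bonferroni(groups, labels=ages)
        if cmp.pair(ages[0], ages[-1]).p_adjusted < 0.05:
            hits += 1
    return hits / n_replicates
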
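"""End-to-end single-field pipeline: simulate/load -> unmix -> segment ->
classify -> quantify, with full provenance (config + checksummed manifest).

Every stage writes its intermediate to the output directory so stages are
independently inspectable and testable; identical (config, seed) produces
byte-identical artifacts and manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import tifffile
from pydantic import BaseModel, ConfigDict, Field

from . import colocalization, quantification, segmentation, spectral
from .colocalization import CONNEXINS
from .scene import GroundTruth, SceneConfig, build_scene, render_lambda_stack
from .spectral import MARKER_ASSIGNMENT, default_reference_spectra
from .stacks import LambdaStack, read_ome_tiff, write_ome_tiff, write_label_tiff

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


class SegmentationParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    threshold: float | Literal["otsu"] = "otsu"
    min_size: int = 2
    connectivity: Literal[6, 18, 26] = 26


class MergeParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    rule: Literal["voxel_overlap", "centroid_distance"] = "voxel_overlap"
    max_distance_um: float = 1.0


class CompartmentParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    max_distance_um: float = 2.0
    fraction: float = 0.5


class RunConfig(BaseModel):
    """Schema-validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    scene: Optional[dict] = None          # SceneConfig payload: simulate on the fly
    stack_path: Optional[str] = None      # or a pre-acquired/unmixed lambda stack
    spectra_csv: Optional[str] = None     # reference fingerprints; model defaults if None
    channels: tuple[str, ...] = CONNEXINS
    vessel_marker: str = "GS-lectin"
    segmentation: SegmentationParams = Field(default_factory=SegmentationParams)
    merge: MergeParams = Field(default_factory=MergeParams)
    compartment: CompartmentParams = Field(default_factory=CompartmentParams)
    background_column: bool = False
    vessel_min_size: int = 50         # voxels; suppresses speckle in the vessel mask
    retinal_area_mm2: float = 52.0
    retina_vessel_area_mm2: float = 15.0
    output_dir: str = "cxplaque_run"
    seed: int = 0
    log_level: str = "INFO"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _resolve_spectra(config: RunConfig, bin_centers) -> spectral.ReferenceSpectraSet:
    if config.spectra_csv:
        refs = spectral.ReferenceSpectraSet.from_csv(config.spectra_csv)
    else:
        refs = default_reference_spectra(bin_centers)
    return refs


def validate_config(config: RunConfig) -> None:
    """Schema-level checks performed before any computation."""
    if (config.scene is None) == (config.stack_path is None):
        raise ValueError("exactly one of scene / stack_path must be set")
    needed_markers = set(config.channels) | {config.vessel_marker}
    fluor_of = {marker: fluor for fluor, marker in MARKER_ASSIGNMENT.items()}
    unknown = needed_markers - set(fluor_of)
    if unknown:
        raise ValueError(f"no fluorophore assignment for marker(s): {sorted(unknown)}")
    if config.spectra_csv:
        refs = spectral.ReferenceSpectraSet.from_csv(config.spectra_csv)
        missing = {m for m in needed_markers if fluor_of[m] not in refs.fluorophores}
        if missing:
            raise ValueError(f"spectra file lacks fingerprints for channel(s): {sorted(missing)}")


def plaques_to_frame(plaques) -> pd.DataFrame:
    """Plaque table: one-hot connexin columns, class label, compartment, size."""
    rows = []
    for p in plaques:
        c = p.centroid_um
        row = {"id": p.id, "class": p.members.label,
               "compartment": p.compartment,
               "voxel_count": p.voxel_count, "size_um3": p.size_um3,
               "centroid_z_um": c[0], "centroid_y_um": c[1], "centroid_x_um": c[2]}
        for cx in CONNEXINS:
            row[cx] = int(cx in p.members)
        rows.append(row)
    cols = ["id", "class", "compartment", *CONNEXINS,
            "voxel_count", "size_um3", "centroid_z_um", "centroid_y_um", "centroid_x_um"]
    return pd.DataFrame(rows, columns=cols)


def process_field(stack: LambdaStack, config: RunConfig,
                  refs: spectral.ReferenceSpectraSet):
    """Unmix, segment, merge and classify one field in memory.

    Returns ``(plaques, unmixed, channel_objects, vessel_mask)``.
    """
    unmixed = spectral.linear_unmix(stack, refs,
                                    background_column=config.background_column)
    fluor_of = {marker: fluor for fluor, marker in MARKER_ASSIGNMENT.items()}
    channel_objects = {}
    for cx in config.channels:
        channel_objects[cx] = segmentation.segment_channel(
            unmixed.channel(fluor_of[cx]), channel=cx,
            threshold=config.segmentation.threshold,
            min_size=config.segmentation.min_size,
            connectivity=config.segmentation.connectivity,
            voxel_size=stack.voxel_size)
    vessel_map = unmixed.channel(fluor_of[config.vessel_marker])
    vessel_objs = segmentation.segment_channel(
        vessel_map, channel=config.vessel_marker, threshold="otsu",
        min_size=config.vessel_min_size,
        connectivity=config.segmentation.connectivity,
        voxel_size=stack.voxel_size)
    vessel_mask = vessel_objs.label_image() > 0
    plaques = colocalization.merge_channels(
        channel_objects, rule=config.merge.rule,
        max_distance_um=config.merge.max_distance_um)
    colocalization.assign_compartments(
        plaques, vessel_mask, stack.voxel_size,
        max_distance_um=config.compartment.max_distance_um,
        fraction=config.compartment.fraction)
    return plaques, unmixed, channel_objects, vessel_mask


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages, writing artifacts and a checksummed manifest.

    Returns the manifest (artifact name -> sha256).  Any stage failure
    aborts with :class:`PipelineStageError` naming the stage.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def emit(name: str) -> Path:
        p = out / name
        artifacts.append(p)
        return p

    try:
        validate_config(config)
    except Exception as exc:
        raise PipelineStageError("validate", exc) from exc

    cfg_path = emit("config.json")
    # output_dir is implied by the file's own location; omitting it keeps
    # re-runs of one configuration byte-identical wherever they are written
    cfg_path.write_text(json.dumps(config.model_dump(exclude={"output_dir"}),
                                   indent=2, sort_keys=True) + "\n")

    truth: GroundTruth | None = None
    try:
        if config.scene is not None:
            payload = dict(config.scene)
            payload["seed"] = config.seed
            scene_cfg = SceneConfig.from_json(json.dumps(payload))
            scene_cfg.to_json(emit("scene_config.json"))
            truth = build_scene(scene_cfg)
            truth.to_json(emit("ground_truth.json"))
            refs = _resolve_spectra(config, scene_cfg.bin_centers)
            stack = render_lambda_stack(truth, refs, scene_cfg)
            write_ome_tiff(emit("stack.ome.tif"), stack)
        else:
            stack = read_ome_tiff(config.stack_path)
            refs = _resolve_spectra(config, stack.bin_centers)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("simulate/load", exc) from exc

    refs.to_csv(emit("spectra.csv"))

    try:
        plaques, unmixed, channel_objects, vessel_mask = process_field(stack, config, refs)
    except Exception as exc:
        raise PipelineStageError("unmix/segment/classify", exc) from exc

    try:
        ab = np.concatenate([unmixed.abundances,
                             unmixed.residual[..., None]], axis=-1)
        names = list(unmixed.fluorophores) + ["residual"]
        tifffile.imwrite(emit("abundances.ome.tif"),
                         np.moveaxis(ab, -1, 1).astype(np.float32), ome=True,
                         photometric="minisblack",
                         metadata={"axes": "ZCYX", "Channel": {"Name": names},
                                   "UUID": "urn:uuid:00000000-0000-0000-0000-000000000000"},
                         software=None, datetime=False)
        for cx, ch in channel_objects.items():
            ch.to_frame().to_csv(emit(f"objects_{cx}.csv"), index=False)
            write_label_tiff(emit(f"labels_{cx}.ome.tif"), ch.label_image(),
                             stack.voxel_size)
        write_label_tiff(emit("vessel_mask.ome.tif"),
                         vessel_mask.astype(np.int32), stack.voxel_size)
        plaques_to_frame(plaques).to_csv(emit("plaques.csv"), index=False)
    except Exception as exc:
        raise PipelineStageError("export", exc) from exc

    try:
        field_par_area = (stack.field_shape[1] * stack.voxel_size[1]
                          * stack.field_shape[2] * stack.voxel_size[2]) * 1e-6
        if truth is not None:
            field_vessel_area = truth.vessel_surface_area_mm2
        else:
            field_vessel_area = quantification.vessel_surface_area(
                mask=vessel_mask, voxel_size=stack.voxel_size)
        for mode in ("class", "connexin"):
            tab = quantification.tabulate_plaques(plaques, mode=mode)
            summary = quantification.summarize_retina(
                tab, field_par_area, field_vessel_area,
                config.retinal_area_mm2, config.retina_vessel_area_mm2)
            summary.table.to_csv(emit(f"field_summary_{mode}.csv"), index=False)
        if truth is not None:
            planted = pd.DataFrame(
                [{"compartment": comp, "key": label, "count": n}
                 for (comp, label), n in sorted(truth.class_counts().items())])
            planted.to_csv(emit("planted_counts.csv"), index=False)
    except Exception as exc:
        raise PipelineStageError("quantify", exc) from exc

    manifest = {p.name: _sha256(p) for p in sorted(artifacts)}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: %d artifacts in %s", len(manifest), out)
    return manifest
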
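"""Ground-truthed synthetic wholemount fields of view.

Emulates a nerve-fiber-layer field: a vessel (tube) mask, GFAP-positive
stellate astrocytes, and punctate connexin plaques planted with known
combination class, size, intensity and compartment, rendered through
overlapping fluorophore emission spectra into a noisy lambda stack.  The
planted ground truth makes every downstream stage (unmixing, segmentation,
colocalization, quantification, statistics) testable without real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .colocalization import (ALL_CLASSES, CONNEXINS, PARENCHYMAL, VASCULAR,
                             CombinationClass, vessel_distance_map)
from .spectral import (MARKER_ASSIGNMENT, GridMismatchError,
                       ReferenceSpectraSet)
from .stacks import LambdaStack, default_bin_centers


class PlacementError(RuntimeError):
    """The field is too small/crowded to place a requested object."""


@dataclass
class TubeSpec:
    """One straight vessel segment: endpoints and radius in um."""
    p0: tuple[float, float, float]   # (z, y, x) um
    p1: tuple[float, float, float]
    radius: float


@dataclass
class AstrocyteSpec:
    count: int = 6
    soma_radius_um: float = 5.0
    process_count: int = 6
    process_length_um: float = 25.0
    process_radius_um: float = 0.8


@dataclass
class PlaqueSpec:
    """Expected plaque counts per class and compartment, sizes, intensities.

    ``class_means`` maps a class label ("Cx26/Cx30") to per-compartment
    expected counts per field, e.g. ``{"Cx30": {"parenchymal": 30.0,
    "vascular": 15.0}}``.  Sizes are voxel counts drawn from a clipped
    log-normal; intensities are photon-scale arbitrary units per labeled
    connexin.
    """
    class_means: dict = field(default_factory=dict)
    size_log_mean: float = np.log(6.0)
    size_log_sigma: float = 0.6
    min_voxels: int = 2
    max_voxels: int = 30
    intensity: dict = field(default_factory=lambda: {cx: 40.0 for cx in CONNEXINS})

    def mean_for(self, cls: CombinationClass, compartment: str) -> float:
        return float(self.class_means.get(cls.label, {}).get(compartment, 0.0))


@dataclass
class NoiseSpec:
    background: float = 2.0
    autofluorescence: float = 0.5
    poisson_gain: float = 0.0        # photons per intensity unit; 0 disables shot noise
    read_sd: float = 0.0             # additive Gaussian sd; 0 disables

    @property
    def enabled(self) -> bool:
        return self.poisson_gain > 0 or self.read_sd > 0


def _default_vessels() -> list[TubeSpec]:
    # one capillary-calibre vessel crossing the default 128 x 128 um field
    return [TubeSpec((12.3, 10.0, 10.0), (12.3, 118.0, 118.0), 3.0)]


@dataclass
class SceneConfig:
    """Full description of one synthetic field of view."""

    field_shape: tuple[int, int, int] = (3, 512, 512)
    voxel_size: tuple[float, float, float] = (8.2, 0.25, 0.25)
    vessels: list[TubeSpec] = field(default_factory=_default_vessels)
    astrocytes: AstrocyteSpec = field(default_factory=AstrocyteSpec)
    plaques: PlaqueSpec = field(default_factory=PlaqueSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    vascular_distance_um: float = 2.0
    vascular_fraction: float = 0.5
    parenchymal_clearance_um: float = 4.0
    gfap_intensity: float = 30.0
    vessel_intensity: float = 30.0
    n_bins: int = 32
    spectral_range: tuple[float, float] = (411.0, 754.0)
    seed: int = 0
    max_placement_retries: int = 200

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.field_shape):
            raise ValueError("field_shape must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        for t in self.vessels:
            if t.radius <= 0:
                raise ValueError("vessel radius must be positive")
        for label, comp_means in self.plaques.class_means.items():
            CombinationClass.from_label(label)
            if any(m < 0 for m in comp_means.values()):
                raise ValueError(f"negative expected count for {label}")
        if any(i <= self.noise.background for i in self.plaques.intensity.values()):
            raise ValueError("plaque intensities must exceed the background level")

    @property
    def bin_centers(self) -> np.ndarray:
        return default_bin_centers(self.n_bins, self.spectral_range)

    @property
    def field_area_mm2(self) -> float:
        """xy extent of the field, mm^2 (the parenchymal reference area)."""
        _, ny, nx = self.field_shape
        _, vy, vx = self.voxel_size
        return ny * vy * nx * vx * 1e-6

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "SceneConfig":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        payload["vessels"] = [TubeSpec(tuple(t["p0"]), tuple(t["p1"]), t["radius"])
                              for t in payload.get("vessels", [])]
        payload["astrocytes"] = AstrocyteSpec(**payload.get("astrocytes", {}))
        payload["plaques"] = PlaqueSpec(**payload.get("plaques", {}))
        payload["noise"] = NoiseSpec(**payload.get("noise", {}))
        for key in ("field_shape", "voxel_size", "spectral_range"):
            payload[key] = tuple(payload[key])
        return cls(**payload)


@dataclass
class PlantedPlaque:
    id: int
    members: CombinationClass
    voxels: np.ndarray               # (n, 3) int (z, y, x)
    compartment: str
    voxel_size: tuple[float, float, float]

    @property
    def centroid_um(self) -> np.ndarray:
        return (self.voxels.mean(axis=0) + 0.5) * np.asarray(self.voxel_size)


@dataclass
class GroundTruth:
    """Planted objects and masks for one synthetic field."""

    plaques: list[PlantedPlaque]
    vessel_mask: np.ndarray
    astrocyte_mask: np.ndarray
    parenchymal_area_mm2: float
    vessel_surface_area_mm2: float
    field_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]

    def class_counts(self) -> dict[tuple[str, str], int]:
        """Planted plaque count per (compartment, class label)."""
        counts: dict[tuple[str, str], int] = {}
        for p in self.plaques:
            key = (p.compartment, p.members.label)
            counts[key] = counts.get(key, 0) + 1
        return counts

    def to_json(self, path=None) -> str:
        payload = {
            "field_shape": list(self.field_shape),
            "voxel_size": list(self.voxel_size),
            "parenchymal_area_mm2": self.parenchymal_area_mm2,
            "vessel_surface_area_mm2": self.vessel_surface_area_mm2,
            "vessel_mask_rle": _rle_encode(self.vessel_mask),
            "astrocyte_mask_rle": _rle_encode(self.astrocyte_mask),
            "plaques": [{
                "id": p.id, "class": p.members.label, "compartment": p.compartment,
                "voxels": p.voxels.tolist(),
            } for p in self.plaques],
        }
        text = json.dumps(payload, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "GroundTruth":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        shape = tuple(payload["field_shape"])
        voxel_size = tuple(payload["voxel_size"])
        plaques = [PlantedPlaque(
            d["id"], CombinationClass.from_label(d["class"]),
            np.array(d["voxels"], dtype=int).reshape(-1, 3),
            d["compartment"], voxel_size) for d in payload["plaques"]]
        return cls(plaques,
                   _rle_decode(payload["vessel_mask_rle"], shape),
                   _rle_decode(payload["astrocyte_mask_rle"], shape),
                   payload["parenchymal_area_mm2"],
                   payload["vessel_surface_area_mm2"], shape, voxel_size)


def _rle_encode(mask: np.ndarray) -> list[int]:
    """Run lengths of a flattened binary mask, starting with a zero-run."""
    flat = np.asarray(mask, dtype=bool).ravel()
    if flat.size == 0:
        return []
    change = np.flatnonzero(np.diff(flat.astype(np.int8))) + 1
    bounds = np.concatenate([[0], change, [flat.size]])
    runs = np.diff(bounds).tolist()
    if flat[0]:                      # encoded stream must start with a 0-run
        runs = [0] + runs
    return [int(r) for r in runs]


def _rle_decode(runs: list[int], shape: tuple[int, ...]) -> np.ndarray:
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos, val = 0, False
    for r in runs:
        if val:
            flat[pos:pos + r] = True
        pos += r
        val = not val
    return flat.reshape(shape)


def _voxel_centers_um(shape, voxel_size):
    axes = [(np.arange(n) + 0.5) * v for n, v in zip(shape, voxel_size)]
    return np.meshgrid(*axes, indexing="ij")


def _rasterize_tubes(shape, voxel_size, tubes) -> np.ndarray:
    """Binary mask of voxels whose center lies within a tube radius."""
    mask = np.zeros(shape, dtype=bool)
    if not tubes:
        return mask
    zz, yy, xx = _voxel_centers_um(shape, voxel_size)
    pts = np.stack([zz, yy, xx], axis=-1)
    for tube in tubes:
        p0 = np.asarray(tube.p0, dtype=float)
        p1 = np.asarray(tube.p1, dtype=float)
        axis = p1 - p0
        length2 = float(axis @ axis)
        rel = pts - p0
        if length2 == 0:
            dist = np.linalg.norm(rel, axis=-1)
        else:
            t = np.clip((rel @ axis) / length2, 0.0, 1.0)
            dist = np.linalg.norm(rel - t[..., None] * axis, axis=-1)
        mask |= dist <= tube.radius
    return mask


def _astrocyte_mask(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Stellate astrocytes: spherical somata with radiating thin processes."""
    nz, ny, nx = config.field_shape
    vz, vy, vx = config.voxel_size
    spec = config.astrocytes
    tubes = []
    for _ in range(spec.count):
        cz = (nz * vz) / 2.0
        cy = rng.uniform(0, ny * vy)
        cx = rng.uniform(0, nx * vx)
        tubes.append(TubeSpec((cz, cy, cx), (cz, cy, cx), spec.soma_radius_um))
        for _ in range(spec.process_count):
            theta = rng.uniform(0, 2 * np.pi)
            ey = cy + spec.process_length_um * np.sin(theta)
            ex = cx + spec.process_length_um * np.cos(theta)
            tubes.append(TubeSpec((cz, cy, cx), (cz, ey, ex), spec.process_radius_um))
    return _rasterize_tubes(config.field_shape, config.voxel_size, tubes)


def _blob_offsets(n_voxels: int, rng: np.random.Generator) -> np.ndarray:
    """Offsets of an in-plane digital ellipse of exactly ``n_voxels`` voxels.

    Plaques are small irregular puncta spanning one z-slice (axial sampling
    is much coarser than the plaque scale); irregularity comes from a random
    elongation and orientation.
    """
    if n_voxels <= 1:
        return np.zeros((1, 3), dtype=int)
    elong = rng.uniform(1.0, 2.0)
    theta = rng.uniform(0.0, np.pi)
    r = int(np.ceil(np.sqrt(n_voxels * elong / np.pi))) + 2
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    u = np.cos(theta) * dx + np.sin(theta) * dy
    v = -np.sin(theta) * dx + np.cos(theta) * dy
    metric = (u / elong) ** 2 + v ** 2
    flat = np.argsort(metric, axis=None, kind="stable")[:n_voxels]
    offs = np.column_stack([np.zeros(n_voxels, dtype=int),
                            dy.ravel()[flat], dx.ravel()[flat]])
    return offs


def tube_lateral_area_mm2(tubes: list[TubeSpec]) -> float:
    """Analytic lateral surface area of tube segments, sum(2 pi r L), in mm^2."""
    from .quantification import vessel_surface_area
    if not tubes:
        return 0.0
    return vessel_surface_area(tubes=tubes)


def build_scene(config: SceneConfig) -> GroundTruth:
    """Plant vessels, astrocytes and connexin plaques into a field.

    Per-class plaque counts are Poisson with the configured means; vascular
    plaques are placed so the vessel-distance rule labels them vascular,
    parenchymal plaques are placed clear of the vessels.  Plaques are
    pairwise disjoint with at least a one-voxel gap.  Identical
    (config, seed) yields identical ground truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    vessel_mask = _rasterize_tubes(config.field_shape, config.voxel_size, config.vessels)
    astro_mask = _astrocyte_mask(config, rng)
    dist = vessel_distance_map(vessel_mask, config.voxel_size)

    vasc_cand = np.argwhere(dist <= config.vascular_distance_um)
    par_cand = np.argwhere(dist > config.parenchymal_clearance_um)
    occupancy = np.zeros(config.field_shape, dtype=bool)
    shape = np.asarray(config.field_shape)

    plaques: list[PlantedPlaque] = []
    pid = 0
    for cls in ALL_CLASSES:
        for compartment in (PARENCHYMAL, VASCULAR):
            mean = config.plaques.mean_for(cls, compartment)
            n = int(rng.poisson(mean)) if mean > 0 else 0
            candidates = vasc_cand if compartment == VASCULAR else par_cand
            for _ in range(n):
                if len(candidates) == 0:
                    raise PlacementError(
                        f"no candidate sites for {compartment} plaques "
                        f"(class {cls.label}); field or vessel geometry too small")
                size = int(np.clip(
                    np.round(rng.lognormal(config.plaques.size_log_mean,
                                           config.plaques.size_log_sigma)),
                    config.plaques.min_voxels, config.plaques.max_voxels))
                placed = False
                for _attempt in range(config.max_placement_retries):
                    center = candidates[rng.integers(len(candidates))]
                    voxels = center + _blob_offsets(size, rng)
                    if (voxels < 0).any() or (voxels >= shape).any():
                        continue
                    idx = tuple(voxels.T)
                    if occupancy[idx].any():
                        continue
                    near = float(np.mean(dist[idx] <= config.vascular_distance_um))
                    label = VASCULAR if near >= config.vascular_fraction else PARENCHYMAL
                    if label != compartment:
                        continue
                    pid += 1
                    plaques.append(PlantedPlaque(pid, cls, voxels, compartment,
                                                 config.voxel_size))
                    # reserve the plaque plus a one-voxel halo so planted
                    # plaques can never touch (keeps segmentation separable)
                    lo = np.maximum(voxels.min(axis=0) - 1, 0)
                    hi = np.minimum(voxels.max(axis=0) + 2, shape)
                    sub = occupancy[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
                    local = voxels - lo
                    halo = np.zeros_like(sub)
                    for dz in (-1, 0, 1):
                        for dyy in (-1, 0, 1):
                            for dxx in (-1, 0, 1):
                                pts = local + (dz, dyy, dxx)
                                ok = ((pts >= 0) & (pts < sub.shape)).all(axis=1)
                                halo[tuple(pts[ok].T)] = True
                    sub |= halo
                    placed = True
                    break
                if not placed:
                    raise PlacementError(
                        f"failed to place a {compartment} {cls.label} plaque of "
                        f"{size} voxels after {config.max_placement_retries} retries")

    return GroundTruth(plaques, vessel_mask, astro_mask,
                       config.field_area_mm2,
                       tube_lateral_area_mm2(config.vessels),
                       config.field_shape, config.voxel_size)


def _fluorophore_for_marker() -> dict[str, str]:
    return {marker: fluor for fluor, marker in MARKER_ASSIGNMENT.items()}


def planted_abundances(truth: GroundTruth, config: SceneConfig,
                       fluorophores: tuple[str, ...]) -> np.ndarray:
    """Noise-free per-fluorophore abundance maps implied by the ground truth."""
    k_index = {f: i for i, f in enumerate(fluorophores)}
    fluor_of = _fluorophore_for_marker()
    abund = np.zeros((*truth.field_shape, len(fluorophores)))
    for p in truth.plaques:
        idx = tuple(p.voxels.T)
        for cx in p.members:
            fluor = fluor_of[cx]
            if fluor not in k_index:
                raise KeyError(f"spectra set lacks {fluor} (marker {cx})")
            abund[idx + (k_index[fluor],)] += config.plaques.intensity[cx]
    if config.gfap_intensity and "Cy5" in k_index:
        abund[..., k_index["Cy5"]] += config.gfap_intensity * truth.astrocyte_mask
    if config.vessel_intensity and "AMCA" in k_index:
        abund[..., k_index["AMCA"]] += config.vessel_intensity * truth.vessel_mask
    return abund


def render_lambda_stack(truth: GroundTruth, spectra: ReferenceSpectraSet,
                        config: SceneConfig) -> LambdaStack:
    """Render ground truth through the emission fingerprints into a lambda stack.

    Per voxel the expected signal is ``background + autofluorescence +
    sum_k abundance_k * spectrum_k`` (background and autofluorescence are
    spectrally flat).  Shot noise (Poisson) then read noise (Gaussian) are
    applied if configured; with all noise off the stack is the exact
    linear mixture.
    """
    expected_centers = config.bin_centers
    if spectra.bin_centers.size != expected_centers.size or \
            not np.allclose(spectra.bin_centers, expected_centers):
        raise GridMismatchError("reference spectra bin grid does not match the scene config")
    abund = planted_abundances(truth, config, spectra.fluorophores)
    expected = (config.noise.background + config.noise.autofluorescence
                + abund @ spectra.matrix)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    data = expected
    if config.noise.poisson_gain > 0:
        g = config.noise.poisson_gain
        data = rng.poisson(data * g).astype(float) / g
    if config.noise.read_sd > 0:
        data = data + rng.normal(0.0, config.noise.read_sd, size=data.shape)
    return LambdaStack(np.clip(data, 0.0, None), spectra.bin_centers, config.voxel_size)
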
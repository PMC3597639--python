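"""3D object segmentation of connexin abundance maps.

Each unmixed connexin channel is thresholded and its supra-threshold
voxels are grouped into connected components; components smaller than a
minimum voxel count are discarded.  Objects are measured in voxels, um^3
and 2D projected pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

#: scipy connectivity rank per neighbor count in 3D
_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class SegmentedObject:
    id: int
    voxels: np.ndarray               # (n, 3) int (z, y, x)
    voxel_size: tuple[float, float, float]
    mean_intensity: float

    @property
    def voxel_count(self) -> int:
        return len(self.voxels)

    @property
    def size_um3(self) -> float:
        return self.voxel_count * float(np.prod(self.voxel_size))

    @property
    def pixel_footprint(self) -> int:
        """Area of the z-projection, in pixels."""
        return len(np.unique(self.voxels[:, 1:], axis=0))

    @property
    def centroid_um(self) -> np.ndarray:
        return (self.voxels.mean(axis=0) + 0.5) * np.asarray(self.voxel_size)


@dataclass
class ChannelObjects:
    """All segmented objects of one connexin channel."""

    channel: str
    objects: list[SegmentedObject]
    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    threshold: float
    min_size: int
    connectivity: int = 26

    def __len__(self) -> int:
        return len(self.objects)

    def label_image(self) -> np.ndarray:
        lab = np.zeros(self.shape, dtype=np.int32)
        for obj in self.objects:
            lab[tuple(obj.voxels.T)] = obj.id
        return lab

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "channel": self.channel, "id": o.id,
            "voxel_count": o.voxel_count, "size_um3": o.size_um3,
            "pixel_footprint": o.pixel_footprint,
            "centroid_z_um": o.centroid_um[0],
            "centroid_y_um": o.centroid_um[1],
            "centroid_x_um": o.centroid_um[2],
            "mean_intensity": o.mean_intensity,
        } for o in self.objects]
        return pd.DataFrame(rows, columns=[
            "channel", "id", "voxel_count", "size_um3", "pixel_footprint",
            "centroid_z_um", "centroid_y_um", "centroid_x_um", "mean_intensity"])


def segment_channel(abundance_map: np.ndarray, channel: str = "",
                    threshold: float | str = "otsu", min_size: int = 2,
                    connectivity: int = 26,
                    voxel_size: tuple[float, float, float] = (8.2, 0.25, 0.25),
                    ) -> ChannelObjects:
    """Threshold a 3D abundance map and extract connected objects.

    Foreground is ``{v : I(v) >= threshold}``; components are found under
    the requested 3D connectivity (6, 18 or 26 neighbors) and components
    with fewer than ``min_size`` voxels are discarded.  Object ids are
    assigned in order of each object's lexicographically smallest voxel,
    so segmentation of the same map is fully deterministic.
    """
    arr = np.asarray(abundance_map, dtype=float)
    if arr.ndim != 3:
        raise ValueError(f"abundance map must be 3D; got {arr.ndim}D")
    if not np.isfinite(arr).all():
        raise ValueError("abundance map contains non-finite values")
    if np.any(arr < 0):
        raise ValueError("abundance map must be nonnegative")
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of 6, 18, 26; got {connectivity}")
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold mode {threshold!r}")
        thr = float(threshold_otsu(arr)) if arr.max() > arr.min() else np.inf
    else:
        thr = float(threshold)
        if thr < 0:
            raise ValueError("threshold must be nonnegative")

    mask = arr >= thr
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n = ndimage.label(mask, structure=structure)
    objects = []
    if n:
        slices = ndimage.find_objects(labels)
        anchored = []
        for lab in range(1, n + 1):
            sl = slices[lab - 1]
            voxels = np.argwhere(labels[sl] == lab) + [s.start for s in sl]
            if len(voxels) < min_size:
                continue
            anchored.append((tuple(voxels[0]), voxels))
        anchored.sort(key=lambda t: t[0])
        for oid, (_, voxels) in enumerate(anchored, start=1):
            objects.append(SegmentedObject(
                oid, voxels, tuple(voxel_size),
                float(arr[tuple(voxels.T)].mean())))
    return ChannelObjects(channel, objects, arr.shape, tuple(voxel_size),
                          thr, min_size, connectivity)


def measure_objects(channel_objects: ChannelObjects) -> pd.DataFrame:
    """Per-object measurement table (voxels, um^3, 2D pixel projection)."""
    return channel_objects.to_frame()
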
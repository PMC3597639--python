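"""Spectral image stacks.

A lambda stack is a 4D spectral image: one intensity image per emission
wavelength band, acquired so that overlapping fluorophores can later be
separated by linear unmixing.  The canonical acquisition here is 32 bands
spanning 411-754 nm, stored as ``(z, y, x, band)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

#: Spectral range of the default acquisition, nm.
DEFAULT_RANGE_NM = (411.0, 754.0)

#: Fixed OME UUID so repeated writes of identical data are byte-identical.
_STATIC_UUID = "urn:uuid:00000000-0000-0000-0000-000000000000"
#: Number of spectral bins in the default acquisition.
DEFAULT_N_BINS = 32


def default_bin_centers(n_bins: int = DEFAULT_N_BINS,
                        spectral_range: tuple[float, float] = DEFAULT_RANGE_NM) -> np.ndarray:
    """Evenly spaced bin centers whose outer edges sit on the stated range.

    The nominal 10 nm bandwidth over 411-754 nm does not divide evenly into
    32 bins; the stated endpoints are honoured and the actual bin width is
    (754-411)/32 ~= 10.72 nm.
    """
    lo, hi = spectral_range
    width = (hi - lo) / n_bins
    return lo + width * (np.arange(n_bins) + 0.5)


@dataclass
class LambdaStack:
    """4D spectral image ``(z, y, x, band)`` with voxel geometry.

    Parameters
    ----------
    data : ndarray
        Nonnegative intensities, shape ``(z, y, x, n_bins)``.
    bin_centers : ndarray
        Strictly increasing band-center wavelengths in nm.
    voxel_size : tuple of float
        Voxel edge lengths in um, ``(z, y, x)`` order.
    """

    data: np.ndarray
    bin_centers: np.ndarray = field(default_factory=default_bin_centers)
    voxel_size: tuple[float, float, float] = (8.2, 0.25, 0.25)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.bin_centers = np.asarray(self.bin_centers, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"lambda stack must be 4D (z, y, x, band); got shape {self.data.shape}")
        if self.data.shape[-1] != self.bin_centers.size:
            raise ValueError(
                f"{self.data.shape[-1]} spectral planes but {self.bin_centers.size} bin centers")
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bin centers must be strictly increasing")
        if np.any(self.data < 0):
            raise ValueError("lambda stack intensities must be nonnegative")

    @property
    def n_bins(self) -> int:
        return self.data.shape[-1]

    @property
    def field_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


def write_ome_tiff(path, stack: LambdaStack) -> None:
    """Write a lambda stack as OME-TIFF, bands as channels (ZCYX).

    Channel names record the bin center wavelength so the grid can be
    recovered on read.  The write is reproducible: no datetime or other
    run-varying tags are emitted.
    """
    zcyx = np.ascontiguousarray(np.moveaxis(stack.data, -1, 1)).astype(np.float32)
    names = [f"{c:.4f}nm" for c in stack.bin_centers]
    zs, ys, xs = stack.voxel_size
    tifffile.imwrite(
        path,
        zcyx,
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "ZCYX",
            "UUID": _STATIC_UUID,
            "Channel": {"Name": names},
            "PhysicalSizeZ": zs, "PhysicalSizeZUnit": "µm",
            "PhysicalSizeY": ys, "PhysicalSizeYUnit": "µm",
            "PhysicalSizeX": xs, "PhysicalSizeXUnit": "µm",
        },
        software=None,
        datetime=False,
    )


def read_ome_tiff(path) -> LambdaStack:
    """Read a lambda stack written by :func:`write_ome_tiff`."""
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        meta = tf.ome_metadata
    # normalize axis order to ZCYX
    order = [axes.index(a) for a in "ZCYX"]
    data = np.transpose(data, order)
    import xml.etree.ElementTree as ET

    root = ET.fromstring(meta)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    px = root.find(".//ome:Pixels", ns)
    names = [ch.get("Name") for ch in px.findall("ome:Channel", ns)]
    centers = np.array([float(n.replace("nm", "")) for n in names])
    voxel = (float(px.get("PhysicalSizeZ", 1.0)),
             float(px.get("PhysicalSizeY", 1.0)),
             float(px.get("PhysicalSizeX", 1.0)))
    return LambdaStack(np.moveaxis(data, 1, -1), centers, voxel)


def write_label_tiff(path, labels: np.ndarray, voxel_size=(8.2, 0.25, 0.25)) -> None:
    """Write a 3D integer label image as OME-TIFF (reproducibly)."""
    tifffile.imwrite(
        path,
        labels.astype(np.int32),
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "ZYX",
            "UUID": _STATIC_UUID,
            "PhysicalSizeZ": voxel_size[0],
            "PhysicalSizeY": voxel_size[1],
            "PhysicalSizeX": voxel_size[2],
        },
        software=None,
        datetime=False,
    )
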
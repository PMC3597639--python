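"""Object-based colocalization: merge per-channel objects into plaques.

A gap-junction plaque may contain one, two, three or all four connexin
isoforms (Cx26, Cx30, Cx43, Cx45).  Per-channel segmented objects are
merged into plaques by spatial coincidence, each plaque is assigned the
combination class given by the union of its member channels (15 nonempty
subsets of the four isoforms), and each plaque is assigned to the
parenchymal or vascular compartment by proximity to the vessel mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

CONNEXINS = ("Cx26", "Cx30", "Cx43", "Cx45")

PARENCHYMAL = "parenchymal"
VASCULAR = "vascular"


@dataclass(frozen=True)
class CombinationClass:
    """A nonempty subset of the four astrocyte connexin isoforms.

    Singletons correspond to homomeric/homotypic plaques; larger subsets
    record co-occurrence only — whether a mixed plaque reflects heteromeric
    hemichannels or heterotypic channels is not inferable from
    colocalization and is not attempted.
    """

    members: tuple[str, ...]

    def __init__(self, members) -> None:
        mem = tuple(sorted(set(members), key=CONNEXINS.index))
        if not mem:
            raise ValueError("combination class must be a nonempty connexin subset")
        unknown = set(mem) - set(CONNEXINS)
        if unknown:
            raise ValueError(f"unknown connexin(s): {sorted(unknown)}")
        object.__setattr__(self, "members", mem)

    @property
    def label(self) -> str:
        return "/".join(self.members)

    @property
    def order(self) -> int:
        return len(self.members)

    @classmethod
    def from_label(cls, label: str) -> "CombinationClass":
        return cls(label.split("/"))

    def __contains__(self, connexin: str) -> bool:
        return connexin in self.members

    def __iter__(self):
        return iter(self.members)


#: All 15 possible classes: 4 singletons, 6 pairs, 4 triples, 1 quadruple.
ALL_CLASSES: tuple[CombinationClass, ...] = tuple(
    CombinationClass(c)
    for k in range(1, 5)
    for c in combinations(CONNEXINS, k)
)


@dataclass
class Plaque:
    """One merged gap-junction plaque."""

    id: int
    members: CombinationClass
    voxels: np.ndarray               # (n, 3) int voxel indices (z, y, x)
    voxel_size: tuple[float, float, float]
    compartment: str | None = None

    @property
    def voxel_count(self) -> int:
        return len(self.voxels)

    @property
    def size_um3(self) -> float:
        return self.voxel_count * float(np.prod(self.voxel_size))

    @property
    def centroid_um(self) -> np.ndarray:
        return (self.voxels.mean(axis=0) + 0.5) * np.asarray(self.voxel_size)


class GeometryMismatchError(ValueError):
    """Per-channel object sets do not share voxel geometry."""


def _overlap_edges(channel_objects: dict) -> list[tuple[tuple, tuple]]:
    """Edges between per-channel objects sharing >= 1 voxel, via label images."""
    names = list(channel_objects)
    shape = channel_objects[names[0]].shape
    labels = {}
    for name in names:
        lab = np.zeros(shape, dtype=np.int32)
        for obj in channel_objects[name].objects:
            lab[tuple(obj.voxels.T)] = obj.id
        labels[name] = lab
    edges = []
    for a, b in combinations(names, 2):
        la, lb = labels[a], labels[b]
        both = (la > 0) & (lb > 0)
        if not both.any():
            continue
        pairs = np.unique(np.stack([la[both], lb[both]], axis=1), axis=0)
        edges.extend([((a, int(i)), (b, int(j))) for i, j in pairs])
    return edges


def _centroid_edges(channel_objects: dict, max_distance_um: float) -> list:
    voxel_size = None
    cents, keys = [], []
    for name, ch in channel_objects.items():
        voxel_size = ch.voxel_size
        for obj in ch.objects:
            keys.append((name, obj.id))
            cents.append(obj.centroid_um)
    edges = []
    if not cents:
        return edges
    cents = np.asarray(cents)
    for i in range(len(keys)):
        d = np.linalg.norm(cents[i + 1:] - cents[i], axis=1)
        for off in np.where(d <= max_distance_um)[0]:
            j = i + 1 + off
            if keys[i][0] != keys[j][0]:
                edges.append((keys[i], keys[j]))
    return edges


def merge_channels(channel_objects: dict, rule: str = "voxel_overlap",
                   max_distance_um: float = 1.0) -> list[Plaque]:
    """Merge per-channel objects into plaques.

    Builds a graph whose nodes are the per-channel objects; edges join
    objects that satisfy the merge rule (``voxel_overlap``: share at least
    one voxel; ``centroid_distance``: centroids within ``max_distance_um``).
    Each connected component becomes one plaque whose combination class is
    the union of its member channels.  Every per-channel object belongs to
    exactly one plaque.
    """
    names = list(channel_objects)
    shapes = {channel_objects[n].shape for n in names}
    sizes = {channel_objects[n].voxel_size for n in names}
    if len(shapes) > 1 or len(sizes) > 1:
        raise GeometryMismatchError(f"channels disagree on geometry: {shapes}, {sizes}")
    voxel_size = channel_objects[names[0]].voxel_size

    graph = nx.Graph()
    for name in names:
        for obj in channel_objects[name].objects:
            graph.add_node((name, obj.id))
    if rule == "voxel_overlap":
        graph.add_edges_from(_overlap_edges(channel_objects))
    elif rule == "centroid_distance":
        graph.add_edges_from(_centroid_edges(channel_objects, max_distance_um))
    else:
        raise ValueError(f"unknown merge rule: {rule!r}")

    by_key = {(name, obj.id): obj
              for name in names for obj in channel_objects[name].objects}
    # order plaques by the lexicographically smallest voxel of the component
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)),
        key=lambda comp: min(min(map(tuple, by_key[k].voxels)) for k in comp),
    )
    plaques = []
    for pid, comp in enumerate(components, start=1):
        voxels = np.unique(np.concatenate([by_key[k].voxels for k in comp]), axis=0)
        members = CombinationClass([k[0] for k in comp])
        plaques.append(Plaque(pid, members, voxels, voxel_size))
    return plaques


def vessel_distance_map(vessel_mask: np.ndarray,
                        voxel_size: tuple[float, float, float]) -> np.ndarray:
    """Euclidean distance (um) of every voxel to the nearest vessel voxel."""
    if not vessel_mask.any():
        return np.full(vessel_mask.shape, np.inf)
    return ndimage.distance_transform_edt(~vessel_mask, sampling=voxel_size)


def assign_compartment(plaque: Plaque, vessel_mask: np.ndarray,
                       voxel_size: tuple[float, float, float] | None = None,
                       max_distance_um: float = 2.0, fraction: float = 0.5,
                       distance_map: np.ndarray | None = None) -> str:
    """Assign a plaque to the vascular or parenchymal compartment.

    Vascular iff at least ``fraction`` of the plaque's voxels lie within
    ``max_distance_um`` of the vessel mask; otherwise parenchymal.  An
    empty vessel mask makes every plaque parenchymal (logged).
    """
    if distance_map is None:
        if vessel_mask is None or not vessel_mask.any():
            logger.warning("empty vessel mask: all plaques assigned parenchymal")
            return PARENCHYMAL
        distance_map = vessel_distance_map(vessel_mask, voxel_size)
    d = distance_map[tuple(plaque.voxels.T)]
    near = float(np.mean(d <= max_distance_um))
    return VASCULAR if near >= fraction else PARENCHYMAL


def assign_compartments(plaques: list[Plaque], vessel_mask: np.ndarray,
                        voxel_size: tuple[float, float, float],
                        max_distance_um: float = 2.0,
                        fraction: float = 0.5) -> list[Plaque]:
    """Assign compartments to all plaques, sharing one distance transform."""
    if vessel_mask is None or not vessel_mask.any():
        logger.warning("empty vessel mask: all plaques assigned parenchymal")
        for p in plaques:
            p.compartment = PARENCHYMAL
        return plaques
    dmap = vessel_distance_map(vessel_mask, voxel_size)
    for p in plaques:
        p.compartment = assign_compartment(p, vessel_mask, voxel_size,
                                           max_distance_um, fraction, distance_map=dmap)
    return plaques
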
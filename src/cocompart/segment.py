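"""3D object segmentation and surface meshing.

Puncta channels are thresholded (Otsu within the cell mask by default),
connected components are labelled in 3D, and the nucleus / cell-membrane
masks are turned into closed triangle meshes that later serve as distance
references for the per-object feature model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import marching_cubes

from .preprocess import VoxelStack

log = logging.getLogger(__name__)

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class LabelVolume:
    """Integer label grid: 0 = background, k in 1..n_objects = object id."""

    labels: np.ndarray
    n_objects: int
    channel: str = ""
    connectivity: int = 26

    def object_mask(self, object_id: int) -> np.ndarray:
        if not 1 <= object_id <= self.n_objects:
            raise ValueError(f"object id {object_id} outside 1..{self.n_objects}")
        return self.labels == object_id


@dataclass
class SurfaceMesh:
    """Closed triangle mesh in physical (nm) coordinates.

    ``role`` is "nucleus" or "membrane"; ``volume_nm3`` is the enclosed
    volume from the signed tetrahedron sum.
    """

    vertices: np.ndarray
    faces: np.ndarray
    role: str
    volume_nm3: float

    @property
    def equivalent_radius_nm(self) -> float:
        """Radius of the sphere with the same enclosed volume."""
        return float((3.0 * self.volume_nm3 / (4.0 * np.pi)) ** (1.0 / 3.0))

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @property
    def is_watertight(self) -> bool:
        return bool(self.as_trimesh().is_watertight)


def threshold_channel(
    stack: VoxelStack,
    method: str = "otsu",
    value: float | None = None,
    within_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Binarize a channel; returns the boolean foreground volume.

    method "otsu" computes Otsu's threshold over the voxels inside
    ``within_mask`` (whole grid if None); "fixed" uses ``value`` directly;
    "quantile" thresholds at the ``value`` quantile of the (masked)
    intensities. Voxels outside ``within_mask`` are always background.
    """
    data = stack.data
    if within_mask is not None:
        within_mask = np.asarray(within_mask, dtype=bool)
        if within_mask.shape != data.shape:
            raise ValueError("within_mask shape must match stack shape")
        sample = data[within_mask]
    else:
        sample = data.ravel()
    if sample.size == 0:
        raise ValueError("no voxels to threshold (empty mask)")
    if method == "otsu":
        if np.ptp(sample) == 0:
            raise ValueError(
                "all intensities equal: Otsu threshold undefined, use method='fixed'"
            )
        t = float(threshold_otsu(sample))
    elif method == "fixed":
        if value is None:
            raise ValueError("method 'fixed' requires a threshold value")
        t = float(value)
    elif method == "quantile":
        if value is None or not 0 <= value <= 1:
            raise ValueError("method 'quantile' requires a value in [0, 1]")
        t = float(np.quantile(sample, value))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    log.info("threshold_channel(%s): method=%s t=%.4g", stack.channel, method, t)
    mask = data > t
    if within_mask is not None:
        mask &= within_mask
    return mask


def label_objects(
    mask: np.ndarray,
    connectivity: int = 26,
    min_voxels: int = 5,
    channel: str = "",
) -> LabelVolume:
    """Label 3D connected components, dropping components below ``min_voxels``.

    Labels are relabelled contiguously 1..K in scan order, so identical
    input always yields identical labelling.
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}")
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    raw, n_raw = ndimage.label(mask, structure=structure)
    if n_raw == 0:
        return LabelVolume(raw, 0, channel=channel, connectivity=connectivity)
    counts = np.bincount(raw.ravel(), minlength=n_raw + 1)
    keep = np.flatnonzero(counts[1:] >= min_voxels) + 1
    removed = n_raw - keep.size
    if removed:
        log.info("label_objects(%s): removed %d components < %d voxels",
                 channel, removed, min_voxels)
    remap = np.zeros(n_raw + 1, dtype=raw.dtype)
    remap[keep] = np.arange(1, keep.size + 1)
    return LabelVolume(remap[raw], int(keep.size), channel=channel,
                       connectivity=connectivity)


def mesh_from_mask(
    mask: np.ndarray,
    voxel_size_nm: tuple[float, float, float],
    role: str = "membrane",
) -> SurfaceMesh:
    """Closed surface mesh of a binary mask at the 0.5 iso-level.

    The mask is padded by one voxel so the marching-cubes surface closes even
    when the foreground touches the grid border. Vertices are in physical nm,
    consistent with the convention that voxel (i,j,k) is centred at
    ((i+0.5) dz, (j+0.5) dy, (k+0.5) dx).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot mesh an empty mask")
    padded = np.pad(mask, 1).astype(float)
    spacing = tuple(float(v) for v in voxel_size_nm)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=spacing)
    # marching_cubes puts voxel index i at coordinate i*spacing; shift for the
    # one-voxel pad and the half-voxel centre offset.
    verts = verts + (np.array(spacing) * 0.5 - np.array(spacing))
    tm = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    volume = float(abs(tm.volume))
    if volume <= 0:
        raise ValueError("mesh has non-positive enclosed volume")
    return SurfaceMesh(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces),
                       role=role, volume_nm3=volume)


def watershed_split(
    mask: np.ndarray,
    voxel_size_nm: tuple[float, float, float],
    min_seed_distance_nm: float = 200.0,
) -> np.ndarray:
    """Optional marker-based watershed split of merged puncta.

    Seeds are local maxima of the anisotropy-aware Euclidean distance
    transform separated by at least ``min_seed_distance_nm``. Returns a
    relabelled mask suitable for :func:`label_objects` input (boolean
    regions separated by zero-width watershed lines are preserved as-is).
    """
    from skimage.feature import peak_local_max
    from skimage.segmentation import watershed

    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask, dtype=np.int32)
    dist = ndimage.distance_transform_edt(mask, sampling=voxel_size_nm)
    min_dist_vox = max(1, int(round(min_seed_distance_nm / min(voxel_size_nm))))
    peaks = peak_local_max(dist, min_distance=min_dist_vox, labels=mask,
                           exclude_border=False)
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, p in enumerate(peaks, start=1):
        markers[tuple(p)] = i
    if markers.max() == 0:
        lab, _ = ndimage.label(mask)
        return lab
    return watershed(-dist, markers, mask=mask)
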
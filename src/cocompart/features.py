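"""Per-object feature model: co-compartmentalization, shape, and distances.

Each segmented 3D object is described by 16 attributes plus its molecule
class and treatment label (an 18-dimensional feature space):

====  =======================  =============================================
attr  column                   meaning
====  =======================  =============================================
1     pct_voxels_coloc         % of the object's voxels inside any
                               partner-channel object
2     n_coloc_objects          number of distinct partner objects overlapped
3     volume_nm3               object volume (voxel count x voxel volume)
4     mean_intensity           mean channel intensity over member voxels
5     intensity_sum            integrated channel intensity
6     elongation               major/minor ellipsoid-equivalent axis ratio
7     minor_axis_nm            minor axis length (4 sqrt(eigenvalue))
8     major_axis_nm            major axis length
9-11  angle_major_{x,y,z}_deg  angle of the major axis to x, y, z in [0,90]
12-14 angle_minor_{x,y,z}_deg  angle of the minor axis to x, y, z in [0,90]
15    dist_nucleus_norm        centroid distance to the nuclear surface,
                               normalized by the cell equivalent radius
16    dist_cell_norm           centroid distance to the cell surface,
                               normalized the same way
====  =======================  =============================================

Distances are normalized by the radius of the sphere with the cell mesh's
enclosed volume, making them dimensionless and cell-size invariant.
Degenerate shape attributes (objects with fewer than 4 voxels or a singular
covariance) are reported as NaN sentinels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import VoxelStack
from .segment import LabelVolume, SurfaceMesh

log = logging.getLogger(__name__)

ATTRIBUTE_COLUMNS = (
    "pct_voxels_coloc",
    "n_coloc_objects",
    "volume_nm3",
    "mean_intensity",
    "intensity_sum",
    "elongation",
    "minor_axis_nm",
    "major_axis_nm",
    "angle_major_x_deg",
    "angle_major_y_deg",
    "angle_major_z_deg",
    "angle_minor_x_deg",
    "angle_minor_y_deg",
    "angle_minor_z_deg",
    "dist_nucleus_norm",
    "dist_cell_norm",
)
#: full column order of the exported table: class + treatment + 16 attributes
TABLE_COLUMNS = ("cls", "treatment") + ATTRIBUTE_COLUMNS


def voxel_overlap(
    obj_mask: np.ndarray, partner: LabelVolume
) -> tuple[float, int, list[int]]:
    """Object-level co-localization against a partner label volume.

    Returns (percentage of the object's voxels lying inside any partner
    object, number of distinct partner objects touched, their label ids).
    """
    obj_mask = np.asarray(obj_mask, dtype=bool)
    if obj_mask.shape != partner.labels.shape:
        raise ValueError("object mask and partner volume shapes differ")
    n_vox = int(obj_mask.sum())
    if n_vox == 0:
        raise ValueError("empty object has no defined overlap")
    touched = partner.labels[obj_mask]
    pct = 100.0 * float(np.count_nonzero(touched)) / n_vox
    ids = sorted(int(v) for v in np.unique(touched) if v > 0)
    return pct, len(ids), ids


def principal_axes(
    obj_mask: np.ndarray, voxel_size_nm: tuple[float, float, float]
) -> dict[str, float]:
    """Ellipsoid-equivalent axes of an object from its voxel covariance.

    Eigendecomposition of the covariance of member-voxel physical
    coordinates; axis length = 4 sqrt(eigenvalue) (the diameter of the
    ellipsoid with matching second moments). Angles between each axis and
    the Cartesian x/y/z directions are folded into [0, 90] degrees since
    axes are directionless. Degenerate objects yield NaN for every shape
    attribute, with a logged warning.
    """
    keys = ("major_axis_nm", "minor_axis_nm", "elongation",
            "angle_major_x_deg", "angle_major_y_deg", "angle_major_z_deg",
            "angle_minor_x_deg", "angle_minor_y_deg", "angle_minor_z_deg")
    idx = np.argwhere(np.asarray(obj_mask, dtype=bool))
    if idx.shape[0] < 4:
        log.warning("principal_axes: %d voxels < 4, axes undefined", idx.shape[0])
        return {k: float("nan") for k in keys}
    # physical coordinates in (z,y,x) order
    pts = (idx + 0.5) * np.asarray(voxel_size_nm)
    cov = np.cov(pts, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[0] <= 1e-12 * max(evals[-1], 1.0):
        log.warning("principal_axes: singular covariance, axes undefined")
        return {k: float("nan") for k in keys}
    minor_v, major_v = evecs[:, 0], evecs[:, 2]
    minor_len, major_len = 4.0 * np.sqrt(evals[0]), 4.0 * np.sqrt(evals[2])

    def angles(v):
        # v is (z,y,x); report angles to x, y, z
        ax = {"x": v[2], "y": v[1], "z": v[0]}
        return {
            k: float(np.degrees(np.arccos(np.clip(abs(c), 0.0, 1.0))))
            for k, c in ax.items()
        }

    amaj, amin = angles(major_v), angles(minor_v)
    return {
        "major_axis_nm": float(major_len),
        "minor_axis_nm": float(minor_len),
        "elongation": float(major_len / minor_len),
        "angle_major_x_deg": amaj["x"],
        "angle_major_y_deg": amaj["y"],
        "angle_major_z_deg": amaj["z"],
        "angle_minor_x_deg": amin["x"],
        "angle_minor_y_deg": amin["y"],
        "angle_minor_z_deg": amin["z"],
    }


def point_triangle_distances(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Unsigned distances from each point to each triangle (vectorized).

    ``points`` is (n,3), ``tri`` is (m,3,3). Returns an (n,m) matrix using
    the standard parametric region decomposition of the point-triangle
    problem, evaluated in closed form with clamped barycentric coordinates.
    """
    points = np.asarray(points, dtype=float)
    tri = np.asarray(tri, dtype=float)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac = b - a, c - a
    d00 = np.einsum("ij,ij->i", ab, ab)
    d01 = np.einsum("ij,ij->i", ab, ac)
    d11 = np.einsum("ij,ij->i", ac, ac)
    denom = d00 * d11 - d01 * d01
    denom = np.where(denom <= 0, 1.0, denom)  # degenerate triangles -> edges

    ap = points[:, None, :] - a[None, :, :]  # (n,m,3)
    d20 = np.einsum("nmj,mj->nm", ap, ab)
    d21 = np.einsum("nmj,mj->nm", ap, ac)
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    # clamp into the triangle: project out-of-range barycentrics onto edges
    v_cl = np.clip(v, 0.0, 1.0)
    w_cl = np.clip(w, 0.0, 1.0)
    inside = (v >= 0) & (w >= 0) & (v + w <= 1)

    def seg_param(p_minus_s, d_vec):
        dd = np.einsum("ij,ij->i", d_vec, d_vec)
        dd = np.where(dd <= 0, 1.0, dd)
        return np.clip(np.einsum("nmj,mj->nm", p_minus_s, d_vec) / dd, 0.0, 1.0)

    # candidate closest points: interior projection and the three edges
    t_ab = seg_param(ap, ab)
    t_ac = seg_param(ap, ac)
    bc = c - b
    bp = points[:, None, :] - b[None, :, :]
    t_bc = seg_param(bp, bc)

    cand_in = a[None] + v_cl[..., None] * ab[None] + w_cl[..., None] * ac[None]
    cand_ab = a[None] + t_ab[..., None] * ab[None]
    cand_ac = a[None] + t_ac[..., None] * ac[None]
    cand_bc = b[None] + t_bc[..., None] * bc[None]

    d_in = np.linalg.norm(points[:, None] - cand_in, axis=-1)
    d_in = np.where(inside, d_in, np.inf)
    d_ab = np.linalg.norm(points[:, None] - cand_ab, axis=-1)
    d_ac = np.linalg.norm(points[:, None] - cand_ac, axis=-1)
    d_bc = np.linalg.norm(points[:, None] - cand_bc, axis=-1)
    return np.minimum.reduce([d_in, d_ab, d_ac, d_bc])


def point_mesh_distance(points: np.ndarray, mesh: SurfaceMesh,
                        chunk: int = 4096) -> np.ndarray:
    """Minimum unsigned distance from each point to the mesh surface."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = mesh.vertices[mesh.faces]
    out = np.empty(points.shape[0])
    for start in range(0, tri.shape[0], chunk):
        block = point_triangle_distances(points, tri[start:start + chunk])
        block_min = block.min(axis=1)
        out = block_min if start == 0 else np.minimum(out, block_min)
    return out


def surface_distance(
    point_nm: np.ndarray, mesh: SurfaceMesh, normalizer: SurfaceMesh
) -> float:
    """Normalized unsigned distance from a point to a surface mesh.

    The raw point-to-mesh distance is divided by the *normalizer*'s
    equivalent radius (the radius of the sphere with the cell mesh's
    enclosed volume), yielding a dimensionless, cell-size invariant value.
    """
    for m, what in ((mesh, "target"), (normalizer, "normalizer")):
        if not m.is_watertight:
            raise ValueError(f"{what} mesh ({m.role}) is not watertight")
    d = float(point_mesh_distance(np.asarray(point_nm, dtype=float)[None, :], mesh)[0])
    return d / normalizer.equivalent_radius_nm


def average_object_distance(
    centroids_nm: np.ndarray, normalizer: SurfaceMesh | None = None
) -> float:
    """Mean over objects of the mean centroid distance to all other objects.

    The per-condition spread statistic for one molecule class: for each
    object, average its centroid-to-centroid distance to every other
    same-class object, then average over objects. Returns nm, or a value
    normalized by the cell equivalent radius when ``normalizer`` is given.
    NaN sentinel for fewer than 2 objects.
    """
    pts = np.atleast_2d(np.asarray(centroids_nm, dtype=float))
    n = pts.shape[0]
    if n < 2:
        log.warning("average_object_distance: need >=2 objects, got %d", n)
        return float("nan")
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    per_obj = dist.sum(axis=1) / (n - 1)
    out = float(per_obj.mean())
    if normalizer is not None:
        out /= normalizer.equivalent_radius_nm
    return out


@dataclass
class FeatureTable:
    """Long-format object feature table plus provenance.

    ``table`` is indexed by object id ("<class>-<label>") with columns in
    :data:`TABLE_COLUMNS` order: cls, treatment, then the 16 attributes.
    """

    table: pd.DataFrame
    pairing: dict[str, str]
    scene_id: str = ""

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="object_id")


def compute_feature_table(
    label_volumes: dict[str, LabelVolume],
    stacks: dict[str, VoxelStack],
    nucleus_mesh: SurfaceMesh,
    cell_mesh: SurfaceMesh,
    pairing: dict[str, str],
    treatment: str = "n.t.",
    scene_id: str = "",
) -> FeatureTable:
    """One row per segmented object: 16 attributes + class + treatment.

    ``pairing`` maps each puncta class to the single partner class used for
    the co-localization attributes (e.g. NALP3 -> LC3). Intensities are read
    from the supplied (registered, by default non-deconvolved) stacks. Row
    order is deterministic: class in ``label_volumes`` order, then label id.
    """
    for cls, partner in pairing.items():
        if cls not in label_volumes:
            raise ValueError(f"pairing references unknown class {cls!r}")
        if partner not in label_volumes:
            raise ValueError(f"pairing partner {partner!r} has no label volume")
    for m, what in ((nucleus_mesh, "nucleus"), (cell_mesh, "cell")):
        if m is None:
            raise ValueError(f"missing {what} mesh")
    r_eq = cell_mesh.equivalent_radius_nm

    rows, index, centroids = [], [], []
    for cls, lv in label_volumes.items():
        if cls not in pairing:
            continue
        partner = label_volumes[pairing[cls]]
        stack = stacks[cls]
        vsz = np.asarray(stack.voxel_size_nm, dtype=float)
        voxel_volume = float(np.prod(vsz))
        objects = ndimage.find_objects(lv.labels)
        for k in range(1, lv.n_objects + 1):
            sl = objects[k - 1]
            local = lv.labels[sl] == k
            full = np.zeros(lv.labels.shape, dtype=bool)
            full[sl] = local
            pct, n_co, _ = voxel_overlap(full, partner)
            vox_idx = np.argwhere(full)
            centroid = ((vox_idx + 0.5) * vsz).mean(axis=0)
            centroids.append(centroid)
            intens = stack.data[full]
            shape_attrs = principal_axes(full, stack.voxel_size_nm)
            rows.append({
                "cls": cls,
                "treatment": treatment,
                "pct_voxels_coloc": pct,
                "n_coloc_objects": n_co,
                "volume_nm3": float(vox_idx.shape[0]) * voxel_volume,
                "mean_intensity": float(intens.mean()),
                "intensity_sum": float(intens.sum()),
                **shape_attrs,
            })
            index.append(f"{cls}-{k:04d}")
    # distances queried in one batch per mesh: much cheaper than per object
    if centroids:
        pts = np.asarray(centroids)
        d_nuc = point_mesh_distance(pts, nucleus_mesh) / r_eq
        d_cell = point_mesh_distance(pts, cell_mesh) / r_eq
    else:
        d_nuc = d_cell = np.empty(0)
    for row, dn, dc in zip(rows, d_nuc, d_cell):
        row["dist_nucleus_norm"] = float(dn)
        row["dist_cell_norm"] = float(dc)
    table = pd.DataFrame(rows, index=pd.Index(index, name="object_id"),
                         columns=list(TABLE_COLUMNS))
    return FeatureTable(table=table, pairing=dict(pairing), scene_id=scene_id)
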
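"""Ground-truthed synthetic 3D confocal scenes.

A scene is a single cell: an ellipsoidal cell membrane containing an
ellipsoidal nucleus, with spherical fluorescent puncta of one or more marker
classes scattered in the cytoplasm. Three treatment-sensitive dials control
the spatial statistics the downstream analysis must recover:

* ``aggregation`` — fraction of a class's puncta drawn around a few shared
  cluster sites instead of uniformly (micro-clustering / aggregate growth);
* ``perinuclear_bias`` — fraction placed in a thin shell around the nucleus
  (relocation toward the nucleus);
* ``coloc`` — per class-pair fraction f_ab of class-a puncta placed
  overlapping a class-b punctum (co-compartmentalization).

Channels are rendered as the sum of rasterized puncta convolved with a
Gaussian PSF, plus background, Poisson shot noise and Gaussian read noise.
The returned ground truth (punctum table + cell/nucleus masks) is exact and
unblurred, so every measured statistic has an oracle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import PsfModel, VoxelStack, make_gaussian_psf, psf_convolve

DEFAULT_VOXEL_SIZE_NM = (140.0, 40.0, 40.0)  # (z, y, x)


class GeometryError(ValueError):
    """Scene geometry is inconsistent (e.g. nucleus not inside the cell)."""


class CapacityError(RuntimeError):
    """Requested puncta cannot be placed inside the cell without overlap."""


@dataclass(frozen=True)
class PunctaClassConfig:
    """Punctum population of one marker class.

    Radii and intensities are drawn from truncated normals; radius in nm,
    intensity in photon counts integrated over the punctum.
    """

    name: str
    n: int = 10
    radius_mean_nm: float = 250.0
    radius_sd_nm: float = 40.0
    radius_min_nm: float = 100.0
    intensity_mean: float = 30000.0
    intensity_sd: float = 4000.0


@dataclass(frozen=True)
class PsfParams:
    """Optical parameters of the rendering / deconvolution PSF."""

    na: float = 1.4
    wavelength_nm: float = 520.0
    refractive_index: float = 1.515


@dataclass(frozen=True)
class SceneConfig:
    shape: tuple[int, int, int] = (32, 128, 128)
    voxel_size_nm: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_NM
    cell_axes_nm: tuple[float, float, float] = (1700.0, 2400.0, 2400.0)
    nucleus_axes_nm: tuple[float, float, float] = (900.0, 1100.0, 1100.0)
    classes: tuple[PunctaClassConfig, ...] = (
        PunctaClassConfig("NALP3"),
        PunctaClassConfig("LC3"),
    )
    aggregation: float = 0.0
    n_aggregation_sites: int = 3
    aggregation_sigma_nm: float = 450.0
    perinuclear_bias: float = 0.0
    perinuclear_shell_nm: float = 250.0
    #: extra centre separation (nm) beyond touching spheres for puncta that
    #: are not deliberately co-localized, so diffraction blur cannot fuse
    #: neighbouring puncta into one segmented object
    min_separation_extra_nm: float = 500.0
    coloc: tuple[tuple[tuple[str, str], float], ...] = ()
    psf: PsfParams | None = PsfParams()
    background: float = 20.0
    poisson_noise: bool = True
    gaussian_noise_sd: float = 2.0
    treatment: str = "n.t."
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 8 for s in self.shape):
            raise GeometryError(f"grid too small: {self.shape}")
        if any(v <= 0 for v in self.voxel_size_nm):
            raise GeometryError("voxel sizes must be > 0")
        if not all(n < c for n, c in zip(self.nucleus_axes_nm, self.cell_axes_nm)):
            raise GeometryError("nucleus ellipsoid must lie strictly inside the cell")
        extent = [s * v for s, v in zip(self.shape, self.voxel_size_nm)]
        if not all(2 * c < e for c, e in zip(self.cell_axes_nm, extent)):
            raise GeometryError("cell ellipsoid does not fit inside the grid")
        for cls in self.classes:
            if cls.n < 0:
                raise ValueError(f"class {cls.name}: punctum count must be >= 0")
        for (a, b), f in self.coloc:
            if not 0 <= f <= 1:
                raise ValueError(f"coloc fraction for ({a},{b}) must be in [0,1], got {f}")
            names = {c.name for c in self.classes}
            if a not in names or b not in names:
                raise ValueError(f"coloc pair ({a},{b}) references unknown class")
        if not 0 <= self.perinuclear_bias <= 1:
            raise ValueError("perinuclear_bias must be in [0,1]")
        if not 0 <= self.aggregation <= 1:
            raise ValueError("aggregation must be in [0,1]")

    def coloc_fraction(self, a: str, b: str) -> float:
        for (pa, pb), f in self.coloc:
            if (pa, pb) == (a, b):
                return f
        return 0.0


@dataclass
class GroundTruth:
    """Exact per-punctum records plus the cell and nucleus masks.

    ``puncta`` columns: punctum_id, cls, z_nm, y_nm, x_nm, radius_nm,
    intensity, partner_id ("" when not co-localized). Partner links are
    symmetric.
    """

    puncta: pd.DataFrame
    cell_mask: np.ndarray
    nucleus_mask: np.ndarray
    config: SceneConfig


def voxel_centers_nm(shape, voxel_size_nm):
    """Physical coordinates of voxel centres along each axis."""
    return [
        (np.arange(n, dtype=float) + 0.5) * d
        for n, d in zip(shape, voxel_size_nm)
    ]


def _ellipsoid_mask(shape, voxel_size_nm, center_nm, axes_nm):
    z, y, x = voxel_centers_nm(shape, voxel_size_nm)
    zz = ((z - center_nm[0]) / axes_nm[0]) ** 2
    yy = ((y - center_nm[1]) / axes_nm[1]) ** 2
    xx = ((x - center_nm[2]) / axes_nm[2]) ** 2
    return (zz[:, None, None] + yy[None, :, None] + xx[None, None, :]) <= 1.0


def rasterize_sphere(shape, voxel_size_nm, center_nm, radius_nm):
    """Boolean mask of voxels whose centres lie within the sphere.

    Returns (slices, local_mask); the mask can be empty for sub-voxel radii.
    """
    lo, hi = [], []
    for ax in range(3):
        d = voxel_size_nm[ax]
        lo.append(max(0, int(np.floor((center_nm[ax] - radius_nm) / d - 0.5))))
        hi.append(min(shape[ax], int(np.ceil((center_nm[ax] + radius_nm) / d + 0.5))))
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    coords = [
        (np.arange(l, h, dtype=float) + 0.5) * voxel_size_nm[ax] - center_nm[ax]
        for ax, (l, h) in enumerate(zip(lo, hi))
    ]
    if any(c.size == 0 for c in coords):
        return sl, np.zeros([max(0, h - l) for l, h in zip(lo, hi)], dtype=bool)
    r2 = (coords[0][:, None, None] ** 2 + coords[1][None, :, None] ** 2
          + coords[2][None, None, :] ** 2)
    return sl, r2 <= radius_nm**2


def _ellipsoid_value(p, center, axes):
    return sum(((p[i] - center[i]) / axes[i]) ** 2 for i in range(3))


def _sample_direction(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def generate_scene(config: SceneConfig) -> tuple[dict[str, VoxelStack], GroundTruth]:
    """Render one scene and return (channels, ground truth).

    Channel order is fixed: one channel per puncta class in config order,
    then "nucleus" and "cellmask". Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    shape, vsz = config.shape, config.voxel_size_nm
    center = tuple(0.5 * s * d for s, d in zip(shape, vsz))
    cell_mask = _ellipsoid_mask(shape, vsz, center, config.cell_axes_nm)
    nucleus_mask = _ellipsoid_mask(shape, vsz, center, config.nucleus_axes_nm)

    cell_volume = 4.0 / 3.0 * np.pi * float(np.prod(config.cell_axes_nm))
    total_punctum_volume = sum(
        cls.n * 4.0 / 3.0 * np.pi * cls.radius_mean_nm**3 for cls in config.classes
    )
    if total_punctum_volume > 0.25 * cell_volume:
        raise CapacityError(
            f"requested puncta volume ({total_punctum_volume:.3g} nm^3) exceeds 25% "
            f"of the cell volume ({cell_volume:.3g} nm^3)"
        )

    def inside_cytoplasm(p, margin):
        # sphere of radius `margin` fully inside the cell, centre outside nucleus
        shrunk = tuple(max(a - margin, 1.0) for a in config.cell_axes_nm)
        if _ellipsoid_value(p, center, shrunk) > 1.0:
            return False
        return _ellipsoid_value(p, center, config.nucleus_axes_nm) > 1.0

    def sample_uniform(margin):
        lo = np.array(center) - np.array(config.cell_axes_nm)
        hi = np.array(center) + np.array(config.cell_axes_nm)
        for _ in range(10_000):
            p = rng.uniform(lo, hi)
            if inside_cytoplasm(p, margin):
                return p
        raise CapacityError("could not sample a cytoplasmic point")

    def sample_perinuclear(margin):
        # a point on the nucleus surface pushed radially outward so the
        # punctum sits within a thin shell hugging the nucleus
        axes = np.array(config.nucleus_axes_nm)
        for _ in range(10_000):
            u = _sample_direction(rng)
            surf = np.array(center) + u / np.sqrt(np.sum((u / axes) ** 2))
            t = rng.uniform(0.0, config.perinuclear_shell_nm)
            p = surf + u * (margin + t)
            if inside_cytoplasm(p, margin):
                return p
        raise CapacityError("could not sample a perinuclear point")

    # each class clusters around its own sites (aggregates are class-specific)
    sites_by_class = {
        cls.name: [sample_uniform(0.0) for _ in range(config.n_aggregation_sites)]
        for cls in config.classes
    }

    def sample_clustered(margin, cls_name):
        sites = sites_by_class[cls_name]
        for _ in range(10_000):
            site = sites[rng.integers(len(sites))]
            p = site + rng.normal(scale=config.aggregation_sigma_nm, size=3)
            if inside_cytoplasm(p, margin):
                return p
        raise CapacityError("could not sample a clustered point")

    # --- placement -------------------------------------------------------
    placed: list[dict] = []  # records across all classes

    def separated(p, r, cls_name, records, same_class_extra=None):
        # same-channel puncta keep the extra margin so diffraction blur
        # cannot fuse them; cross-channel puncta only need to not touch
        # (different channels never merge, but accidental overlap would
        # corrupt the co-localization ground truth)
        if same_class_extra is None:
            same_class_extra = config.min_separation_extra_nm
        for rec in records:
            extra = same_class_extra if rec["cls"] == cls_name else 20.0
            if np.linalg.norm(p - rec["pos"]) < r + rec["radius_nm"] + extra:
                return False
        return True

    for cls in config.classes:
        n_peri = _round_half_up(config.perinuclear_bias * cls.n)
        n_agg = _round_half_up(config.aggregation * (cls.n - n_peri))
        modes = ["perinuclear"] * n_peri + ["clustered"] * n_agg
        modes += ["uniform"] * (cls.n - len(modes))
        for i, mode in enumerate(modes):
            r = float(np.clip(rng.normal(cls.radius_mean_nm, cls.radius_sd_nm),
                              cls.radius_min_nm, None))
            intensity = float(max(rng.normal(cls.intensity_mean, cls.intensity_sd),
                                  0.1 * cls.intensity_mean))
            for attempt in range(5000):
                if mode == "perinuclear":
                    p = sample_perinuclear(r)
                elif mode == "clustered":
                    p = sample_clustered(r, cls.name)
                else:
                    p = sample_uniform(r)
                if separated(p, r, cls.name, placed):
                    break
            else:
                raise CapacityError(
                    f"could not place punctum {i} of class {cls.name} "
                    f"after 5000 attempts"
                )
            placed.append({
                "punctum_id": f"{cls.name}-{i:03d}",
                "cls": cls.name,
                "pos": p,
                "radius_nm": r,
                "intensity": intensity,
                "partner_id": "",
                "mode": mode,
            })

    by_class: dict[str, list[dict]] = {}
    for rec in placed:
        by_class.setdefault(rec["cls"], []).append(rec)

    # --- co-localization: reposition a fraction of class-a puncta onto b --
    for (a, b), f in config.coloc:
        recs_a, recs_b = by_class.get(a, []), by_class.get(b, [])
        k = _round_half_up(f * len(recs_a))
        free_a = [ra for ra in recs_a if ra["partner_id"] == ""]
        free_b = [rb for rb in recs_b if rb["partner_id"] == ""]
        if k > len(free_a) or k > len(free_b):
            raise CapacityError(
                f"coloc pair ({a},{b}): need {k} free puncta on both sides, "
                f"have {len(free_a)} / {len(free_b)}"
            )
        chosen_a = list(rng.choice(len(free_a), size=k, replace=False))
        chosen_b = list(rng.choice(len(free_b), size=k, replace=False))
        for ia, ib in zip(chosen_a, chosen_b):
            ra, rb = free_a[ia], free_b[ib]
            others = [rec for rec in placed if rec is not ra and rec is not rb]
            for attempt in range(2000):
                off = _sample_direction(rng) * rng.uniform(0.0, ra["radius_nm"])
                p = rb["pos"] + off
                if not inside_cytoplasm(p, 0.0):
                    continue
                # a punctum parked on its partner cannot always honour the
                # full same-class margin; a reduced margin keeps merges rare,
                # and in very crowded scenes the margin is waived entirely
                # rather than failing the scene
                sce = min(150.0, config.min_separation_extra_nm)
                if attempt >= 1000:
                    sce = 0.0
                if not separated(p, ra["radius_nm"], ra["cls"], others,
                                 same_class_extra=sce):
                    continue
                # require a genuine voxel-level overlap with the partner
                sl, m = rasterize_sphere(shape, vsz, p, ra["radius_nm"])
                slb, mb = rasterize_sphere(shape, vsz, rb["pos"], rb["radius_nm"])
                full_a = np.zeros(shape, dtype=bool)
                full_a[sl] = m
                full_b = np.zeros(shape, dtype=bool)
                full_b[slb] = mb
                if (full_a & full_b).any():
                    break
            else:
                raise CapacityError(f"could not co-localize {ra['punctum_id']}")
            ra["pos"] = p
            ra["partner_id"] = rb["punctum_id"]
            rb["partner_id"] = ra["punctum_id"]

    # --- rendering -------------------------------------------------------
    psf_model: PsfModel | None = None
    if config.psf is not None:
        psf_model = make_gaussian_psf(
            config.psf.na, config.psf.wavelength_nm,
            config.psf.refractive_index, vsz,
        )

    channels: dict[str, VoxelStack] = {}
    for cls in config.classes:
        field_arr = np.zeros(shape)
        for rec in by_class.get(cls.name, []):
            sl, m = rasterize_sphere(shape, vsz, rec["pos"], rec["radius_nm"])
            if m.any():
                field_arr[sl][m] += rec["intensity"] / m.sum()
            else:  # punctum smaller than a voxel: deposit in the nearest voxel
                idx = tuple(
                    int(np.clip(rec["pos"][ax] / vsz[ax] - 0.5, 0, shape[ax] - 1))
                    for ax in range(3)
                )
                field_arr[idx] += rec["intensity"]
        if psf_model is not None:
            field_arr = psf_convolve(field_arr, psf_model)
        field_arr = field_arr + config.background
        if config.poisson_noise:
            field_arr = rng.poisson(np.maximum(field_arr, 0.0)).astype(float)
        if config.gaussian_noise_sd > 0:
            field_arr = field_arr + rng.normal(0.0, config.gaussian_noise_sd,
                                               size=shape)
        channels[cls.name] = VoxelStack(np.maximum(field_arr, 0.0), vsz,
                                        channel=cls.name)

    # nucleus and cell-mask channels emulate traced binary masks: crisp,
    # noise-free, scaled to a nominal intensity
    channels["nucleus"] = VoxelStack(nucleus_mask.astype(float) * 1000.0, vsz,
                                     channel="nucleus")
    channels["cellmask"] = VoxelStack(cell_mask.astype(float) * 1000.0, vsz,
                                      channel="cellmask")

    puncta = pd.DataFrame(
        [
            {
                "punctum_id": rec["punctum_id"],
                "cls": rec["cls"],
                "z_nm": rec["pos"][0],
                "y_nm": rec["pos"][1],
                "x_nm": rec["pos"][2],
                "radius_nm": rec["radius_nm"],
                "intensity": rec["intensity"],
                "partner_id": rec["partner_id"],
            }
            for rec in placed
        ],
        columns=["punctum_id", "cls", "z_nm", "y_nm", "x_nm", "radius_nm",
                 "intensity", "partner_id"],
    )
    gt = GroundTruth(puncta=puncta, cell_mask=cell_mask,
                     nucleus_mask=nucleus_mask, config=config)
    return channels, gt


def render_treatment_panel(
    base: SceneConfig,
    effects: dict[str, dict] | None = None,
) -> list[tuple[str, dict[str, VoxelStack], GroundTruth]]:
    """One scene per treatment, applying per-treatment config overrides.

    ``effects`` maps treatment label -> {SceneConfig field: value}. An empty
    or None map yields the single base scene under its own treatment label.
    Seeds are offset deterministically per treatment so scenes differ.
    """
    if not effects:
        effects = {base.treatment: {}}
    valid = {f.name for f in dataclasses.fields(SceneConfig)}
    panel = []
    for i, (treatment, overrides) in enumerate(effects.items()):
        unknown = set(overrides) - valid
        if unknown:
            raise KeyError(f"unknown SceneConfig override keys: {sorted(unknown)}")
        cfg = replace(base, treatment=treatment, seed=base.seed + i, **overrides)
        channels, gt = generate_scene(cfg)
        panel.append((treatment, channels, gt))
    return panel


def nucleus_distances_nm(gt: GroundTruth, cls: str | None = None) -> np.ndarray:
    """Ground-truth punctum centroid distances to the nucleus *surface*.

    Distance is along the ray from the shared cell/nucleus centre, which is
    exact for the scene's concentric-ellipsoid geometry. Used by recovery
    tests as an oracle independent of any mesh.
    """
    cfg = gt.config
    center = np.array([0.5 * s * d for s, d in zip(cfg.shape, cfg.voxel_size_nm)])
    df = gt.puncta if cls is None else gt.puncta[gt.puncta["cls"] == cls]
    pts = df[["z_nm", "y_nm", "x_nm"]].to_numpy() - center
    # scale factor t where the ray crosses the nucleus ellipsoid
    denom = np.sqrt(np.sum((pts / np.array(cfg.nucleus_axes_nm)) ** 2, axis=1))
    denom = np.where(denom == 0, np.inf, denom)
    surface_pts = pts / denom[:, None]
    return np.linalg.norm(pts - surface_pts, axis=1)
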
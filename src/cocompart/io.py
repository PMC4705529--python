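"""File I/O: OME-TIFF scene round trips, ground-truth sidecars, provenance.

One scene is stored as a single multi-channel OME-TIFF (axes CZYX) with the
physical voxel size in the OME metadata and the channel order fixed and
recorded: the puncta classes in configuration order, then "nucleus", then
"cellmask". Ground truth travels as a CSV (punctum table) plus a JSON
sidecar (scene configuration and masks summary).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .preprocess import VoxelStack
from .scene import GroundTruth, SceneConfig


def write_scene_tiff(path, channels: dict[str, VoxelStack]) -> None:
    """Write channels to one OME-TIFF with voxel size metadata (nm -> um)."""
    path = Path(path)
    names = list(channels)
    first = channels[names[0]]
    dz, dy, dx = first.voxel_size_nm
    data = np.stack([channels[n].data for n in names]).astype(np.float32)
    tifffile.imwrite(
        path,
        data,
        metadata={
            "axes": "CZYX",
            "Channel": {"Name": names},
            "PhysicalSizeX": dx / 1000.0,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": dy / 1000.0,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": dz / 1000.0,
            "PhysicalSizeZUnit": "µm",
        },
        ome=True,
    )


def read_stack(
    path,
    expected_channels: list[str] | None = None,
    voxel_size_nm: tuple[float, float, float] | None = None,
) -> dict[str, VoxelStack]:
    """Read a multi-channel OME-TIFF back into named VoxelStacks.

    Voxel size is taken from the OME metadata; ``voxel_size_nm`` is the
    config fallback when the file carries none. Raises when the channel
    count does not match ``expected_channels``.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        ome = tf.ome_metadata
    if data.ndim == 3:
        data = data[None]
    names, meta_vsz = _parse_ome(ome)
    if meta_vsz is not None:
        vsz = meta_vsz
    elif voxel_size_nm is not None:
        vsz = tuple(float(v) for v in voxel_size_nm)
    else:
        raise ValueError(
            f"{path}: no voxel size in metadata and no config fallback given"
        )
    if not names or len(names) != data.shape[0]:
        names = [f"channel_{i}" for i in range(data.shape[0])]
    if expected_channels is not None:
        if len(expected_channels) != data.shape[0]:
            raise ValueError(
                f"{path}: {data.shape[0]} channels in file, expected "
                f"{len(expected_channels)}: {expected_channels}"
            )
        names = list(expected_channels)
    return {
        n: VoxelStack(data[i].astype(float), vsz, channel=n)
        for i, n in enumerate(names)
    }


def _parse_ome(ome_xml: str | None):
    if not ome_xml:
        return [], None
    import xml.etree.ElementTree as ET

    root = ET.fromstring(ome_xml)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    names, vsz = [], None
    for px in root.iter(f"{{{ns['ome']}}}Pixels"):
        for ch in px.iter(f"{{{ns['ome']}}}Channel"):
            names.append(ch.get("Name") or ch.get("ID", ""))
        sx, sy, sz = (px.get(k) for k in
                      ("PhysicalSizeX", "PhysicalSizeY", "PhysicalSizeZ"))
        if sx and sy and sz:
            # OME stores um; stacks use nm
            vsz = (float(sz) * 1000.0, float(sy) * 1000.0, float(sx) * 1000.0)
        break
    return names, vsz


def write_ground_truth(prefix, gt: GroundTruth) -> tuple[Path, Path]:
    """Write the punctum table (CSV) and a JSON sidecar next to it."""
    prefix = Path(prefix)
    csv_path = prefix.with_suffix(".csv")
    json_path = prefix.with_suffix(".json")
    gt.puncta.to_csv(csv_path, index=False)
    sidecar = {
        "config": config_to_dict(gt.config),
        "n_puncta": int(len(gt.puncta)),
        "cell_mask_voxels": int(gt.cell_mask.sum()),
        "nucleus_mask_voxels": int(gt.nucleus_mask.sum()),
    }
    json_path.write_text(json.dumps(sidecar, indent=2))
    return csv_path, json_path


def config_to_dict(config: SceneConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: convert(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)}
        if isinstance(obj, (tuple, list)):
            return [convert(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    return convert(config)


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config_dict, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(path, config_dict: dict, seed: int, extra: dict | None = None):
    """JSON provenance block: config hash, seed, package versions."""
    import cocompart

    record = {
        "config_hash": config_hash(config_dict),
        "seed": seed,
        "versions": {
            "cocompart": cocompart.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "config": config_dict,
    }
    if extra:
        record.update(extra)
    Path(path).write_text(json.dumps(record, indent=2))


def write_mesh_ply(path, mesh) -> None:
    """Optional PLY export of a surface mesh."""
    tm = mesh.as_trimesh()
    tm.export(Path(path), file_type="ply", encoding="ascii")
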
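"""TIFF input/output, ROI files and provenance records."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .stack import ImageStack


def read_stack(
    path,
    voxel_size=None,
    channel_names=None,
    time_interval=None,
    axes: str | None = None,
) -> ImageStack:
    """Read a single- or multi-channel TIFF / OME-TIFF as an ImageStack.

    The axis order is taken from the TIFF series metadata (subset of
    CZTYX) unless overridden with ``axes``; voxel size is read from OME
    pixel-size metadata when present and can be overridden.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        file_axes = axes or series.axes
        meta_voxel = _ome_voxel_size(tf)
    target = "CTZYX"
    # common synonyms: samples → channel, unknown/image sequence → z
    ax = (
        file_axes.upper().replace("S", "C").replace("Q", "Z").replace("I", "Z")
    )
    if len(ax) != data.ndim or any(c not in target for c in ax) or len(set(ax)) != len(ax):
        raise ValueError(f"cannot map TIFF axes {file_axes!r} onto (C,T,Z,Y,X)")
    perm = np.argsort([target.index(c) for c in ax], kind="stable")
    arr = np.transpose(data, perm)
    for i, c in enumerate(target):
        if c not in ax:
            arr = np.expand_dims(arr, i)
    vs = voxel_size or meta_voxel or (1.0, 1.0, 1.0)
    return ImageStack(
        data=arr,
        voxel_size=vs,
        channel_names=list(channel_names) if channel_names else [],
        time_interval=time_interval,
    )


def _ome_voxel_size(tf: "tifffile.TiffFile"):
    try:
        if tf.ome_metadata:
            import xml.etree.ElementTree as ET

            root = ET.fromstring(tf.ome_metadata)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            px = root.find(".//ome:Pixels", ns)
            if px is not None:
                dz = float(px.get("PhysicalSizeZ", 1.0))
                dy = float(px.get("PhysicalSizeY", 1.0))
                dx = float(px.get("PhysicalSizeX", 1.0))
                return (dz, dy, dx)
    except Exception:
        pass
    return None


def write_stack(path, stack: ImageStack) -> None:
    dz, dy, dx = stack.voxel_size
    tifffile.imwrite(
        path,
        np.asarray(stack.data),
        metadata={
            "axes": "CTZYX",
            "PhysicalSizeZ": dz,
            "PhysicalSizeY": dy,
            "PhysicalSizeX": dx,
        },
    )


def write_labels(path, labels: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(labels, dtype=np.int32))


def write_object_table(path, table: pd.DataFrame, run_id: str | None = None) -> None:
    cols = [
        "object_id",
        "voxel_count",
        "volume_um3",
        "centroid_z_um",
        "centroid_y_um",
        "centroid_x_um",
    ]
    out = table[[c for c in cols if c in table.columns]].copy()
    if run_id is not None:
        out["run_id"] = run_id
    out.to_csv(path, index=False)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


PROVENANCE_SCHEMA_VERSION = "1"


def provenance_record(params: dict, inputs=()) -> dict:
    """Machine-readable record of one analysis run.

    The run id is a digest of the parameters and input checksums, so an
    identical configuration reproduces byte-identical outputs.
    """
    from . import __version__

    checksums = {str(p): file_sha256(p) for p in inputs}
    digest = hashlib.sha256(
        json.dumps({"p": params, "i": checksums}, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    return {
        "run_id": digest,
        "software": "woundquant",
        "version": __version__,
        "schema_version": PROVENANCE_SCHEMA_VERSION,
        "parameters": params,
        "input_checksums": checksums,
    }


def write_summary(path, summary: dict, provenance: dict | None = None) -> None:
    payload = dict(summary)
    if provenance is not None:
        payload["provenance"] = provenance
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify) + "\n")


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
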
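"""Standard-format I/O: OME-TIFF stacks, annotation and result CSV tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import ImageStack, OpticsParams, SchemaError

ROI_ANNOTATION_COLUMNS = ("structure", "pair_id", "x_px", "y_px", "z_plane")
POINT_ANNOTATION_COLUMNS = ("object", "pair_id", "x_px", "y_px", "z_plane", "frame")
TRAJECTORY_COLUMNS = ("frame", "time_s", "object", "track_id", "sister",
                      "x", "y", "z", "elongation")
TRACE_COLUMNS = ("bundle_id", "bundle_class", "point_index", "x_um", "y_um")


def write_stack(path, stack: ImageStack) -> None:
    """Write an :class:`ImageStack` as OME-TIFF with pixel-size metadata."""
    axes = "TCZYX" if stack.is_timelapse else "CZYX"
    o = stack.optics
    metadata = {
        "axes": axes,
        "PhysicalSizeX": o.pixel_size_xy,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": o.pixel_size_xy,
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeZ": o.z_step,
        "PhysicalSizeZUnit": "µm",
        "Channel": {"Name": list(stack.channel_names)[: stack.n_channels]},
    }
    if stack.frame_interval_s is not None:
        metadata["TimeIncrement"] = stack.frame_interval_s
        metadata["TimeIncrementUnit"] = "s"
    tifffile.imwrite(
        str(path), stack.data.astype(np.float32), ome=True, metadata=metadata
    )


def read_stack(path, optics: OpticsParams | None = None) -> ImageStack:
    """Read an OME-TIFF written by :func:`write_stack`.

    When ``optics`` is omitted, pixel size and z-step are taken from the OME
    metadata and the remaining optical parameters keep their defaults.
    """
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        axes = tf.series[0].axes
        if optics is None:
            px = z = None
            try:
                from xml.etree import ElementTree

                root = ElementTree.fromstring(tf.ome_metadata)
                ns = {"ome": root.tag.split("}")[0].strip("{")}
                pix = root.find(".//ome:Pixels", ns)
                px = float(pix.get("PhysicalSizeX"))
                z = float(pix.get("PhysicalSizeZ"))
            except Exception:
                pass
            kwargs = {}
            if px:
                kwargs["pixel_size_xy"] = px
            if z:
                kwargs["z_step"] = z
            optics = OpticsParams(**kwargs)
    # normalize axis order to (C, Z, Y, X) / (T, C, Z, Y, X)
    want = "TCZYX" if "T" in axes else "CZYX"
    for ax in want:
        if ax not in axes:
            data = np.expand_dims(data, 0)
            axes = ax + axes
    order = [axes.index(ax) for ax in want]
    data = np.transpose(data, order)
    return ImageStack(data=data, optics=optics)


def _validate(df: pd.DataFrame, required, what: str) -> pd.DataFrame:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {', '.join(missing)}")
    for col in required:
        if df[col].isna().any():
            rows = df.index[df[col].isna()].tolist()[:5]
            raise SchemaError(f"{what}: column {col!r} has missing values (rows {rows})")
    return df


def read_roi_annotations(path) -> pd.DataFrame:
    """ROI annotation CSV: structure, pair_id, x_px, y_px, z_plane."""
    return _validate(pd.read_csv(path), ROI_ANNOTATION_COLUMNS, Path(path).name)


def read_point_annotations(path) -> pd.DataFrame:
    """Point annotation CSV: object, pair_id, x_px, y_px, z_plane, frame."""
    return _validate(pd.read_csv(path), POINT_ANNOTATION_COLUMNS, Path(path).name)


def read_trajectories(path) -> pd.DataFrame:
    """Trajectory CSV: frame, time_s, object, track_id, sister, x, y, z,
    elongation (µm / seconds)."""
    return _validate(pd.read_csv(path), TRAJECTORY_COLUMNS, Path(path).name)


def read_traces(path) -> dict:
    """Bundle-trace CSV -> {bundle_id: (bundle_class, (N, 2) µm points)}."""
    df = _validate(pd.read_csv(path), TRACE_COLUMNS, Path(path).name)
    out = {}
    for bid, grp in df.groupby("bundle_id"):
        grp = grp.sort_values("point_index")
        out[bid] = (grp["bundle_class"].iloc[0], grp[["x_um", "y_um"]].to_numpy(float))
    return out


def write_table(path, df: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
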
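"""Reading and writing calibrated multi-channel 3D stacks.

Stacks are plain multi-page TIFF / OME-TIFF.  Voxel spacing is taken from
OME metadata or an ImageJ-style resolution tag when present; otherwise it
must be supplied explicitly (an override is also honoured when metadata
exists).  A missing calibration is an error, never a silent default: every
downstream density is normalised by the physical image volume.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import tifffile
import yaml

from .geometry import BinaryVolume, IntensityVolume, VoxelGeometry

__all__ = ["read_stack", "write_stack", "write_mask", "read_mask", "project_max"]


def _spacing_from_tiff(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    # OME-XML PhysicalSize first, then ImageJ metadata + resolution tags.
    try:
        if tif.ome_metadata:
            import xml.etree.ElementTree as ET

            root = ET.fromstring(tif.ome_metadata)
            for el in root.iter():
                if el.tag.endswith("Pixels"):
                    sx = el.get("PhysicalSizeX")
                    sy = el.get("PhysicalSizeY")
                    sz = el.get("PhysicalSizeZ")
                    if sx and sy and sz:
                        return (float(sz), float(sy), float(sx))
    except Exception:
        pass
    try:
        page = tif.pages[0]
        ij = tif.imagej_metadata or {}
        zspacing = ij.get("spacing")
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        if zspacing and xres and yres:
            xr = xres.value[0] / xres.value[1]
            yr = yres.value[0] / yres.value[1]
            if xr > 0 and yr > 0:
                return (float(zspacing), 1.0 / yr, 1.0 / xr)
    except Exception:
        pass
    return None


def _sidecar_spacing(path: str) -> tuple[float, float, float] | None:
    sidecar = os.path.splitext(path)[0] + ".yaml"
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
        sp = meta.get("spacing_zyx")
        if sp is not None:
            return tuple(float(s) for s in sp)
    return None


def read_stack(path: str | os.PathLike,
               spacing_override: Sequence[float] | None = None,
               channel: str = "endothelium") -> IntensityVolume:
    """Read a single- or multi-page TIFF z-stack as a calibrated volume.

    Spacing resolution order: explicit ``spacing_override`` (z, y, x in µm),
    then OME / ImageJ metadata, then a ``<stem>.yaml`` sidecar with a
    ``spacing_zyx`` entry.  If none is available, a :class:`ValueError` is
    raised rather than assuming unit spacing.
    """
    path = os.fspath(path)
    with tifffile.TiffFile(path) as tif:
        shapes = {p.shape for p in tif.pages}
        if len(shapes) > 1:
            raise ValueError(f"{path}: pages have inconsistent dimensions {sorted(shapes)}")
        data = tif.asarray()
        meta_spacing = _spacing_from_tiff(tif)
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a grayscale z-stack, got shape {data.shape}")

    if spacing_override is not None:
        spacing = tuple(float(s) for s in spacing_override)
    elif meta_spacing is not None:
        spacing = meta_spacing
    else:
        spacing = _sidecar_spacing(path)
        if spacing is None:
            raise ValueError(
                f"{path}: no voxel spacing in metadata and no override/sidecar given; "
                "refusing to guess a calibration")

    geometry = VoxelGeometry(spacing, data.shape)
    return IntensityVolume(np.asarray(data, dtype=np.float64), geometry, channel=channel)


def write_stack(volume: IntensityVolume, path: str | os.PathLike) -> None:
    """Write a calibrated volume as an ImageJ-style TIFF (round-trip safe).

    Values are stored bit-exactly (float32 input stays float32, integer
    stays integer; float64 is written as float64 raw TIFF when ImageJ mode
    cannot hold it).  Spacing is encoded in the resolution tags and the
    ImageJ ``spacing`` field, recoverable to at least 6 decimals.
    """
    path = os.fspath(path)
    sz, sy, sx = volume.geometry.spacing_zyx
    data = volume.values
    if data.dtype == np.float64:
        data = data  # raw TIFF below
        imagej = False
    else:
        imagej = True
    kwargs = dict(resolution=(1.0 / sx, 1.0 / sy), photometric="minisblack")
    if imagej:
        tifffile.imwrite(path, data, imagej=True,
                         metadata={"spacing": sz, "unit": "um", "axes": "ZYX"},
                         **kwargs)
    else:
        tifffile.imwrite(path, data, metadata={"spacing": sz, "axes": "ZYX"}, **kwargs)
        # raw float64 TIFF loses the ImageJ spacing tag; keep a sidecar
        with open(os.path.splitext(path)[0] + ".yaml", "w") as fh:
            yaml.safe_dump({"spacing_zyx": [sz, sy, sx]}, fh)


def write_mask(mask: BinaryVolume, path: str | os.PathLike) -> None:
    """Write a binary mask as an 8-bit TIFF (0/255) with calibration."""
    vol = IntensityVolume(mask.values.astype(np.uint8) * 255, mask.geometry)
    write_stack(vol, path)


def read_mask(path: str | os.PathLike,
              spacing_override: Sequence[float] | None = None) -> BinaryVolume:
    vol = read_stack(path, spacing_override=spacing_override)
    return BinaryVolume(vol.values > 0, vol.geometry)


def project_max(volume: IntensityVolume) -> IntensityVolume:
    """Maximum-intensity projection along z (the 2D merge of a z-stack).

    Returns a single-plane volume whose pixel (y, x) is the maximum of the
    input over z; the planar pixel area is spacing_y × spacing_x.  Used for
    the planar microglial distribution analysis.
    """
    if volume.shape[0] < 1:
        raise ValueError("volume has no z-planes")
    plane = volume.values.max(axis=0)[None, :, :]
    return IntensityVolume(plane, volume.geometry.planar, channel=volume.channel)
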
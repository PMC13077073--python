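"""File I/O: ImageJ-compatible TIFF stacks, SWC centerlines, CSV/JSON tables."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .core import CenterlineGraph, VolumeStack

__all__ = ["write_tiff", "read_tiff", "write_swc", "write_json", "read_json"]


def write_tiff(path: str | Path, stack: VolumeStack) -> None:
    """Write a stack as an ImageJ-compatible TIFF with spacing metadata.

    Lateral pixel size goes into the TIFF resolution tags; the z step (for
    3D stacks) into the ImageJ ``spacing`` field, all in micrometres.
    """
    data = stack.data
    if data.ndim not in (3, 4):
        raise ValueError("only 3D/4D stacks are written as TIFF")
    sz, sy, sx = stack.spacing_um[-3:] if len(stack.spacing_um) >= 3 else (1.0, *stack.spacing_um[-2:])
    tifffile.imwrite(
        str(path),
        data.astype(np.float32),
        imagej=True,
        resolution=(1.0 / sx, 1.0 / sy),
        metadata={"spacing": sz, "unit": "um", "axes": "ZYX" if data.ndim == 3 else "TZYX"},
    )


def read_tiff(path: str | Path, spacing_um: tuple[float, ...] | None = None) -> VolumeStack:
    """Read a TIFF stack; spacing from ImageJ metadata unless overridden."""
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        if spacing_um is None:
            meta = tif.imagej_metadata or {}
            sz = float(meta.get("spacing", 1.0))
            page = tif.pages[0]
            xres = page.tags.get("XResolution")
            yres = page.tags.get("YResolution")
            sx = xres.value[1] / xres.value[0] if xres else 1.0
            sy = yres.value[1] / yres.value[0] if yres else 1.0
            spacing_um = (sz, sy, sx)
    return VolumeStack(data=data, spacing_um=spacing_um)


def write_swc(path: str | Path, graph: CenterlineGraph) -> None:
    """Write centerlines as SWC, one unrooted tree per segment.

    SWC coordinates are (x, y, z) in micrometres; radii in the fifth column.
    Node type 0 (undefined) is used since vessels are not neurites.
    """
    lines = []
    node_id = 1
    for seg in graph.segments:
        parent = -1
        for (z, y, x), r in zip(seg.points_um, seg.radii_um):
            lines.append(f"{node_id} 0 {x:.4f} {y:.4f} {z:.4f} {r:.4f} {parent}")
            parent = node_id
            node_id += 1
    Path(path).write_text("\n".join(lines) + "\n")


def write_json(path: str | Path, obj: dict) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
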
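"""File formats: mask/image PNGs, labelme-style polygon JSON, partition export.

Masks are single-channel PNGs with 0 = background and 255 = foreground.
Polygon annotations follow the labelme layout (``shapes[].points`` in image
pixel coordinates) and are rasterized with an even-odd scanline fill.
Partitions export as a 4-valued label PNG (1-4 = R1-R4) plus a JSON
sidecar with the geometry that produced them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .errors import BadImage
from .geometry import SubRegionPartition


def read_image(path) -> np.ndarray:
    """Read an RGB image as an H×W×3 uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_image(path, rgb: np.ndarray) -> None:
    arr = np.asarray(rgb)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise BadImage(f"expected H×W×3 image, got shape {arr.shape}")
    Image.fromarray(arr.astype(np.uint8), mode="RGB").save(Path(path))


def read_mask(path) -> np.ndarray:
    """Read a mask PNG; any nonzero pixel counts as foreground."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L")) > 0


def write_mask(path, mask: np.ndarray) -> None:
    arr = (np.asarray(mask) > 0).astype(np.uint8) * 255
    Image.fromarray(arr, mode="L").save(Path(path))


def rasterize_polygon(points, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize one polygon (vertices as (x, y) pixel coordinates) to a mask."""
    img = Image.new("L", (shape[1], shape[0]), 0)
    draw = ImageDraw.Draw(img)
    draw.polygon([(float(x), float(y)) for x, y in points], outline=1, fill=1)
    return np.asarray(img) > 0


def read_labelme(path, image_shape: tuple[int, int] | None = None):
    """Read a labelme-style annotation file into per-instance masks.

    Returns ``(masks, labels)`` where labels are the annotation's shape
    labels (strings).  ``image_shape`` overrides the file's recorded
    ``imageHeight``/``imageWidth``.
    """
    data = json.loads(Path(path).read_text())
    if image_shape is None:
        image_shape = (int(data["imageHeight"]), int(data["imageWidth"]))
    masks, labels = [], []
    for shape in data.get("shapes", []):
        if shape.get("shape_type", "polygon") != "polygon":
            continue
        masks.append(rasterize_polygon(shape["points"], image_shape))
        labels.append(shape.get("label", ""))
    return masks, labels


def write_labelme(path, masks, labels, image_shape: tuple[int, int],
                  image_path: str = "") -> None:
    """Write masks as labelme-style polygon annotations (contour vertices)."""
    from .geometry import trace_contour

    shapes = []
    for mask, label in zip(masks, labels):
        contour = trace_contour(mask)
        # keep a closed, de-duplicated vertex loop
        pts = []
        for x, y in contour:
            if not pts or pts[-1] != [float(x), float(y)]:
                pts.append([float(x), float(y)])
        shapes.append(
            {"label": str(label), "points": pts, "shape_type": "polygon"}
        )
    doc = {
        "version": "5.0.0",
        "flags": {},
        "shapes": shapes,
        "imagePath": image_path,
        "imageData": None,
        "imageHeight": int(image_shape[0]),
        "imageWidth": int(image_shape[1]),
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def export_partition(partition: SubRegionPartition, png_path, json_path=None) -> None:
    """Export a partition as a 1-4 label PNG plus a JSON geometry sidecar."""
    label_img = partition.label_image()
    Image.fromarray(label_img, mode="L").save(Path(png_path))
    if json_path is None:
        json_path = Path(png_path).with_suffix(".json")
    chord = partition.chord
    sidecar = {
        "chord": {
            "start": [chord.p_start.x, chord.p_start.y],
            "end": [chord.p_end.x, chord.p_end.y],
            "length": chord.length,
        },
        "quarter_points": [[p.x, p.y] for p in partition.quarter_points],
        "cut_lines": [
            {"a": l.a, "b": l.b, "c": l.c} for l in partition.cut_lines
        ],
        "region_centroids": [[p.x, p.y] for p in partition.region_centroids],
        "region_areas": partition.areas,
        "cut_intersections": [
            [[p.x, p.y] for p in pair] for pair in partition.cut_intersections
        ],
    }
    Path(json_path).write_text(json.dumps(sidecar, indent=2) + "\n")
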
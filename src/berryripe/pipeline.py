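"""End-to-end orchestration: image + instance masks in, stage predictions out.

The pipeline runs each instance through preprocess → partition → regional
features → classifier prediction.  It is total: every input instance
yields exactly one result, either a stage prediction or a structured error
code — a bad instance never aborts the batch.  Segmentation is pluggable:
masks come from files (or any callable producing them); no detector ships
with the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageDraw
from scipy import ndimage

from . import colors, geometry
from .classify import STAGE_NAMES, RipenessModel
from .errors import BerryRipeError
from .geometry import SubRegionPartition


@dataclass
class InstanceResult:
    """Prediction (or structured failure) for one instance."""

    instance_id: str
    stage: int | None = None
    stage_name: str | None = None
    probability: float | None = None
    probabilities: np.ndarray | None = None
    partition: SubRegionPartition | None = None
    features: np.ndarray | None = None
    mask: np.ndarray | None = None
    error: str | None = None
    meta: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.error is None

    def to_dict(self) -> dict:
        out = {"instance_id": self.instance_id, "error": self.error}
        if self.ok:
            out.update(
                stage=int(self.stage),
                stage_name=self.stage_name,
                probability=round(float(self.probability), 6),
                probabilities=[round(float(p), 6) for p in self.probabilities],
            )
        return out


def run_pipeline(
    image: np.ndarray,
    masks: list[np.ndarray],
    model: RipenessModel,
    channel_subset=colors.SELECTED_CHANNELS,
    instance_ids: list[str] | None = None,
) -> list[InstanceResult]:
    """Predict the ripeness stage of every masked instance in an image.

    Per-instance failures (empty/too-small masks, degenerate geometry) are
    reported as the error's class name in ``InstanceResult.error``.
    """
    stack = colors.to_channel_stack(image) if masks else None
    ids = instance_ids or [f"inst{i:03d}" for i in range(len(masks))]
    results = []
    for inst_id, mask in zip(ids, masks):
        try:
            part = geometry.partition(mask)
            fv = colors.regional_features(stack, part, channel_subset)
            proba = model.predict_proba(fv.values, schema=fv.schema)[0]
            k = int(np.argmax(proba))
            stage = int(model.classes[k])
            results.append(
                InstanceResult(
                    instance_id=inst_id,
                    stage=stage,
                    stage_name=STAGE_NAMES[stage],
                    probability=float(proba[k]),
                    probabilities=proba,
                    partition=part,
                    features=fv.values,
                    mask=np.asarray(mask) > 0,
                )
            )
        except BerryRipeError as exc:
            results.append(
                InstanceResult(
                    instance_id=inst_id,
                    mask=np.asarray(mask) > 0,
                    error=type(exc).__name__,
                    meta={"message": str(exc)},
                )
            )
    return results


def extract_features_frame(
    instances, channel_subset=colors.SELECTED_CHANNELS
) -> "pd.DataFrame":
    """Regional features for a list of synthetic (or loaded) instances.

    Returns a DataFrame with one ``<channel>_<region>`` column per feature,
    plus ``label`` and ``instance_id``.  Instances whose geometry fails are
    dropped with their error recorded in ``frame.attrs['errors']``.
    """
    import pandas as pd

    rows, labels, ids, errors = [], [], [], {}
    schema = colors.feature_schema(channel_subset)
    columns = [f"{ch}_{reg}" for ch, reg in schema]
    for i, inst in enumerate(instances):
        inst_id = getattr(inst, "seed_key", None) or f"inst{i:04d}"
        try:
            part = geometry.partition(inst.mask)
            stack = colors.to_channel_stack(inst.rgb)
            fv = colors.regional_features(stack, part, channel_subset)
        except BerryRipeError as exc:
            errors[str(inst_id)] = type(exc).__name__
            continue
        rows.append(fv.values)
        labels.append(inst.label)
        ids.append(str(inst_id))
    frame = pd.DataFrame(np.array(rows), columns=columns)
    frame["label"] = labels
    frame["instance_id"] = ids
    frame.attrs["errors"] = errors
    frame.attrs["channel_subset"] = list(channel_subset)
    return frame


#: Deterministic display colors per stage (White → Full ripe), plus error blue.
STAGE_COLORS = (
    (235, 235, 235),
    (250, 200, 120),
    (250, 150, 80),
    (235, 100, 60),
    (220, 40, 40),
    (130, 10, 30),
)
ERROR_COLOR = (60, 110, 230)


def render_overlay(image: np.ndarray, results: list[InstanceResult]) -> np.ndarray:
    """Draw instance outlines, stage names and probabilities on the image.

    Purely deterministic: identical inputs produce identical output bytes.
    Failed instances are outlined in blue with their error code.
    """
    canvas = np.asarray(image).astype(np.uint8).copy()
    for res in results:
        if res.mask is None:
            continue
        color = ERROR_COLOR if not res.ok else STAGE_COLORS[res.stage]
        boundary = res.mask & ~ndimage.binary_erosion(res.mask)
        canvas[boundary] = color

    im = Image.fromarray(canvas, mode="RGB")
    draw = ImageDraw.Draw(im)
    for res in results:
        if res.mask is None or not res.mask.any():
            continue
        ys, xs = np.nonzero(res.mask)
        x0, y0 = int(xs.min()), int(ys.min())
        text = (
            f"{res.stage_name} p={res.probability:.2f}"
            if res.ok
            else f"error: {res.error}"
        )
        color = ERROR_COLOR if not res.ok else STAGE_COLORS[res.stage]
        draw.rectangle(
            [x0, max(y0 - 12, 0), x0 + 6 * len(text) + 4, max(y0 - 12, 0) + 12],
            fill=(0, 0, 0),
        )
        draw.text((x0 + 2, max(y0 - 12, 0) + 1), text, fill=color)
    return np.asarray(im)
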
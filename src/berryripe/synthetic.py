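"""Seeded generator of strawberry-like instance patches, masks and scenes.

Every other module is testable without any image download: this module
draws convex teardrop fruit silhouettes in roughly fruit-hanging
orientation and paints them according to the six-stage ripeness
definition, in which the red surface fraction grows from the tip upward —
White ≈ 0, Breaking ≈ 1/5, Turning-1 ≈ 2/5, Turning-2 ≈ 3/5, Ripe ≈ 4/5,
and Full ripe fully red but darker.

The generator emulates the features the ripeness method relies on (shape
convexity, downward tip within ±30°, tip-up red gradient, stage-dependent
darkening, pixel noise, occlusion in scenes) and deliberately nothing else:
no achenes, calyx, lighting or photorealism.

All outputs are pure functions of (parameters, seed): per-instance RNG
streams are derived from ``SeedSequence([seed, stage, index])``, so a
dataset is byte-identical across runs and machines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import BadShapeParams

#: Red surface fraction per ripeness stage, tip upward.
RED_FRACTIONS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)

#: Ordinal stage names, index = integer label.
STAGE_NAMES = ("White", "Breaking", "Turning-1", "Turning-2", "Ripe", "Full ripe")


@dataclass(frozen=True)
class StageColorModel:
    """Colors and noise defining how each stage is painted.

    ``transition_band`` is the width of the smooth green-to-red blend as a
    fraction of fruit height; ``noise_sd`` is per-channel Gaussian pixel
    noise in 8-bit units and is the difficulty dial for classification.
    """

    red_fractions: tuple = RED_FRACTIONS
    unripe_green: tuple = (170, 200, 140)
    ripe_red: tuple = (200, 40, 40)
    dark_red: tuple = (140, 20, 30)
    transition_band: float = 0.08
    noise_sd: float = 6.0

    def red_fraction(self, stage: int) -> float:
        return self.red_fractions[stage]


@dataclass
class SyntheticInstance:
    """One generated fruit: patch, mask, label and generator metadata."""

    rgb: np.ndarray
    mask: np.ndarray
    label: int
    rotation: float
    seed_key: tuple
    meta: dict = field(default_factory=dict)


def _teardrop_halfwidth(v: np.ndarray) -> np.ndarray:
    """Normalized half-width profile of the fruit, v=0 at top, v=1 at tip.

    A Beta-like profile ``v**0.5 * (1-v)**0.8``: rounded shoulder at the
    top, pointed tip at the bottom, widest above the midline (v ≈ 0.385).
    The profile is concave, so the silhouette is convex.
    """
    v = np.clip(v, 0.0, 1.0)
    vstar = 0.5 / 1.3
    peak = vstar**0.5 * (1 - vstar) ** 0.8
    return np.clip(v, 0, 1) ** 0.5 * (1 - np.clip(v, 0, 1)) ** 0.8 / peak


def make_shape_mask(
    height: int,
    width: int,
    elongation: float = 1.4,
    rotation: float = 0.0,
    seed: int = 0,
    fill: float = 0.86,
) -> np.ndarray:
    """A convex teardrop fruit mask, tip pointing down before rotation.

    The silhouette is evaluated analytically: each pixel's coordinates are
    rotated by ``-rotation`` (degrees, about the patch center) into fruit
    coordinates and tested against the teardrop half-width profile, so
    rotation introduces no resampling artifacts and a 180° rotation is an
    exact vertical mirror.

    ``elongation`` is fruit height over maximal fruit width; ``fill`` is
    the fraction of the patch the fruit spans.  ``seed`` jitters the
    fruit's size slightly (±4%).
    """
    if height < 16 or width < 16:
        raise BadShapeParams(f"patch dims must be >= 16, got {height}x{width}")
    if elongation <= 0 or not (0 < fill <= 1):
        raise BadShapeParams("elongation and fill must be positive")
    rng = np.random.default_rng(seed)
    jitter = 1.0 + rng.uniform(-0.04, 0.04)
    fruit_h = fill * height * jitter
    fruit_w = min(fruit_h / elongation, fill * width)

    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    yy, xx = np.mgrid[0:height, 0:width]
    theta = np.deg2rad(rotation)
    # rotate image coords by -theta into fruit coords
    fx = (xx - cx) * np.cos(-theta) - (yy - cy) * np.sin(-theta)
    fy = (xx - cx) * np.sin(-theta) + (yy - cy) * np.cos(-theta)
    v = fy / fruit_h + 0.5  # 0 at fruit top, 1 at tip
    inside = (v >= 0) & (v <= 1) & (np.abs(fx) <= (fruit_w / 2) * _teardrop_halfwidth(v))
    if inside.sum() < 64:
        raise BadShapeParams(
            f"generated mask too small ({int(inside.sum())} px); enlarge the patch"
        )
    return inside


def _axis_coordinate(mask: np.ndarray, rotation: float) -> np.ndarray:
    """Normalized position along the fruit axis for every pixel (0 top, 1 tip)."""
    height, width = mask.shape
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    yy, xx = np.mgrid[0:height, 0:width]
    theta = np.deg2rad(rotation)
    fy = (xx - cx) * np.sin(-theta) + (yy - cy) * np.cos(-theta)
    fg = fy[mask]
    lo, hi = fg.min(), fg.max()
    return np.clip((fy - lo) / max(hi - lo, 1e-9), 0.0, 1.0)


def paint_stage(
    mask: np.ndarray,
    stage: int,
    color_model: StageColorModel | None = None,
    seed: int = 0,
    rotation: float = 0.0,
    background: tuple = (128, 128, 128),
) -> np.ndarray:
    """Paint a fruit mask at a given ripeness stage.

    The red region grows from the tip upward: the red/green boundary is a
    line perpendicular to the fruit axis (horizontal in fruit coordinates,
    i.e. before rotation), placed at the height where the cumulative
    foreground area from the tip equals the stage's red surface fraction —
    so "one-fifth red" means one fifth of the visible fruit surface, not of
    its height.  Full ripe is painted dark red throughout.  A smooth
    transition band and seeded Gaussian pixel noise are applied; the
    background is neutral gray.
    """
    model = color_model or StageColorModel()
    rng = np.random.default_rng(seed)
    mask = np.asarray(mask) > 0
    rf = model.red_fraction(stage)

    v = _axis_coordinate(mask, rotation)
    from_tip = 1.0 - v
    if rf <= 0.0:
        alpha = np.zeros_like(from_tip)
    elif rf >= 1.0:
        alpha = np.ones_like(from_tip)
    else:
        boundary = float(np.quantile(from_tip[mask], rf))
        alpha = np.clip((boundary - from_tip) / model.transition_band + 0.5, 0.0, 1.0)

    red = np.array(model.dark_red if rf >= 1.0 else model.ripe_red, dtype=float)
    green = np.array(model.unripe_green, dtype=float)
    img = np.empty(mask.shape + (3,), dtype=float)
    img[:] = np.array(background, dtype=float)
    fruit = alpha[..., None] * red + (1.0 - alpha[..., None]) * green
    img[mask] = fruit[mask]
    img += rng.normal(0.0, model.noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def make_instance(
    stage: int,
    seed_key,
    patch_size: tuple[int, int] = (96, 80),
    color_model: StageColorModel | None = None,
    max_rotation: float = 30.0,
) -> SyntheticInstance:
    """One random fruit at a stage, fully determined by ``seed_key``."""
    ss = np.random.SeedSequence(list(seed_key))
    rng = np.random.default_rng(ss)
    rotation = float(rng.uniform(-max_rotation, max_rotation))
    elongation = float(rng.uniform(1.25, 1.6))
    shape_seed, paint_seed = (int(s) for s in ss.generate_state(2) >> 1)
    mask = make_shape_mask(
        patch_size[0], patch_size[1],
        elongation=elongation, rotation=rotation, seed=shape_seed,
    )
    rgb = paint_stage(
        mask, stage, color_model=color_model, seed=paint_seed, rotation=rotation
    )
    return SyntheticInstance(
        rgb=rgb,
        mask=mask,
        label=stage,
        rotation=rotation,
        seed_key=tuple(seed_key),
        meta={"elongation": elongation, "patch_size": patch_size},
    )


def make_dataset(
    n_per_stage: int,
    seed: int = 0,
    patch_size: tuple[int, int] = (96, 80),
    color_model: StageColorModel | None = None,
    out_dir=None,
) -> tuple[list[SyntheticInstance], pd.DataFrame]:
    """A balanced labelled dataset of ``6 * n_per_stage`` instances.

    Returns the instances plus a manifest (one row per instance: id, stage
    label and name, rotation, seed key; with ``out_dir`` also the written
    PNG paths).  Per-instance randomness is keyed by (seed, stage, index),
    so the output is reproducible instance-by-instance.
    """
    if n_per_stage < 1:
        raise ValueError("n_per_stage must be >= 1")
    instances = []
    rows = []
    for stage in range(6):
        for idx in range(n_per_stage):
            inst = make_instance(
                stage, (seed, stage, idx),
                patch_size=patch_size, color_model=color_model,
            )
            instances.append(inst)
            rows.append(
                {
                    "instance_id": f"s{stage}_i{idx:04d}",
                    "label": stage,
                    "stage": STAGE_NAMES[stage],
                    "rotation_deg": round(inst.rotation, 3),
                    "seed": seed,
                }
            )
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        from . import io as brio

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for inst, row in zip(instances, manifest.itertuples()):
            img_path = out_dir / f"{row.instance_id}.png"
            mask_path = out_dir / f"{row.instance_id}_mask.png"
            brio.write_image(img_path, inst.rgb)
            brio.write_mask(mask_path, inst.mask)
            paths.append((img_path.name, mask_path.name))
        manifest["image"] = [p[0] for p in paths]
        manifest["mask"] = [p[1] for p in paths]
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return instances, manifest


@dataclass
class Scene:
    """A composited multi-fruit image with per-instance ground truth."""

    image: np.ndarray
    masks: list[np.ndarray]       # visible (possibly occluded) masks
    full_masks: list[np.ndarray]  # un-occluded silhouettes
    labels: list[int]


def _textured_background(shape, rng) -> np.ndarray:
    """Low-frequency mottled gray-green canvas, like out-of-focus foliage."""
    h, w = shape
    coarse = rng.normal(0, 1, size=(max(h // 16, 2), max(w // 16, 2), 3))
    reps = (h // coarse.shape[0] + 1, w // coarse.shape[1] + 1)
    tex = np.kron(coarse, np.ones((reps[0], reps[1], 1)))[:h, :w]
    base = np.array([95.0, 110.0, 85.0])
    return np.clip(base + 18.0 * tex, 0, 255)


def make_scene(
    n_instances: int,
    occlusion_fraction: float = 0.0,
    seed: int = 0,
    canvas: tuple[int, int] = (360, 480),
    patch_size: tuple[int, int] = (96, 80),
    color_model: StageColorModel | None = None,
) -> Scene:
    """Composite ``n_instances`` fruits on a textured background.

    With ``occlusion_fraction`` > 0 the last instance is deliberately
    placed over the previous one so the lower fruit loses roughly that
    fraction of its area (clipped to 10-50%); overlapped pixels always
    belong to the upper (later-drawn) instance.  With 0, placements are
    disjoint by construction.
    """
    if n_instances < 1:
        raise ValueError("n_instances must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 999]))
    h, w = canvas
    ph, pw = patch_size

    # disjoint grid placement, shuffled
    cols, rows_n = w // pw, h // ph
    if cols * rows_n < n_instances:
        raise ValueError(
            f"canvas {canvas} fits at most {cols * rows_n} patches of {patch_size}"
        )
    cells = [(r, c) for r in range(rows_n) for c in range(cols)]
    rng.shuffle(cells)
    offsets = [(r * ph, c * pw) for r, c in cells[:n_instances]]

    instances = [
        make_instance(
            int(rng.integers(0, 6)), (seed, 7, i),
            patch_size=patch_size, color_model=color_model,
        )
        for i in range(n_instances)
    ]

    if occlusion_fraction > 0 and n_instances >= 2:
        target = float(np.clip(occlusion_fraction, 0.1, 0.5))
        base = offsets[-2]
        lower = instances[-2].mask
        area = lower.sum()
        best = None
        for f in np.linspace(0.15, 0.95, 33):
            dy, dx = 0, int(round(f * pw))
            oy, ox = base[0] + dy, base[1] + dx
            if oy + ph > h or ox + pw > w:
                continue
            shift = ox - base[1]
            overlap = (lower[:, shift:] & instances[-1].mask[:, : pw - shift]).sum()
            ratio = overlap / area
            if best is None or abs(ratio - target) < abs(best[0] - target):
                best = (ratio, (oy, ox))
        if best is not None:
            offsets[-1] = best[1]

    image = _textured_background(canvas, rng)
    occupancy = np.full(canvas, -1, dtype=int)
    full_masks = []
    for i, (inst, (oy, ox)) in enumerate(zip(instances, offsets)):
        full = np.zeros(canvas, dtype=bool)
        full[oy : oy + ph, ox : ox + pw] = inst.mask
        full_masks.append(full)
        patch_region = image[oy : oy + ph, ox : ox + pw]
        patch_region[inst.mask] = inst.rgb[inst.mask]
        occupancy[full] = i  # later instances overwrite: upper wins

    visible = [occupancy == i for i in range(n_instances)]
    noise = np.random.default_rng(np.random.SeedSequence([seed, 998]))
    image = np.clip(
        np.round(image + noise.normal(0, 2.0, size=image.shape)), 0, 255
    ).astype(np.uint8)
    return Scene(
        image=image,
        masks=visible,
        full_masks=full_masks,
        labels=[inst.label for inst in instances],
    )
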
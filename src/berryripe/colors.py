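"""Color-channel conversion and regional color-feature extraction.

Fruit ripeness is a color phenomenon: as a strawberry ripens its surface
turns from light green to red from the tip upward, which shows up most
strongly in the CIELAB a channel (green-red opponent axis) and HSV
saturation, while the blue, green and lightness channels fall.  Of the nine
candidate channels {R, G, B, H, S, V, L, a, b}, the five informative ones
{B, G, L, a, S} are used for regional feature extraction.

All channels are rescaled to 8-bit conventions so that a single SVM kernel
width is meaningful across channels: R/G/B stay 0-255, S and V map to
0-255, H maps to 0-179 (half-degrees), L* maps to 0-255 (L*·255/100), and
a*/b* are offset-coded as value+128.

The regional feature vector is the per-channel mean over each of the four
sub-regions R1..R4, ordered channel-major and region-minor, e.g. for the
full subset: (B,R1) (B,R2) ... (S,R3) (S,R4) — 20 values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color as skcolor
from skimage import transform as sktransform

from .errors import BadImage, EmptyMask, EmptyRegion
from .geometry import SubRegionPartition

#: All nine candidate channels.
ALL_CHANNELS = ("R", "G", "B", "H", "S", "V", "L", "a", "b")

#: The selected channels for regional features, in their fixed order.
SELECTED_CHANNELS = ("B", "G", "L", "a", "S")

#: Region labels in feature order.
REGION_NAMES = ("R1", "R2", "R3", "R4")

#: Target (width, height) of the bounding-box resize used by the
#: flattened-pixel baseline extractor.
METHOD1_SIZE = (30, 40)


@dataclass
class ChannelStack:
    """Nine aligned single-channel views of one RGB patch, 8-bit scaled."""

    channels: dict[str, np.ndarray]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class FeatureVector:
    """Ordered feature values plus the (channel, region) schema behind them."""

    values: np.ndarray
    schema: list[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.values)


def _ordered_subset(channel_subset) -> list[str]:
    subset = list(channel_subset)
    bad = [ch for ch in subset if ch not in SELECTED_CHANNELS]
    if bad:
        raise ValueError(
            f"unknown channels {bad}; choose from {SELECTED_CHANNELS}"
        )
    return [ch for ch in SELECTED_CHANNELS if ch in subset]


def to_channel_stack(rgb_patch: np.ndarray) -> ChannelStack:
    """Convert an 8-bit sRGB patch into the nine candidate channels.

    HSV and CIELAB (D65) are computed from sRGB and rescaled to the 8-bit
    conventions documented in the module docstring.

    Raises
    ------
    BadImage
        If the input is not an H×W×3 image.
    """
    arr = np.asarray(rgb_patch)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise BadImage(f"expected an H×W×3 RGB image, got shape {arr.shape}")
    rgb = arr.astype(np.float64)
    if arr.dtype != np.uint8 and rgb.max() <= 1.0:
        rgb = rgb * 255.0
    unit = rgb / 255.0

    hsv = skcolor.rgb2hsv(unit)
    lab = skcolor.rgb2lab(unit)

    channels = {
        "R": rgb[..., 0],
        "G": rgb[..., 1],
        "B": rgb[..., 2],
        "H": hsv[..., 0] * 179.0,
        "S": hsv[..., 1] * 255.0,
        "V": hsv[..., 2] * 255.0,
        "L": lab[..., 0] * 255.0 / 100.0,
        "a": np.clip(lab[..., 1] + 128.0, 0.0, 255.0),
        "b": np.clip(lab[..., 2] + 128.0, 0.0, 255.0),
    }
    return ChannelStack(channels=channels)


def whole_fruit_means(stack: ChannelStack, mask: np.ndarray) -> dict[str, float]:
    """Mean of each of the nine channels over foreground pixels.

    This is both the channel-selection statistic and the whole-foreground
    baseline feature extractor ("method 2").
    """
    fg = np.asarray(mask) > 0
    if not fg.any():
        raise EmptyMask("cannot average over an empty mask")
    return {ch: float(stack[ch][fg].mean()) for ch in ALL_CHANNELS}


def regional_features(
    stack: ChannelStack,
    partition: SubRegionPartition,
    channel_subset=SELECTED_CHANNELS,
) -> FeatureVector:
    """Per-sub-region channel means: the package's primary feature extractor.

    One value per (channel, region) pair, channel-major in the fixed order
    B, G, L, a, S filtered to ``channel_subset``, region-minor R1..R4.
    """
    subset = _ordered_subset(channel_subset)
    values = []
    schema = []
    for ch in subset:
        plane = stack[ch]
        for k, region in enumerate(partition.regions):
            if not region.any():
                raise EmptyRegion(f"region R{k + 1} is empty")
            values.append(float(plane[region].mean()))
            schema.append((ch, REGION_NAMES[k]))
    return FeatureVector(values=np.array(values), schema=schema)


def method2_features(
    stack: ChannelStack, mask: np.ndarray, channel_subset=SELECTED_CHANNELS
) -> FeatureVector:
    """Whole-foreground per-channel means as a feature vector (baseline method 2)."""
    subset = _ordered_subset(channel_subset)
    means = whole_fruit_means(stack, mask)
    return FeatureVector(
        values=np.array([means[ch] for ch in subset]),
        schema=[(ch, "all") for ch in subset],
    )


def method1_features(
    rgb_patch: np.ndarray, channel_subset=SELECTED_CHANNELS
) -> FeatureVector:
    """Flattened-pixel baseline (method 1): resize the bounding-box crop to 30×40.

    The rectangular crop — background pixels included — is resized to 30
    columns by 40 rows with bilinear interpolation, converted to channels,
    and each requested channel is flattened row-major, giving 1200 values
    per channel.
    """
    arr = np.asarray(rgb_patch)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise BadImage(f"expected an H×W×3 RGB image, got shape {arr.shape}")
    subset = _ordered_subset(channel_subset)
    w, h = METHOD1_SIZE
    if arr.shape[:2] != (h, w):
        resized = sktransform.resize(
            arr.astype(np.float64), (h, w), order=1, preserve_range=True,
            anti_aliasing=False,
        )
    else:
        resized = arr.astype(np.float64)
    stack = to_channel_stack(resized)
    values = np.concatenate([stack[ch].ravel() for ch in subset])
    schema = [
        (ch, f"px{i}") for ch in subset for i in range(h * w)
    ]
    return FeatureVector(values=values, schema=schema)


def feature_schema(channel_subset=SELECTED_CHANNELS) -> list[tuple[str, str]]:
    """The (channel, region) schema of the regional extractor for a subset."""
    subset = _ordered_subset(channel_subset)
    return [(ch, r) for ch in subset for r in REGION_NAMES]
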
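"""Hue-threshold target encoding ("image slicer" stage).

The camera frame is converted to HSV planes, thresholded on circular hue
distance (plus saturation/value gates) into a binary mask, the mask is cut
into five equal vertical strips, and the white-pixel imbalance between the
leftmost three and rightmost three strips is quantized into a batch of
stimulation signals for one half of the network.

Note the leftmost-3 and rightmost-3 strip groups share the middle strip, so
the middle strip cancels in the difference: ``left3 - right3 =
s0 + s1 - s3 - s4``. That literal overlapping comparison is the default;
``disjoint=True`` compares strips {0,1} vs {3,4} directly (identical
difference, smaller sums).

The side convention is contralateral: a left-heavy mask (target seen on the
left) stimulates the RIGHT network half, and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.color import rgb2hsv

DEFAULT_QUANTUM = 500  # white-pixel difference per stimulation signal


class Side(Enum):
    LEFT = "left"
    RIGHT = "right"
    NONE = "none"


@dataclass(frozen=True)
class HSVPlanes:
    """Per-pixel hue (degrees in [0, 360)), saturation and value (fractions)."""

    hue: np.ndarray
    saturation: np.ndarray
    value: np.ndarray


@dataclass(frozen=True)
class StripSums:
    """White-pixel count per vertical strip, strip 0 leftmost."""

    sums: tuple[int, int, int, int, int]

    @property
    def left3(self) -> int:
        return self.sums[0] + self.sums[1] + self.sums[2]

    @property
    def right3(self) -> int:
        return self.sums[2] + self.sums[3] + self.sums[4]

    @property
    def total(self) -> int:
        return int(sum(self.sums))

    @property
    def difference(self) -> int:
        """left3 - right3 (the middle strip cancels)."""
        return self.left3 - self.right3


@dataclass(frozen=True)
class StimulusBatch:
    """Quantized stimulation command: ``count`` signals to one network half."""

    side: Side
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be non-negative")
        if (self.count == 0) != (self.side is Side.NONE):
            raise ValueError("side is NONE iff count is 0")


def rgb_to_hsv(frame: np.ndarray) -> HSVPlanes:
    """Split an RGB frame into hue/saturation/value planes.

    Achromatic pixels get hue 0 with saturation 0.
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError("frame must be (height, width, 3)")
    hsv = rgb2hsv(frame)
    return HSVPlanes(hue=hsv[:, :, 0] * 360.0, saturation=hsv[:, :, 1], value=hsv[:, :, 2])


def circular_hue_distance(hue: np.ndarray, center: float) -> np.ndarray:
    """Shortest angular distance (degrees) between hues, wrapping at 360."""
    return np.abs((np.asarray(hue) - center + 180.0) % 360.0 - 180.0)


def threshold_hue(
    planes: HSVPlanes,
    hue_center: float = 0.0,
    hue_tol: float = 10.0,
    sat_min: float = 0.5,
    val_min: float = 0.3,
) -> np.ndarray:
    """Binary mask: white where the pixel is the desired hue.

    A pixel is white iff its circular hue distance to ``hue_center`` is at
    most ``hue_tol`` AND saturation >= ``sat_min`` AND value >= ``val_min``
    (the saturation/value gates reject achromatic and dark pixels whose hue
    is meaningless). Wrap-around is handled: center 0 with tol 10 admits 355.
    """
    if hue_tol < 0:
        raise ValueError("hue_tol must be non-negative")
    if not (0 <= sat_min <= 1 and 0 <= val_min <= 1):
        raise ValueError("sat_min and val_min must be in [0, 1]")
    return (
        (circular_hue_distance(planes.hue, hue_center) <= hue_tol)
        & (planes.saturation >= sat_min)
        & (planes.value >= val_min)
    )


def strip_edges(width: int) -> np.ndarray:
    """Column boundaries of the 5 vertical strips (6 monotone edges).

    Strips partition the columns; widths differ by at most one pixel, with
    the wider strips leftmost when ``width % 5 != 0``.
    """
    if width < 5:
        raise ValueError("mask width must be at least 5 columns")
    base, rem = divmod(width, 5)
    widths = np.array([base + 1] * rem + [base] * (5 - rem))
    return np.concatenate([[0], np.cumsum(widths)])


def strip_sums(mask: np.ndarray) -> StripSums:
    """White-pixel count in each of the five vertical strips of a mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    edges = strip_edges(mask.shape[1])
    sums = tuple(int(mask[:, edges[i] : edges[i + 1]].sum()) for i in range(5))
    return StripSums(sums)


def stimulus_from_sums(
    sums: StripSums, quantum: int = DEFAULT_QUANTUM, disjoint: bool = False
) -> StimulusBatch:
    """Quantize the strip imbalance into a stimulation batch.

    Each full ``quantum`` (default 500) of white-pixel difference between the
    left and right strip groups becomes one digitized synaptic signal,
    delivered to the network half opposite the heavy side (left-heavy mask ->
    RIGHT half). ``disjoint`` switches to comparing strips {0,1} vs {3,4};
    the difference, and hence the output, is unchanged.
    """
    if quantum <= 0:
        raise ValueError("quantum must be positive")
    if disjoint:
        diff = (sums.sums[0] + sums.sums[1]) - (sums.sums[3] + sums.sums[4])
    else:
        diff = sums.difference
    count = abs(diff) // quantum
    if count == 0:
        return StimulusBatch(Side.NONE, 0)
    return StimulusBatch(Side.RIGHT if diff > 0 else Side.LEFT, int(count))


def frame_to_stimulus(
    frame: np.ndarray,
    hue_center: float = 0.0,
    hue_tol: float = 10.0,
    sat_min: float = 0.5,
    val_min: float = 0.3,
    quantum: int = DEFAULT_QUANTUM,
) -> tuple[StripSums, StimulusBatch]:
    """Full per-frame pipeline: HSV -> threshold -> strips -> stimulus."""
    mask = threshold_hue(rgb_to_hsv(frame), hue_center, hue_tol, sat_min, val_min)
    sums = strip_sums(mask)
    return sums, stimulus_from_sums(sums, quantum)


def stimuli_to_csv(records: list[dict], path: str | Path) -> pd.DataFrame:
    """Write per-frame records (frame_index, s0..s4, left3, right3, side, count)."""
    df = pd.DataFrame(
        records,
        columns=["frame_index", "s0", "s1", "s2", "s3", "s4", "left3", "right3", "side", "count"],
    )
    df.to_csv(path, index=False)
    return df


def stimulus_record(frame_index: int, sums: StripSums, stim: StimulusBatch) -> dict:
    s = sums.sums
    return {
        "frame_index": frame_index,
        "s0": s[0], "s1": s[1], "s2": s[2], "s3": s[3], "s4": s[4],
        "left3": sums.left3, "right3": sums.right3,
        "side": stim.side.value, "count": stim.count,
    }
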
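"""Objective image-quality metrics: CNR with the FAZ/corner ROI scheme, and
PSNR against the averaged reference.

CNR uses five circular regions of interest: one background disc placed in
the foveal avascular zone (capillary-free, so its signal is pure noise) and
four foreground discs at the image corners where vasculature is dense:

    CNR = (f - b) / sqrt(df**2 + db**2)

with f, b the mean gray values of the pooled foreground and background
pixels and df, db their standard deviations.

PSNR treats the multi-frame averaged image as the ground truth:

    PSNR(dB) = 10 * log10(MAX_I**2 / MSE),   MAX_I = 255 for 8-bit images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_io import EnFaceImage

__all__ = [
    "CircleRoi",
    "RoiSet",
    "RoiStatistics",
    "PsnrResult",
    "place_cnr_rois",
    "cnr",
    "psnr",
]

DEFAULT_ROI_DIAMETER_PX = 20
DEFAULT_CORNER_INSET_PX = 4


@dataclass(frozen=True)
class CircleRoi:
    """Disc ROI; rasterized as pixels whose centers lie within the radius
    (distance ties included)."""

    center: tuple[float, float]  # (row, col)
    diameter_px: float

    @property
    def radius(self) -> float:
        return self.diameter_px / 2.0

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        d2 = (rr - self.center[0]) ** 2 + (cc - self.center[1]) ** 2
        return d2 <= self.radius**2

    def in_bounds(self, shape: tuple[int, int]) -> bool:
        r, c = self.center
        return (
            r - self.radius >= -0.5
            and c - self.radius >= -0.5
            and r + self.radius <= shape[0] - 0.5
            and c + self.radius <= shape[1] - 0.5
        )


@dataclass
class RoiSet:
    """One background disc (FAZ) and four foreground discs (corners)."""

    background: CircleRoi
    foreground: list[CircleRoi]

    def to_dict(self) -> dict:
        return {
            "background": {"center": list(self.background.center), "diameter_px": self.background.diameter_px},
            "foreground": [
                {"center": list(f.center), "diameter_px": f.diameter_px} for f in self.foreground
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RoiSet":
        return cls(
            background=CircleRoi(tuple(d["background"]["center"]), d["background"]["diameter_px"]),
            foreground=[CircleRoi(tuple(f["center"]), f["diameter_px"]) for f in d["foreground"]],
        )


@dataclass
class RoiStatistics:
    """Pooled foreground / background means and standard deviations."""

    f: float
    b: float
    delta_f: float
    delta_b: float


@dataclass
class PsnrResult:
    mse: float
    max_i: int
    psnr_db: float  # +inf sentinel when mse == 0


def place_cnr_rois(
    image: EnFaceImage,
    faz_center: tuple[float, float] | None = None,
    diameter_px: int = DEFAULT_ROI_DIAMETER_PX,
    corner_inset_px: int = DEFAULT_CORNER_INSET_PX,
) -> RoiSet:
    """Place the background ROI at the FAZ center and four foreground ROIs
    inset from the image corners.

    ``faz_center`` defaults to the geometric image center (the scan is
    centered on the fovea); pass it explicitly for off-center fields.
    """
    h, w = image.pixels.shape
    r = diameter_px / 2.0
    if faz_center is None:
        faz_center = ((h - 1) / 2.0, (w - 1) / 2.0)
    off = corner_inset_px + r
    rois = RoiSet(
        background=CircleRoi(tuple(faz_center), diameter_px),
        foreground=[
            CircleRoi((off, off), diameter_px),
            CircleRoi((off, w - 1 - off), diameter_px),
            CircleRoi((h - 1 - off, off), diameter_px),
            CircleRoi((h - 1 - off, w - 1 - off), diameter_px),
        ],
    )
    for roi in [rois.background, *rois.foreground]:
        if not roi.in_bounds((h, w)):
            raise ValueError(f"ROI at {roi.center} does not fit inside the image")
    return rois


def cnr(image: EnFaceImage, rois: RoiSet) -> tuple[RoiStatistics, float]:
    """Contrast-to-noise ratio between pooled corner discs and the FAZ disc.

    The four foreground discs are pooled into one pixel set.  A constant
    image returns CNR 0; unequal means with zero spread are degenerate.
    """
    px = image.astype_float()
    shape = px.shape
    fg = np.concatenate([px[roi.mask(shape)] for roi in rois.foreground])
    bg = px[rois.background.mask(shape)]
    if fg.size == 0 or bg.size == 0:
        raise ValueError("empty ROI")
    stats = RoiStatistics(
        f=float(fg.mean()), b=float(bg.mean()), delta_f=float(fg.std()), delta_b=float(bg.std())
    )
    denom = math.hypot(stats.delta_f, stats.delta_b)
    if denom == 0.0:
        if stats.f == stats.b:
            return stats, 0.0
        raise ValueError("degenerate ROI statistics: zero spread with unequal means")
    return stats, (stats.f - stats.b) / denom


def psnr(sample: EnFaceImage, reference: EnFaceImage) -> PsnrResult:
    """Peak signal-to-noise ratio of ``sample`` against ``reference`` (dB).

    Identical images give ``mse == 0`` and a ``+inf`` sentinel (never an
    error).  Symmetric in its two arguments.
    """
    if sample.pixels.shape != reference.pixels.shape:
        raise ValueError("sample and reference dimensions differ")
    diff = sample.astype_float() - reference.astype_float()
    mse = float((diff**2).mean())
    if mse == 0.0:
        return PsnrResult(mse=0.0, max_i=255, psnr_db=math.inf)
    return PsnrResult(mse=mse, max_i=255, psnr_db=10.0 * math.log10(255.0**2 / mse))
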
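"""Image containers and raster I/O shared by every stage of the pipeline.

The universal currency is the :class:`EnFaceImage`: a 2-D, 8-bit grayscale
en face angiogram with a physical scale (mm per pixel).  A 3 x 3 mm field
sampled on a 232 x 232 grid — the acquisition geometry this package
emulates — corresponds to ``mm_per_pixel = 3 / 232``.

Conventions fixed for the whole repository: row-major arrays, origin at the
top-left corner, ``(row, col)`` 0-based indexing, pixel centers at integer
coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "LABELS",
    "DEFAULT_MM_PER_PIXEL",
    "EnFaceImage",
    "ImageMeta",
    "read_enface",
    "write_enface",
]

#: Closed set of image provenance labels used throughout the pipeline.
LABELS = frozenset({"original", "averaged", "denoised", "clean"})

#: 3 mm field of view on a 232-pixel grid.
DEFAULT_MM_PER_PIXEL = 3.0 / 232.0

MIN_DIM = 32


@dataclass
class ImageMeta:
    """Sidecar metadata carried alongside an image raster."""

    label: str = "original"
    mm_per_pixel: float = DEFAULT_MM_PER_PIXEL
    seed: int | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(
                f"label {self.label!r} not in {sorted(LABELS)}"
            )


@dataclass
class EnFaceImage:
    """A 2-D 8-bit grayscale en face angiogram with physical scale.

    Parameters
    ----------
    pixels:
        2-D ``uint8`` array, intensities in [0, 255].
    mm_per_pixel:
        Physical pixel pitch; must be positive.
    label:
        One of ``original``, ``averaged``, ``denoised``, ``clean``.
    seed:
        Seed used to synthesize the image, if synthetic.
    provenance:
        Free-form note on how the image was produced.
    """

    pixels: np.ndarray
    mm_per_pixel: float = DEFAULT_MM_PER_PIXEL
    label: str = "original"
    seed: int | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected single-channel 2-D raster, got shape {px.shape}")
        if px.dtype != np.uint8:
            if np.issubdtype(px.dtype, np.integer) or np.issubdtype(px.dtype, np.floating):
                if px.min() < 0 or px.max() > 255:
                    raise ValueError("intensities must lie in [0, 255]")
                px = px.astype(np.uint8)
            else:
                raise ValueError(f"unsupported dtype {px.dtype}")
        if px.shape[0] < MIN_DIM or px.shape[1] < MIN_DIM:
            raise ValueError(f"image dimensions must be >= {MIN_DIM}, got {px.shape}")
        if not (self.mm_per_pixel > 0):
            raise ValueError("mm_per_pixel must be positive")
        if self.label not in LABELS:
            raise ValueError(f"label {self.label!r} not in {sorted(LABELS)}")
        self.pixels = px

    @property
    def height_px(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width_px(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def field_mm(self) -> tuple[float, float]:
        """Physical field extent (height, width) in mm."""
        return (self.height_px * self.mm_per_pixel, self.width_px * self.mm_per_pixel)

    @property
    def meta(self) -> ImageMeta:
        return ImageMeta(
            label=self.label,
            mm_per_pixel=self.mm_per_pixel,
            seed=self.seed,
            provenance=self.provenance,
        )

    def astype_float(self) -> np.ndarray:
        """Return pixels as float64 in [0, 255] (a copy)."""
        return self.pixels.astype(np.float64)

    def replace(self, **kwargs) -> "EnFaceImage":
        """Return a copy with the given fields replaced."""
        fields = dict(
            pixels=self.pixels.copy(),
            mm_per_pixel=self.mm_per_pixel,
            label=self.label,
            seed=self.seed,
            provenance=self.provenance,
        )
        fields.update(kwargs)
        return EnFaceImage(**fields)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_enface(path: str | Path, mm_per_pixel: float | None = None) -> EnFaceImage:
    """Read an 8-bit (or 16-bit, rescaled) grayscale raster as an EnFaceImage.

    16-bit inputs are rescaled so the image maximum maps to 255.  A JSON
    sidecar with the same stem (``img.png`` -> ``img.json``) is merged if
    present; an explicit ``mm_per_pixel`` argument takes precedence over the
    sidecar, which takes precedence over the default scale.

    Raises
    ------
    ValueError
        If the raster is not single-channel.
    """
    path = Path(path)
    raw = iio.imread(path)
    if raw.ndim != 2:
        raise ValueError(
            f"expected single-channel grayscale raster, got shape {raw.shape} "
            "(no silent luminance conversion is performed)"
        )
    if raw.dtype == np.uint8:
        px = raw
    elif raw.dtype == np.uint16:
        mx = int(raw.max())
        if mx == 0:
            px = raw.astype(np.uint8)
        else:
            px = np.rint(raw.astype(np.float64) * (255.0 / mx)).astype(np.uint8)
    else:
        raise ValueError(f"unsupported raster dtype {raw.dtype}")

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())

    scale = mm_per_pixel if mm_per_pixel is not None else meta.get("mm_per_pixel", DEFAULT_MM_PER_PIXEL)
    return EnFaceImage(
        pixels=px,
        mm_per_pixel=float(scale),
        label=meta.get("label", "original"),
        seed=meta.get("seed"),
        provenance=meta.get("provenance", str(path)),
    )


def write_enface(image: EnFaceImage, path: str | Path) -> None:
    """Write an EnFaceImage as a lossless 8-bit PNG plus a JSON sidecar.

    The sidecar records ``mm_per_pixel`` (full precision), ``label``,
    ``seed`` and ``provenance``.  Writing the same image twice produces
    byte-identical files.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    iio.imwrite(path, image.pixels)
    sidecar = {
        "mm_per_pixel": image.mm_per_pixel,
        "label": image.label,
        "seed": image.seed,
        "provenance": image.provenance,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True) + "\n")
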
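"""Frame registration and multi-frame averaging.

Repeated acquisitions of the same field are aligned to the first frame by
exhaustive integer-translation search maximizing the normalized
cross-correlation over the overlap, then averaged per pixel over the frames
available at that pixel.  The averaged image serves downstream both as the
denoiser's teacher and as the reference ("ground truth") for PSNR.

Frames whose registration peak correlation falls below a threshold are
excluded from the average — modelling acquisitions that fail to register
because of poor fixation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import EnFaceImage
from .synthdata import FrameStack

__all__ = ["RegistrationResult", "RegistrationError", "register_frames", "average_frames"]

DEFAULT_MAX_SHIFT = 10
DEFAULT_EXCLUSION_THRESHOLD = 0.2


class RegistrationError(RuntimeError):
    pass


@dataclass
class RegistrationResult:
    """Integer alignment of each frame to frame 0.

    ``offsets[i]`` is the translation to apply to frame ``i`` so it
    re-aligns with frame 0 (so a frame whose scene moved by ``(+3, -2)``
    gets offset ``(-3, +2)``).
    """

    offsets: list[tuple[int, int]]
    peak_correlation: list[float]
    excluded_frames: list[int]

    def __post_init__(self) -> None:
        if self.offsets and self.offsets[0] != (0, 0):
            raise ValueError("frame 0 is the reference; its offset must be (0, 0)")

    def included(self, n_frames: int) -> list[int]:
        return [i for i in range(n_frames) if i not in set(self.excluded_frames)]


def _as_frames(stack: FrameStack | list[EnFaceImage]) -> list[EnFaceImage]:
    return list(stack.frames) if isinstance(stack, FrameStack) else list(stack)


def _ncc_at_shift(ref: np.ndarray, img: np.ndarray, dr: int, dc: int) -> float:
    """Pearson correlation between ref and img translated by (dr, dc),
    computed over the overlap region only."""
    h, w = ref.shape
    r0, r1 = max(0, dr), min(h, h + dr)
    c0, c1 = max(0, dc), min(w, w + dc)
    if r1 - r0 < 8 or c1 - c0 < 8:
        return -1.0
    a = ref[r0:r1, c0:c1]
    b = img[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        # both patches constant -> perfectly aligned by convention
        return 1.0 if np.allclose(a, b) else 0.0
    return float((a * b).sum() / denom)


def register_frames(
    stack: FrameStack | list[EnFaceImage],
    max_shift: int = DEFAULT_MAX_SHIFT,
    exclusion_threshold: float = DEFAULT_EXCLUSION_THRESHOLD,
) -> RegistrationResult:
    """Register every frame to frame 0 by exhaustive integer search.

    For each frame the translation within ``±max_shift`` maximizing the
    normalized cross-correlation with frame 0 is selected.  Frames whose
    peak correlation is below ``exclusion_threshold`` are flagged excluded.

    Raises
    ------
    RegistrationError
        If every non-reference frame is excluded.
    """
    frames = _as_frames(stack)
    if len(frames) < 2:
        raise ValueError("registration needs at least 2 frames")
    shape = frames[0].pixels.shape
    if any(f.pixels.shape != shape for f in frames):
        raise ValueError("all frames must share dimensions")

    ref = frames[0].astype_float()
    offsets: list[tuple[int, int]] = [(0, 0)]
    peaks: list[float] = [1.0]
    excluded: list[int] = []

    shifts = range(-max_shift, max_shift + 1)
    for i, frame in enumerate(frames[1:], start=1):
        img = frame.astype_float()
        best = (-2.0, (0, 0))
        for dr in shifts:
            for dc in shifts:
                c = _ncc_at_shift(ref, img, dr, dc)
                if c > best[0]:
                    best = (c, (dr, dc))
        peaks.append(best[0])
        offsets.append(best[1])
        if best[0] < exclusion_threshold:
            excluded.append(i)

    if len(excluded) == len(frames) - 1:
        raise RegistrationError("registration failed: all frames excluded")
    return RegistrationResult(offsets=offsets, peak_correlation=peaks, excluded_frames=excluded)


def average_frames(
    stack: FrameStack | list[EnFaceImage], reg: RegistrationResult | None = None
) -> EnFaceImage:
    """Arithmetic mean of the re-aligned, non-excluded frames.

    At pixels where a translated frame has no data (near borders) the mean
    is taken over the frames that do cover the pixel, so the output keeps
    the full input dimensions — required for pixelwise PSNR against it.
    """
    frames = _as_frames(stack)
    if reg is None:
        reg = RegistrationResult(
            offsets=[(0, 0)] * len(frames),
            peak_correlation=[1.0] * len(frames),
            excluded_frames=[],
        )
    include = reg.included(len(frames))
    if not include:
        raise ValueError("no non-excluded frames to average")

    h, w = frames[0].pixels.shape
    acc = np.zeros((h, w), dtype=np.float64)
    cnt = np.zeros((h, w), dtype=np.float64)
    for i in include:
        dr, dc = reg.offsets[i]
        r0, r1 = max(0, dr), min(h, h + dr)
        c0, c1 = max(0, dc), min(w, w + dc)
        acc[r0:r1, c0:c1] += frames[i].pixels[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
        cnt[r0:r1, c0:c1] += 1.0
    mean = np.where(cnt > 0, acc / np.maximum(cnt, 1.0), 0.0)
    px = np.rint(mean).astype(np.uint8)
    return EnFaceImage(
        pixels=px,
        mm_per_pixel=frames[0].mm_per_pixel,
        label="averaged",
        seed=getattr(stack, "seed", None) if isinstance(stack, FrameStack) else None,
        provenance=f"average of {len(include)} frames",
    )
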
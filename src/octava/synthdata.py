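"""Synthetic en face angiogram simulator.

Generates complete synthetic "eyes": a ground-truth branching vascular
network with a central foveal avascular zone (FAZ), a clean noiseless
render, and a stack of repeated noisy acquisitions of the same field.
The degradations emulate what single-shot OCT angiography frames show in
practice:

* multiplicative speckle on the flow signal (gamma, mean 1),
* an additive background noise floor that dominates avascular regions,
* per-segment flow-decorrelation dropout gaps along vessels,
* small integer inter-frame translations from imperfect fixation,
* optional focal signal attenuation ("shadow", e.g. media opacity) and a
  bright motion-line row.

Every operation is a pure function of its inputs and seed, so the whole
module is reproducible and, with noise disabled, collapses to an identity
pipeline around :func:`render_clean`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

from .core_io import DEFAULT_MM_PER_PIXEL, EnFaceImage

__all__ = [
    "Segment",
    "VesselTruth",
    "Shadow",
    "MotionLine",
    "NoiseParams",
    "FrameStack",
    "generate_vessel_truth",
    "render_clean",
    "simulate_single_shot",
    "simulate_eye",
]


@dataclass
class Segment:
    """One vessel centerline: an (n, 2) float array of (row, col) points in
    pixel units with a per-point radius profile in pixels."""

    points: np.ndarray
    radii: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        self.radii = np.asarray(self.radii, dtype=np.float64).reshape(-1)
        if len(self.points) != len(self.radii):
            raise ValueError("points and radii must have equal length")
        if len(self.radii) and self.radii.min() <= 0:
            raise ValueError("all radii must be positive")


@dataclass
class VesselTruth:
    """Ground-truth vasculature for one synthetic eye."""

    segments: list[Segment]
    faz_center: tuple[float, float]
    faz_radius_px: float
    field_px: int
    mm_per_pixel: float = DEFAULT_MM_PER_PIXEL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.faz_radius_px < 0:
            raise ValueError("faz_radius_px must be nonnegative")
        c = np.asarray(self.faz_center, dtype=np.float64)
        for seg in self.segments:
            if len(seg.points) == 0:
                continue
            d = np.hypot(*(seg.points - c).T)
            if d.min() < self.faz_radius_px:
                raise ValueError("centerline point inside the FAZ disc")
            if seg.points.min() < 0 or seg.points.max() > self.field_px - 1:
                raise ValueError("centerline point outside field bounds")

    def faz_mask(self) -> np.ndarray:
        """Boolean mask of pixels whose centers lie inside the FAZ disc."""
        rr, cc = np.mgrid[0 : self.field_px, 0 : self.field_px]
        return (rr - self.faz_center[0]) ** 2 + (cc - self.faz_center[1]) ** 2 <= self.faz_radius_px**2

    def all_points(self) -> np.ndarray:
        if not self.segments:
            return np.empty((0, 2))
        return np.concatenate([s.points for s in self.segments], axis=0)


@dataclass
class Shadow:
    """Focal signal attenuation: intensities inside the disc are multiplied
    by ``attenuation`` (0 = fully dark, 1 = no effect)."""

    center: tuple[float, float]
    radius_px: float
    attenuation: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.attenuation <= 1.0):
            raise ValueError("attenuation must lie in [0, 1]")


@dataclass
class MotionLine:
    """One saturated row emulating a horizontal motion artifact."""

    row: int
    gain: float = 2.0


@dataclass
class NoiseParams:
    """Per-frame degradation model.

    speckle_shape:
        Shape of the mean-1 multiplicative gamma speckle; larger means less
        speckle.  ``None`` (or ``inf``) disables speckle.
    background_level:
        Scale of the additive folded-normal noise floor as a fraction of the
        8-bit range; dominates avascular areas.
    grain_px:
        Correlation length of the speckle and background noise fields in
        pixels (0 = independent per pixel).  Coherent-imaging speckle has a
        finite grain, which is what lets noise specks survive median
        prefiltering and binarize as false flow in single shots.
    dropout_prob:
        Per-segment probability of a local flow-decorrelation gap.
    jitter_max_px:
        Bound on the uniform integer inter-frame translation.
    """

    speckle_shape: float | None = 3.0
    background_level: float = 0.32
    grain_px: float = 0.8
    dropout_prob: float = 0.25
    jitter_max_px: int = 3
    shadow: Shadow | None = None
    motion_line: MotionLine | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_prob <= 1.0):
            raise ValueError("dropout_prob must lie in [0, 1]")
        if not (0.0 <= self.background_level <= 1.0):
            raise ValueError("background_level must lie in [0, 1]")
        if self.jitter_max_px < 0:
            raise ValueError("jitter_max_px must be nonnegative")

    @property
    def speckle_enabled(self) -> bool:
        return self.speckle_shape is not None and math.isfinite(self.speckle_shape)

    @classmethod
    def noiseless(cls) -> "NoiseParams":
        return cls(speckle_shape=None, background_level=0.0, dropout_prob=0.0, jitter_max_px=0)


@dataclass
class FrameStack:
    """Repeated acquisitions of one synthetic eye.

    ``frames[0]`` is by convention the "original" single-shot image; its
    true offset is forced to (0, 0).
    """

    frames: list[EnFaceImage]
    true_offsets: list[tuple[int, int]]
    clean: EnFaceImage
    truth: VesselTruth
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("a FrameStack needs at least one frame")
        if len(self.frames) != len(self.true_offsets):
            raise ValueError("frames and true_offsets lengths differ")

    @property
    def original(self) -> EnFaceImage:
        return self.frames[0]

    @property
    def n_frames(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# ground-truth vasculature


def _rot(v: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def generate_vessel_truth(
    field_px: int = 232,
    mm_per_pixel: float = DEFAULT_MM_PER_PIXEL,
    n_trees: int = 14,
    branch_prob: float = 0.045,
    turn_sigma: float = 0.16,
    faz_radius_mm: float = 0.25,
    root_radius_px: float = 2.6,
    min_radius_px: float = 0.7,
    seed: int = 0,
) -> VesselTruth:
    """Grow stochastic branching vessel trees inward from the field edges.

    Trees start at jittered positions on the field perimeter, random-walk
    toward the FAZ boundary with gentle direction noise, taper along their
    length, and occasionally spawn thinner side branches.  No centerline
    point enters the FAZ disc.  Deterministic for a fixed seed.
    """
    if field_px < 64:
        raise ValueError("field_px must be >= 64")
    if faz_radius_mm < 0:
        raise ValueError("faz_radius_mm must be nonnegative")
    if root_radius_px < 0.5 or min_radius_px < 0.5:
        raise ValueError("vessel radii below 0.5 px cannot be rendered")

    rng = np.random.default_rng(seed)
    center = np.array([(field_px - 1) / 2.0, (field_px - 1) / 2.0])
    faz_radius_px = faz_radius_mm / mm_per_pixel
    lo, hi = 0.0, float(field_px - 1)

    segments: list[Segment] = []
    # (start point, direction, radius, depth) work queue
    queue: list[tuple[np.ndarray, np.ndarray, float, int]] = []

    for t in range(n_trees):
        # evenly spaced perimeter parameter with jitter
        u = (t + rng.uniform(0.1, 0.9)) / max(n_trees, 1)
        p = 4.0 * u  # perimeter position in [0, 4)
        if p < 1:
            start = np.array([lo, p * hi])
        elif p < 2:
            start = np.array([(p - 1) * hi, hi])
        elif p < 3:
            start = np.array([hi, (3 - p) * hi])
        else:
            start = np.array([(4 - p) * hi, lo])
        d = center - start
        d = d / np.linalg.norm(d)
        d = _rot(d, rng.normal(0.0, 0.35))
        queue.append((start, d, root_radius_px, 0))

    max_depth = 3
    step = 1.0
    while queue:
        pos, d, radius, depth = queue.pop()
        pts: list[np.ndarray] = []
        radii: list[float] = []
        max_len = int(rng.integers(40, 2 * field_px))
        for _ in range(max_len):
            if radius < min_radius_px:
                break
            if not (lo <= pos[0] <= hi and lo <= pos[1] <= hi):
                break
            if np.linalg.norm(pos - center) < faz_radius_px + 1.0:
                break  # stop at the FAZ boundary: the disc stays capillary-free
            pts.append(pos.copy())
            radii.append(radius)
            # curve toward the fovea with direction noise
            to_center = center - pos
            to_center /= max(np.linalg.norm(to_center), 1e-9)
            d = d + 0.04 * to_center
            d /= np.linalg.norm(d)
            d = _rot(d, rng.normal(0.0, turn_sigma))
            pos = pos + step * d
            radius *= 0.9975
            if depth < max_depth and rng.random() < branch_prob and radius > 1.3 * min_radius_px:
                side = 1.0 if rng.random() < 0.5 else -1.0
                child_dir = _rot(d, side * rng.uniform(0.5, 1.1))
                queue.append((pos.copy(), child_dir, radius * rng.uniform(0.55, 0.75), depth + 1))
                radius *= 0.88  # parent thins past the bifurcation
        if len(pts) >= 2:
            segments.append(Segment(np.array(pts), np.array(radii)))

    return VesselTruth(
        segments=segments,
        faz_center=(float(center[0]), float(center[1])),
        faz_radius_px=float(faz_radius_px),
        field_px=field_px,
        mm_per_pixel=mm_per_pixel,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# rendering


def _stamp_discs(
    canvas: np.ndarray,
    points: np.ndarray,
    radii: np.ndarray,
    value: float,
) -> None:
    """Max-composite anti-aliased discs onto ``canvas`` in place.

    The disc edge is feathered over one pixel: coverage = clip(r + 0.5 - d).
    """
    h, w = canvas.shape
    for (r0, c0), rad in zip(points, radii):
        r_lo = max(int(math.floor(r0 - rad - 1)), 0)
        r_hi = min(int(math.ceil(r0 + rad + 1)) + 1, h)
        c_lo = max(int(math.floor(c0 - rad - 1)), 0)
        c_hi = min(int(math.ceil(c0 + rad + 1)) + 1, w)
        if r_lo >= r_hi or c_lo >= c_hi:
            continue
        rr = np.arange(r_lo, r_hi)[:, None] - r0
        cc = np.arange(c_lo, c_hi)[None, :] - c0
        d = np.sqrt(rr * rr + cc * cc)
        cov = np.clip(rad + 0.5 - d, 0.0, 1.0)
        window = canvas[r_lo:r_hi, c_lo:c_hi]
        np.maximum(window, value * cov, out=window)


def render_clean(
    truth: VesselTruth,
    vessel_intensity: float = 0.85,
    bed_intensity: float = 0.12,
) -> EnFaceImage:
    """Render the noiseless en face image of a ground-truth vasculature.

    Vessels are drawn as anti-aliased discs stamped along each centerline at
    its local radius.  Outside the FAZ a faint diffuse capillary-bed texture
    at ``bed_intensity`` stands in for capillaries below the resolved scale.
    The FAZ interior is exactly zero before noise.
    """
    if not (0.0 < vessel_intensity <= 1.0):
        raise ValueError("vessel_intensity must lie in (0, 1]")
    if not (0.0 <= bed_intensity < vessel_intensity):
        raise ValueError("bed_intensity must lie in [0, vessel_intensity)")

    n = truth.field_px
    canvas = np.zeros((n, n), dtype=np.float64)
    for seg in truth.segments:
        _stamp_discs(canvas, seg.points, seg.radii, vessel_intensity)

    if bed_intensity > 0:
        rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 0xBED]))
        tex = ndi.gaussian_filter(rng.standard_normal((n, n)), sigma=1.2)
        tex = (tex - tex.min()) / max(tex.max() - tex.min(), 1e-12)
        bed = bed_intensity * (0.35 + 0.65 * tex)
        canvas = np.maximum(canvas, bed)

    canvas[truth.faz_mask()] = 0.0
    px = np.rint(np.clip(canvas, 0.0, 1.0) * 255.0).astype(np.uint8)
    return EnFaceImage(
        pixels=px,
        mm_per_pixel=truth.mm_per_pixel,
        label="clean",
        seed=truth.seed,
        provenance="render_clean",
    )


# ---------------------------------------------------------------------------
# noise


def _dropout_mask(
    truth: VesselTruth, dropout_prob: float, rng: np.random.Generator, shape: tuple[int, int]
) -> np.ndarray:
    """Multiplicative attenuation field for flow-decorrelation gaps.

    Each segment independently suffers a gap with probability
    ``dropout_prob``; the gap is a geometric-length run of centerline points
    whose local discs are attenuated to near zero.
    """
    att = np.ones(shape, dtype=np.float64)
    gap = np.zeros(shape, dtype=np.float64)
    for seg in truth.segments:
        if rng.random() >= dropout_prob or len(seg.points) < 4:
            continue
        n = len(seg.points)
        start = int(rng.integers(0, n))
        length = 1 + int(rng.geometric(0.12))
        stop = min(start + length, n)
        _stamp_discs(gap, seg.points[start:stop], seg.radii[start:stop] + 0.8, 1.0)
    att -= 0.92 * gap
    return att


def simulate_single_shot(
    clean: EnFaceImage,
    noise: NoiseParams,
    seed: int,
    truth: VesselTruth | None = None,
    offset: tuple[int, int] = (0, 0),
) -> EnFaceImage:
    """Degrade a clean render into one single-shot acquisition.

    Applied in order: per-segment dropout gaps (needs ``truth``), scene
    translation by ``offset`` (zero fill), multiplicative gamma speckle on
    the signal, additive folded-normal background noise, optional shadow
    attenuation and motion-line gain; then clip and quantize to 8 bits.
    Deterministic for a fixed seed.
    """
    if clean.label != "clean":
        raise ValueError("simulate_single_shot expects a clean render")
    rng = np.random.default_rng(seed)
    sig = clean.astype_float()

    if truth is not None and noise.dropout_prob > 0:
        sig *= _dropout_mask(truth, noise.dropout_prob, rng, sig.shape)

    if offset != (0, 0):
        sig = ndi.shift(sig, offset, order=0, mode="constant", cval=0.0)

    if noise.speckle_enabled:
        k = float(noise.speckle_shape)
        speck = rng.gamma(shape=k, scale=1.0 / k, size=sig.shape)
        if noise.grain_px > 0:
            # correlate the grain, then restore the mean-1 / original-spread stats
            sm = ndi.gaussian_filter(speck, noise.grain_px)
            sd = sm.std()
            if sd > 0:
                sm = 1.0 + (sm - sm.mean()) * (speck.std() / sd)
            speck = np.clip(sm, 0.0, None)
        sig *= speck

    if noise.background_level > 0:
        bg = np.abs(rng.normal(0.0, noise.background_level * 255.0, size=sig.shape))
        if noise.grain_px > 0:
            sm = ndi.gaussian_filter(bg, noise.grain_px)
            sd = sm.std()
            if sd > 0:
                bg = np.clip(sm.mean() + (sm - sm.mean()) * (bg.std() / sd), 0.0, None)
            else:
                bg = sm
        sig += bg

    if noise.shadow is not None:
        sh = noise.shadow
        rr, cc = np.mgrid[0 : sig.shape[0], 0 : sig.shape[1]]
        inside = (rr - sh.center[0]) ** 2 + (cc - sh.center[1]) ** 2 <= sh.radius_px**2
        sig[inside] *= sh.attenuation

    if noise.motion_line is not None:
        ml = noise.motion_line
        if 0 <= ml.row < sig.shape[0]:
            sig[ml.row, :] *= ml.gain

    px = np.rint(np.clip(sig, 0.0, 255.0)).astype(np.uint8)
    return EnFaceImage(
        pixels=px,
        mm_per_pixel=clean.mm_per_pixel,
        label="original",
        seed=seed,
        provenance="simulate_single_shot",
    )


def simulate_eye(
    noise: NoiseParams | None = None,
    n_frames: int = 10,
    seed: int = 0,
    field_px: int = 232,
    mm_per_pixel: float = DEFAULT_MM_PER_PIXEL,
    vessel_intensity: float = 0.85,
    bed_intensity: float = 0.12,
    **truth_kwargs,
) -> FrameStack:
    """Simulate one eye: ground truth, clean render, and ``n_frames`` noisy
    repeated acquisitions with independent noise and integer jitter.

    Frame 0 is the "original" and its offset is forced to (0, 0); the other
    frames are translated by integers drawn uniformly from
    ``[-jitter_max_px, +jitter_max_px]^2``, recorded in ``true_offsets``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    noise = noise if noise is not None else NoiseParams()
    if noise.jitter_max_px >= field_px / 4:
        raise ValueError("jitter_max_px >= field_px/4: unregisterable by design")

    ss = np.random.SeedSequence(seed)
    truth_seed, jitter_seed, *frame_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 + n_frames)
    ]
    truth = generate_vessel_truth(
        field_px=field_px, mm_per_pixel=mm_per_pixel, seed=truth_seed, **truth_kwargs
    )
    clean = render_clean(truth, vessel_intensity=vessel_intensity, bed_intensity=bed_intensity)

    jrng = np.random.default_rng(jitter_seed)
    j = noise.jitter_max_px
    offsets: list[tuple[int, int]] = [(0, 0)]
    for _ in range(1, n_frames):
        offsets.append((int(jrng.integers(-j, j + 1)), int(jrng.integers(-j, j + 1))))

    frames = [
        simulate_single_shot(clean, noise, frame_seeds[i], truth=truth, offset=offsets[i])
        for i in range(n_frames)
    ]
    return FrameStack(frames=frames, true_offsets=offsets, clean=clean, truth=truth, seed=seed)
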
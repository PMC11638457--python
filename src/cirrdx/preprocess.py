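"""Turn a registered, masked multi-sequence study into the CNN slice stack.

Steps: rigid co-registration (classical NCC grid search), selection of the
five axial slices around the largest liver cross-section, percentile clipping,
square zero-padding, resizing, joint min-max normalization, and the online
training augmentations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .errors import DegenerateInputError, DomainError

log = logging.getLogger(__name__)

__all__ = [
    "MriStudy",
    "SlicePack",
    "RigidTransform",
    "AugmentConfig",
    "register_rigid",
    "apply_rigid",
    "select_slices",
    "preprocess_stack",
    "augment",
]

F32 = np.float32


# ---------------------------------------------------------------- containers


@dataclass
class MriStudy:
    """Multi-sequence 3-D study with a shared binary liver mask.

    Volumes are (z, y, x); axial slices index the first axis (0-based).
    """

    sequences: dict[str, np.ndarray]
    mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    case_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        shapes = {v.shape for v in self.sequences.values()} | {self.mask.shape}
        if len(shapes) != 1:
            raise DomainError("all volumes and the mask must share one shape")
        if not self.mask.any():
            raise DomainError("liver mask is empty")
        for name, vol in self.sequences.items():
            if not np.isfinite(vol).all():
                raise DomainError(f"sequence {name!r} contains non-finite values")


@dataclass
class SlicePack:
    """Model-ready stack: channels are sequence-major, slice-minor,
    image-then-mask; values in [0, 1], masks exactly {0, 1}."""

    slices: np.ndarray  # (C, H, W) float32
    slice_indices: list[int]
    size: int
    norm_bounds: dict[str, tuple[float, float]]
    sequences: list[str]
    case_id: str = ""

    @property
    def n_channels(self) -> int:
        return self.slices.shape[0]


@dataclass(frozen=True)
class RigidTransform:
    """Displacement of the moving volume relative to the fixed one:
    the moving content sits at +translation; realignment shifts by
    -translation and -rotation."""

    translation: tuple[float, float, float]  # voxels (z, y, x)
    rotation: float = 0.0  # degrees about the axial (z) axis

    def __post_init__(self):
        if not np.isfinite(self.translation).all() or not np.isfinite(self.rotation):
            raise DomainError("transform must be finite")
        if abs(self.rotation) > 30:
            raise DomainError("|rotation| must be <= 30 degrees")


@dataclass
class AugmentConfig:
    rotate_deg: tuple[float, float] = (-10.0, 10.0)
    zoom: tuple[float, float] = (0.9, 1.1)
    contrast_gamma: tuple[float, float] = (0.8, 1.25)
    noise_sd: float = 0.01
    elastic_alpha: float = 8.0
    elastic_sigma: float = 4.0
    apply_prob: float = 0.5
    enabled: bool = True

    def __post_init__(self):
        for name in ("rotate_deg", "zoom", "contrast_gamma"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise DomainError(f"{name} range is not well-ordered")
        if not 0.0 <= self.apply_prob <= 1.0:
            raise DomainError("apply_prob must be in [0, 1]")


# -------------------------------------------------------------- registration


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel().astype(np.float64)
    b = b.ravel().astype(np.float64)
    a -= a.mean()
    b -= b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    return float(a @ b / denom) if denom > 0 else 0.0


def _int_shift(vol: np.ndarray, shift: tuple[int, int, int]) -> np.ndarray:
    """Shift by integer voxels, zero fill (content moves by +shift)."""
    out = np.zeros_like(vol)
    src, dst = [], []
    for s, n in zip(shift, vol.shape):
        if abs(s) >= n:
            return out
        src.append(slice(max(0, -s), n - max(0, s)))
        dst.append(slice(max(0, s), n - max(0, -s)))
    out[tuple(dst)] = vol[tuple(src)]
    return out


def _rotate_axial(vol: np.ndarray, degrees: float, order: int) -> np.ndarray:
    if degrees == 0.0:
        return vol
    return ndimage.rotate(vol, degrees, axes=(1, 2), reshape=False, order=order,
                          mode="constant", cval=0.0)


def apply_rigid(vol: np.ndarray, transform: RigidTransform, order: int = 1) -> np.ndarray:
    """Resample ``vol`` into the fixed frame (undo the recovered motion).

    ``order=1`` for images, ``order=0`` for masks.
    """
    out = _rotate_axial(vol, -transform.rotation, order)
    t = transform.translation
    if all(float(v).is_integer() for v in t):
        return _int_shift(out, tuple(-int(v) for v in t))
    return ndimage.shift(out, [-v for v in t], order=order, mode="constant", cval=0.0)


def register_rigid(moving: np.ndarray, fixed: np.ndarray, max_shift: int = 3,
                   rotations=(0.0,)) -> tuple[RigidTransform, np.ndarray]:
    """Recover the rigid motion of ``moving`` relative to ``fixed`` by
    maximizing NCC over a coarse-to-fine grid of integer translations
    (within +/- ``max_shift`` voxels) and axial rotations.

    Returns the transform and the realigned moving volume (linear
    interpolation; use :func:`apply_rigid` with ``order=0`` for masks).
    """
    if moving.shape != fixed.shape:
        raise DomainError("moving and fixed volumes must share a shape")
    if np.ptp(moving) == 0 or np.ptp(fixed) == 0:
        raise DegenerateInputError("cannot register an all-constant volume")

    def search(mov, fix, candidates):
        best = (-np.inf, (0, 0, 0))
        for t in candidates:
            score = _ncc(_int_shift(mov, tuple(-v for v in t)), fix)
            if score > best[0]:
                best = (score, t)
        return best

    best_overall = (-np.inf, (0, 0, 0), 0.0)
    for rot in rotations:
        mov = _rotate_axial(moving, -rot, order=1) if rot else moving
        # coarse pass on a 2x-decimated grid
        coarse_mov, coarse_fix = mov[:, ::2, ::2], fixed[:, ::2, ::2]
        rng_z = range(-max_shift, max_shift + 1)
        rng_c = range(-((max_shift + 1) // 2), (max_shift + 1) // 2 + 1)
        coarse_cands = [(z, y, x) for z in rng_z for y in rng_c for x in rng_c]
        _, (cz, cy, cx) = search(coarse_mov, coarse_fix, coarse_cands)
        # refine at full resolution around the upscaled coarse optimum
        cands = set()
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1, -2, 2):
                for dx in (-1, 0, 1, -2, 2):
                    t = (cz + dz, 2 * cy + dy, 2 * cx + dx)
                    if all(abs(v) <= max_shift for v in t):
                        cands.add(t)
        cands.add((0, 0, 0))  # the argmax always includes the identity
        score, t = search(mov, fixed, sorted(cands))
        if score > best_overall[0]:
            best_overall = (score, t, rot)
    score, t, rot = best_overall
    transform = RigidTransform(translation=tuple(float(v) for v in t), rotation=float(rot))
    resampled = apply_rigid(moving, transform, order=1)
    return transform, resampled


# ------------------------------------------------------------ slice selection


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def select_slices(mask: np.ndarray) -> list[int]:
    """Five axial slice indices: the largest-liver-area slice c plus offsets
    at 15% and 25% of the number N of liver-bearing slices on each side,
    clamped to the liver slice range; ties in area break to the lower index.

    Clamping duplicates are shifted inward (toward c) by single steps until
    distinct; if fewer than 5 liver slices exist, repeats remain and a
    warning is logged.
    """
    if not mask.any():
        raise DomainError("mask is empty")
    areas = mask.reshape(mask.shape[0], -1).sum(axis=1)
    nz = np.flatnonzero(areas)
    n = nz.size
    lo, hi = int(nz[0]), int(nz[-1])
    c = int(np.argmax(areas))  # first maximum = lower index on ties
    d15 = _round_half_up(0.15 * n)
    d25 = _round_half_up(0.25 * n)
    desired = [c - d25, c - d15, c, c + d15, c + d25]
    clamped = [min(max(v, lo), hi) for v in desired]
    if hi - lo + 1 < 5:
        if len(set(clamped)) < 5:
            msg = f"only {hi - lo + 1} liver slices; selected indices repeat"
            log.warning(msg)
            warnings.warn(msg)
        return clamped
    # resolve duplicates: greedy inward shift preserving ascending order
    out: list[int] = []
    for i, v in enumerate(clamped):
        floor_i = (out[-1] + 1) if out else lo
        ceil_i = hi - (4 - i)
        out.append(min(max(v, floor_i), ceil_i))
    return out


# ---------------------------------------------------------------- slice pack


def _pad_square(img: np.ndarray) -> np.ndarray:
    h, w = img.shape
    if h == w:
        return img
    d = abs(h - w)
    before, after = d // 2, d - d // 2
    pad = ((before, after), (0, 0)) if h < w else ((0, 0), (before, after))
    return np.pad(img, pad, constant_values=0)


def _resize(img: np.ndarray, size: int, order: int) -> np.ndarray:
    return _sk_resize(img.astype(np.float64), (size, size), order=order,
                      preserve_range=True, anti_aliasing=False)


def preprocess_stack(study: MriStudy, indices: list[int] | None = None,
                     size: int = 512, sequences: tuple[str, ...] | None = None) -> SlicePack:
    """Build the normalized (C, size, size) stack for one study.

    Per sequence: clip at the volume-wise 99.9th percentile, extract the 5
    slices and their masks, zero-pad to square, resize (linear for images,
    nearest for masks) and min-max normalize the 5-slice image group jointly.
    """
    if sequences is None:
        sequences = tuple(study.sequences)
    if indices is None:
        indices = select_slices(study.mask)
    nz = study.mask.shape[0]
    if any(i < 0 or i >= nz for i in indices):
        raise DomainError(f"slice indices {indices} outside volume with {nz} slices")
    channels: list[np.ndarray] = []
    norm_bounds: dict[str, tuple[float, float]] = {}
    for seq in sequences:
        vol = study.sequences[seq].astype(np.float64)
        clip = np.percentile(vol, 99.9)
        vol = np.minimum(vol, clip)
        imgs = [_resize(_pad_square(vol[i]), size, order=1) for i in indices]
        masks = [_resize(_pad_square(study.mask[i].astype(np.float64)), size, order=0)
                 for i in indices]
        group = np.stack(imgs)
        mn, mx = float(group.min()), float(group.max())
        if mx == mn:
            warnings.warn(f"sequence {seq!r}: constant image group, normalized to zeros")
            group = np.zeros_like(group)
        else:
            group = (group - mn) / (mx - mn)
        norm_bounds[seq] = (mn, mx)
        for img, msk in zip(group, masks):
            channels.append(img)
            channels.append((msk > 0.5).astype(np.float64))
    return SlicePack(
        slices=np.stack(channels).astype(F32),
        slice_indices=list(indices),
        size=size,
        norm_bounds=norm_bounds,
        sequences=list(sequences),
        case_id=study.case_id,
    )


# -------------------------------------------------------------- augmentation


def _zoom_2d(img: np.ndarray, factor: float, order: int) -> np.ndarray:
    """Zoom about the image center, keeping the shape."""
    h, w = img.shape
    mat = np.array([[1.0 / factor, 0.0], [0.0, 1.0 / factor]])
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = center - mat @ center
    return ndimage.affine_transform(img, mat, offset=offset, order=order,
                                    mode="constant", cval=0.0)


def _elastic_fields(shape, alpha, sigma, rng):
    dy = ndimage.gaussian_filter(rng.uniform(-1, 1, shape), sigma) * alpha
    dx = ndimage.gaussian_filter(rng.uniform(-1, 1, shape), sigma) * alpha
    yy, xx = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return yy + dy, xx + dx


def augment(pack: SlicePack, cfg: AugmentConfig, rng: np.random.Generator) -> SlicePack:
    """Stochastic training-time augmentation.

    Geometric parameters are drawn once per slice position and shared across
    all sequences and the matching mask channel (masks warped with nearest
    neighbor and re-binarized); photometric transforms touch images only.
    Output is clipped back to [0, 1].  Never applied at inference.
    """
    if not cfg.enabled:
        return pack
    n_seq = len(pack.sequences)
    n_slices = len(pack.slice_indices)
    out = pack.slices.copy()

    for s in range(n_slices):
        do_rot = rng.random() < cfg.apply_prob
        do_zoom = rng.random() < cfg.apply_prob
        do_elastic = rng.random() < cfg.apply_prob
        angle = rng.uniform(*cfg.rotate_deg)
        factor = rng.uniform(*cfg.zoom)
        coords = (_elastic_fields((pack.size, pack.size), cfg.elastic_alpha,
                                  cfg.elastic_sigma, rng) if do_elastic else None)
        for q in range(n_seq):
            ci = (q * n_slices + s) * 2  # image channel; ci+1 is its mask
            for ch, order in ((ci, 1), (ci + 1, 0)):
                img = out[ch].astype(np.float64)
                if do_rot:
                    img = ndimage.rotate(img, angle, reshape=False, order=order,
                                         mode="constant", cval=0.0)
                if do_zoom:
                    img = _zoom_2d(img, factor, order)
                if coords is not None:
                    img = ndimage.map_coordinates(img, coords, order=order,
                                                  mode="constant", cval=0.0)
                out[ch] = img.astype(F32)
        for q in range(n_seq):
            ci = (q * n_slices + s) * 2
            if rng.random() < cfg.apply_prob:  # contrast (per sequence-slice image)
                gamma = rng.uniform(*cfg.contrast_gamma)
                out[ci] = np.power(np.clip(out[ci], 0, 1), gamma, dtype=F32)
            if cfg.noise_sd > 0 and rng.random() < cfg.apply_prob:
                out[ci] = out[ci] + rng.normal(0, cfg.noise_sd, out[ci].shape).astype(F32)

    out = np.clip(out, 0.0, 1.0)
    for q in range(n_seq):
        for s in range(n_slices):
            mi = (q * n_slices + s) * 2 + 1
            out[mi] = (out[mi] > 0.5).astype(F32)
    return SlicePack(out, list(pack.slice_indices), pack.size,
                     dict(pack.norm_bounds), list(pack.sequences), pack.case_id)
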
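"""Stimulus ensembles for BCM learning experiments.

Four generators are provided:

* a two-pattern ensemble of mirrored unit vectors parametrized by the
  angle ``phi`` (the workhorse of the two-input analysis),
* circulant triangular and von Mises tuning-curve ensembles for the
  many-input receptive-field experiments,
* a natural-image stand-in (1/f-spectrum noise images) together with a
  retina-like Difference-of-Gaussians patch pipeline.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
from scipy import ndimage


class StimulusKind(str, Enum):
    PAIR2D = "pair2d"
    TRIANGULAR = "triangular"
    VON_MISES = "von_mises"
    IMAGE_PATCHES = "image_patches"


@dataclass(frozen=True)
class StimulusEnsemble:
    """A set of K input patterns over N synapses.

    ``patterns`` is the K x N matrix X whose rows are the input firing-rate
    vectors x^(k).  Entries are non-negative unless ``zero_mean`` is set
    (only the zero-mean image pipeline produces signed inputs).
    """

    patterns: np.ndarray
    kind: StimulusKind
    params: dict = field(default_factory=dict)
    zero_mean: bool = False

    def __post_init__(self):
        X = np.asarray(self.patterns, dtype=float)
        if X.ndim != 2:
            raise ValueError("patterns must be a K x N matrix")
        K, N = X.shape
        if K < 1 or N < 2:
            raise ValueError(f"need K >= 1 and N >= 2, got K={K}, N={N}")
        if not self.zero_mean and np.any(X < 0):
            raise ValueError("patterns must be non-negative unless zero_mean")
        if np.any(np.all(X == 0, axis=1)):
            raise ValueError("each pattern needs at least one nonzero entry")
        object.__setattr__(self, "patterns", X)

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.patterns.shape[1]

    def save(self, path: str | Path) -> None:
        """Write the pattern matrix as TSV with a JSON metadata sidecar."""
        path = Path(path)
        np.savetxt(path, self.patterns, delimiter="\t")
        meta = {
            "kind": self.kind.value,
            "params": self.params,
            "zero_mean": self.zero_mean,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "StimulusEnsemble":
        path = Path(path)
        X = np.loadtxt(path, delimiter="\t", ndmin=2)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            patterns=X,
            kind=StimulusKind(meta["kind"]),
            params=meta.get("params", {}),
            zero_mean=meta.get("zero_mean", False),
        )


def make_pair2d(phi: float) -> StimulusEnsemble:
    """Two mirrored unit-norm stimuli at angle ``phi``.

    The patterns are x^(1) = (cos phi, sin phi) and x^(2) = (sin phi,
    cos phi): unit vectors mirrored in the diagonal, with an angle
    pi/2 - 2*phi between them.  ``phi = 0`` gives orthogonal stimuli,
    ``phi = pi/4`` parallel (singular) ones.
    """
    if not 0 <= phi < np.pi / 2:
        raise ValueError(f"phi must lie in [0, pi/2), got {phi}")
    c, s = np.cos(phi), np.sin(phi)
    X = np.array([[c, s], [s, c]])
    return StimulusEnsemble(X, StimulusKind.PAIR2D, params={"phi": float(phi)})


def _circular_distance(n: int) -> np.ndarray:
    """n x n matrix of circular index distances min(|i-k|, n-|i-k|)."""
    idx = np.arange(n)
    d = np.abs(idx[None, :] - idx[:, None])
    return np.minimum(d, n - d)


def make_triangular(N: int, K: int, omega: float) -> StimulusEnsemble:
    """Circulant triangular tuning curves of width fraction ``omega``.

    Pattern k has entry max(0, 1 - 2 d(i,k) / (N * omega)) at input i,
    where d is the circular distance with periodic boundaries.  The peak
    value is 1 at i = k and the profile is identical for every k up to a
    circular shift.
    """
    if N < 2 or K < 1:
        raise ValueError("need N >= 2 and K >= 1")
    if omega <= 0:
        raise ValueError(f"width fraction omega must be positive, got {omega}")
    d = _circular_distance(N).astype(float)
    profile = np.clip(1.0 - (2.0 / (N * omega)) * d, 0.0, None)
    X = profile[:K, :]
    return StimulusEnsemble(
        X, StimulusKind.TRIANGULAR, params={"N": N, "K": K, "omega": float(omega)}
    )


def make_von_mises(N: int, K: int) -> StimulusEnsemble:
    """Circulant von Mises tuning curves exp(-(1 + cos(2 pi (i-k)/N)))."""
    if N < 2 or K < 1:
        raise ValueError("need N >= 2 and K >= 1")
    idx = np.arange(N)
    shift = idx[None, :] - idx[:, None]
    X = np.exp(-(1.0 + np.cos(2.0 * np.pi * shift / N)))[:K, :]
    return StimulusEnsemble(X, StimulusKind.VON_MISES, params={"N": N, "K": K})


# ---------------------------------------------------------------------------
# image pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImagePipelineConfig:
    """Geometry and filtering parameters of the retinal patch pipeline.

    ``patch_pixels`` is the exact number of pixels in each circular patch.
    The Difference-of-Gaussians filter has a centre of width 1 pixel and a
    surround of width 3 pixels by default; the widths are the Gaussian
    standard deviations and each Gaussian is normalised to unit sum before
    subtraction so the balanced filter annihilates constant images.
    """

    patch_pixels: int = 400
    dog_center_width: float = 1.0
    dog_surround_width: float = 3.0
    n_patches: int = 40000
    rng_seed: int = 0

    def __post_init__(self):
        if self.patch_pixels <= 0:
            raise ValueError("patch_pixels must be positive")
        if self.dog_surround_width <= self.dog_center_width:
            raise ValueError("surround width must exceed center width")


def generate_synthetic_images(n: int, size: int, seed: int) -> np.ndarray:
    """Stack of n greyscale 1/f-spectrum noise images, each size x size.

    The amplitude spectrum falls off as 1/|f| (the hallmark second-order
    statistic of natural scenes) with independent Gaussian Fourier
    coefficients; each image is rescaled to the [0, 1] intensity range.
    Deterministic given ``seed``.
    """
    if n <= 0:
        raise ValueError("need at least one image")
    if size < 32:
        raise ValueError("images smaller than 32 px are not supported")
    rng = np.random.default_rng(seed)
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    freq = np.hypot(fy, fx)
    amplitude = np.zeros_like(freq)
    amplitude[freq > 0] = 1.0 / freq[freq > 0]
    images = np.empty((n, size, size))
    for j in range(n):
        coeff = rng.standard_normal((size, size)) + 1j * rng.standard_normal((size, size))
        img = np.real(np.fft.ifft2(coeff * amplitude))
        lo, hi = img.min(), img.max()
        images[j] = (img - lo) / (hi - lo)
    return images


def dog_kernel(center_width: float, surround_width: float) -> np.ndarray:
    """Balanced Difference-of-Gaussians kernel (sums to zero).

    Isotropic Gaussians of standard deviation ``center_width`` and
    ``surround_width`` pixels, truncated at four surround widths, each
    normalised to unit sum before subtraction.
    """
    radius = int(np.ceil(4.0 * surround_width))
    ax = np.arange(-radius, radius + 1, dtype=float)
    r2 = ax[:, None] ** 2 + ax[None, :] ** 2
    center = np.exp(-r2 / (2.0 * center_width**2))
    surround = np.exp(-r2 / (2.0 * surround_width**2))
    return center / center.sum() - surround / surround.sum()


def circular_mask(n_pixels: int) -> np.ndarray:
    """Boolean disc mask containing exactly ``n_pixels`` pixels.

    The smallest-radius disc holding at least ``n_pixels`` is trimmed back
    to the exact count by removing the outermost pixels deterministically
    (largest centre distance first, raster order breaking ties).
    """
    radius = 1
    while True:
        side = 2 * radius + 1
        ax = np.arange(side) - radius
        r2 = ax[:, None] ** 2 + ax[None, :] ** 2
        inside = r2 <= radius**2
        if inside.sum() >= n_pixels:
            break
        radius += 1
    mask = inside.copy()
    excess = int(mask.sum()) - n_pixels
    if excess > 0:
        flat_r2 = np.where(mask, r2, -1).ravel()
        # drop the pixels with the largest distance; ties resolved by
        # later raster position first (stable argsort, reversed)
        order = np.argsort(flat_r2, kind="stable")[::-1]
        drop = order[:excess]
        mask.ravel()[drop] = False
    return mask


def make_image_patches(
    images: np.ndarray,
    cfg: ImagePipelineConfig,
    zero_mean: bool = False,
) -> StimulusEnsemble:
    """DoG-filter images and cut random circular patches.

    Each image is convolved with the balanced Difference-of-Gaussians
    kernel, then ``cfg.n_patches`` circular patches of exactly
    ``cfg.patch_pixels`` pixels are sampled at uniformly random positions
    and flattened in raster order.  The whole ensemble is affinely mapped
    to the [0, 1] range (a single map for all patches, preserving
    relative contrast); with ``zero_mean`` True the scaled ensemble is
    additionally shifted so its grand mean is zero, allowing negative
    inputs.
    """
    images = np.asarray(images, dtype=float)
    if images.ndim == 2:
        images = images[None]
    mask = circular_mask(cfg.patch_pixels)
    side = mask.shape[0]
    if images.shape[1] < side or images.shape[2] < side:
        raise ValueError(
            f"images of shape {images.shape[1:]} cannot contain the "
            f"{side} x {side} patch bounding box"
        )
    kernel = dog_kernel(cfg.dog_center_width, cfg.dog_surround_width)
    filtered = np.stack(
        [ndimage.convolve(img, kernel, mode="reflect") for img in images]
    )
    rng = np.random.default_rng(cfg.rng_seed)
    n_img, h, w = filtered.shape
    patches = np.empty((cfg.n_patches, cfg.patch_pixels))
    for j in range(cfg.n_patches):
        i = rng.integers(n_img)
        top = rng.integers(h - side + 1)
        left = rng.integers(w - side + 1)
        patches[j] = filtered[i, top : top + side, left : left + side][mask]
    lo, hi = patches.min(), patches.max()
    patches = (patches - lo) / (hi - lo)
    if zero_mean:
        patches -= patches.mean()
    return StimulusEnsemble(
        patches,
        StimulusKind.IMAGE_PATCHES,
        params={
            "patch_pixels": cfg.patch_pixels,
            "dog_center_width": cfg.dog_center_width,
            "dog_surround_width": cfg.dog_surround_width,
            "n_patches": cfg.n_patches,
            "rng_seed": cfg.rng_seed,
        },
        zero_mean=zero_mean,
    )


def load_images(paths: list[str | Path]) -> np.ndarray:
    """Load greyscale PNG/PGM images into a stack scaled to [0, 1]."""
    import imageio.v3 as iio

    stack = []
    for p in paths:
        img = np.asarray(iio.imread(p), dtype=float)
        if img.ndim == 3:
            img = img.mean(axis=2)
        lo, hi = img.min(), img.max()
        stack.append((img - lo) / (hi - lo) if hi > lo else img * 0.0)
    return np.stack(stack)
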
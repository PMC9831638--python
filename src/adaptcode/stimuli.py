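"""Synthetic visual stimuli: correlated image patches, movies, templates, gratings.

The model population is trained and exercised on standardized grayscale
patches.  Natural scenes are emulated by Gaussian random fields with an
isotropic 1/f-type power spectrum, which share the second-order statistics
that make sparse coding produce localized, oriented features.  The module
also provides the task stimuli: a procedural "tree" object template, the
7x7 white-cross target, and sinusoidal gratings, plus PCA preprocessing of
a patch corpus.

Conventions
-----------
* Patches are ``(W, W)`` float64 arrays, standardized per patch to zero
  mean and unit variance.
* Image positions are 1-based ``(row, col)`` pairs in ``[1, W]``.
* Grating orientation 0 deg produces horizontal stripes (each row is
  constant); orientation increases counter-clockwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "PcaMap",
    "Template",
    "standardize",
    "generate_patches",
    "generate_movie",
    "make_templates",
    "embed_object",
    "superimpose_target",
    "make_grating",
    "preprocess_corpus",
]

#: Pixel value of the white target on the standardized intensity scale.
#: Strongly supra-threshold relative to unit-variance backgrounds.
DEFAULT_WHITE = 3.0


@dataclass(frozen=True)
class Template:
    """A deterministic target image.

    Parameters
    ----------
    pixels
        Image array: ``(W, W)`` for the object template, ``(7, 7)`` for
        the cross.
    kind
        Either ``"object"`` or ``"cross"``.
    """

    pixels: np.ndarray
    kind: str


@dataclass(frozen=True)
class PcaMap:
    """Affine map between pixel space and a reduced PCA space.

    ``components`` has orthonormal rows (``d`` x ``W**2``); ``mean`` is the
    corpus mean in pixel space.
    """

    mean: np.ndarray
    components: np.ndarray

    @property
    def d(self) -> int:
        return self.components.shape[0]

    def reduce(self, images: np.ndarray) -> np.ndarray:
        """Project flattened images onto the retained components.

        Accepts a single image ``(W, W)`` / ``(W**2,)`` or a stack with the
        pixel axis last after flattening.
        """
        flat = np.asarray(images, dtype=float).reshape(-1, self.mean.size)
        out = (flat - self.mean) @ self.components.T
        return out[0] if np.asarray(images).ndim <= 2 and out.shape[0] == 1 else out

    def expand(self, coords: np.ndarray) -> np.ndarray:
        """Back-project reduced coordinates to (flattened) pixel space."""
        coords = np.asarray(coords, dtype=float)
        return coords @ self.components + self.mean


def standardize(image: np.ndarray) -> np.ndarray:
    """Return a zero-mean, unit-variance copy of ``image``.

    Raises
    ------
    ValueError
        If the image is constant (zero variance cannot be standardized).
    """
    image = np.asarray(image, dtype=float)
    sd = image.std()
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a constant or non-finite image")
    return (image - image.mean()) / sd


def _spectral_field(rng: np.random.Generator, W: int, exponent: float) -> np.ndarray:
    """One Gaussian random field with power spectrum ~ f**(-exponent)."""
    fx = np.fft.fftfreq(W)[:, None]
    fy = np.fft.fftfreq(W)[None, :]
    f = np.hypot(fx, fy)
    amp = np.zeros_like(f)
    nz = f > 0
    amp[nz] = f[nz] ** (-exponent / 2.0)
    spec = amp * (rng.standard_normal((W, W)) + 1j * rng.standard_normal((W, W)))
    field = np.fft.ifft2(spec).real
    return field


def _dead_leaves(rng: np.random.Generator, W: int, n_disks: int = 60) -> np.ndarray:
    """Occluding random disks ("dead leaves"): scale-invariant, edge-rich.

    Unlike a Gaussian field of matched spectrum, these images have true
    sparse structure (edges and occlusions), which is what makes learned
    sparse-coding features localized and oriented.
    """
    yy, xx = np.mgrid[0:W, 0:W].astype(float)
    img = rng.standard_normal() * np.ones((W, W))
    # power-law radii: many small leaves, few large ones
    u = rng.random(n_disks)
    radii = 2.0 * (1.0 - u * (1.0 - (2.0 / (0.6 * W)) ** 2)) ** -0.5
    for r in radii:
        cy, cx = rng.uniform(-2, W + 2, size=2)
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        if mask.any():
            img[mask] = rng.standard_normal()
    return img


def generate_patches(
    n: int,
    W: int = 32,
    spectral_exponent: float = 2.0,
    seed: int = 0,
    kind: str = "spectral",
) -> np.ndarray:
    """Draw ``n`` standardized synthetic image patches.

    ``kind="spectral"`` (default) samples Gaussian random fields with an
    isotropic power spectrum ~ ``f**(-spectral_exponent)``;
    ``kind="dead_leaves"`` samples occluding-disk images, which share the
    coarse 1/f-like statistics but additionally carry the sparse edge
    structure of natural scenes.  Returns ``(n, W, W)``; deterministic in
    ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if W < 4:
        raise ValueError("W must be >= 4")
    rng = np.random.default_rng(seed)
    out = np.empty((n, W, W))
    for i in range(n):
        if kind == "dead_leaves":
            field = _dead_leaves(rng, W)
        elif kind == "spectral":
            field = _spectral_field(rng, W, spectral_exponent)
        else:
            raise ValueError(f"unknown patch kind {kind!r}")
        out[i] = standardize(field)
    return out


def generate_movie(
    T: int,
    W: int = 32,
    drift: float = 1.0,
    spectral_exponent: float = 2.0,
    seed: int = 0,
    kind: str = "spectral",
) -> np.ndarray:
    """A movie of ``T`` frames: one correlated texture drifting on a torus.

    Frame ``t`` is the base texture circularly shifted by ``round(t*drift)``
    columns, then standardized; adjacent frames are strongly correlated for
    sub-pixel-to-one-pixel drifts.

    Raises
    ------
    ValueError
        If ``T < 2`` or ``drift`` exceeds the frame width.
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    if abs(drift) > W:
        raise ValueError("drift larger than the frame width")
    rng = np.random.default_rng(seed)
    if kind == "dead_leaves":
        base = standardize(_dead_leaves(rng, W))
    else:
        base = standardize(_spectral_field(rng, W, spectral_exponent))
    frames = np.empty((T, W, W))
    for t in range(T):
        shift = int(round(t * drift)) % W
        frames[t] = np.roll(base, shift, axis=1)
    return frames


def _cross_mask() -> np.ndarray:
    mask = np.zeros((7, 7))
    mask[3, :] = 1.0
    mask[:, 3] = 1.0
    return mask


def _tree_silhouette(W: int, rng: np.random.Generator) -> np.ndarray:
    """Procedural tree-like silhouette: trunk plus a lobed canopy.

    Purely synthetic stand-in for a photographic object template; it is
    deterministic given the generator state and has the coarse structure
    (compact filled blob with a branching outline) the detection task needs.
    """
    yy, xx = np.mgrid[0:W, 0:W].astype(float)
    cy, cx = 0.40 * W, 0.5 * W
    r = np.hypot(yy - cy, xx - cx)
    theta = np.arctan2(yy - cy, xx - cx)
    # canopy: radius modulated by a few random angular harmonics (lobes)
    radius = 0.28 * W * np.ones_like(theta)
    for k in range(2, 6):
        radius += 0.035 * W * rng.uniform(0.5, 1.5) * np.cos(
            k * theta + rng.uniform(0, 2 * np.pi)
        )
    canopy = r <= radius
    trunk = (
        (np.abs(xx - cx) <= max(1.0, 0.04 * W))
        & (yy >= cy)
        & (yy <= 0.92 * W)
    )
    img = (canopy | trunk).astype(float)
    return standardize(img)


def make_templates(
    W: int = 32, seed: int = 0, white: float = DEFAULT_WHITE
) -> tuple[Template, Template]:
    """Build the object template (``W`` x ``W``) and the 7x7 cross target.

    The cross is a plus shape of 13 pixels at value ``white`` on a zero
    background; the object is a standardized procedural tree silhouette,
    deterministic given ``seed``.
    """
    if W < 8:
        raise ValueError("W must be >= 8")
    rng = np.random.default_rng(seed)
    obj = Template(pixels=_tree_silhouette(W, rng), kind="object")
    cross = Template(pixels=white * _cross_mask(), kind="cross")
    return obj, cross


def embed_object(x: np.ndarray, obj: Template, gamma: float) -> np.ndarray:
    """Mix an object template into a patch: ``(1 - gamma) * x + gamma * obj``."""
    x = np.asarray(x, dtype=float)
    if x.shape != obj.pixels.shape:
        raise ValueError("patch and object template shapes differ")
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    return (1.0 - gamma) * x + gamma * obj.pixels


def superimpose_target(
    frame: np.ndarray, cross: Template, position: tuple[float, float]
) -> np.ndarray:
    """Overwrite a 7x7 neighborhood of ``position`` with the cross target.

    ``position`` is a real-valued 1-based ``(row, col)``; it is rounded to
    the nearest integer and clipped to ``[1, W]``.  Cross arms falling
    outside the frame are clipped.
    """
    frame = np.asarray(frame, dtype=float).copy()
    W = frame.shape[0]
    r = int(np.clip(np.round(position[0]), 1, W)) - 1
    c = int(np.clip(np.round(position[1]), 1, W)) - 1
    mask = cross.pixels != 0
    for dr in range(-3, 4):
        for dc in range(-3, 4):
            if mask[dr + 3, dc + 3]:
                rr, cc = r + dr, c + dc
                if 0 <= rr < W and 0 <= cc < W:
                    frame[rr, cc] = cross.pixels[dr + 3, dc + 3]
    return frame


def make_grating(
    orientation: float, frequency: float, phase: float = 0.0, W: int = 32
) -> np.ndarray:
    """Standardized sinusoidal grating.

    Parameters
    ----------
    orientation
        Stripe orientation in degrees, in ``[0, 180)`` by convention
        (values outside are wrapped).  0 deg gives horizontal stripes.
    frequency
        Cycles per patch; must be nonzero.
    phase
        Phase offset in radians.
    """
    if frequency == 0:
        raise ValueError("frequency 0 gives a constant patch")
    theta = np.deg2rad(orientation % 180.0)
    yy, xx = np.mgrid[0:W, 0:W].astype(float)
    # wave vector perpendicular to the stripes
    u = np.cos(theta) * yy + np.sin(theta) * xx
    return standardize(np.sin(2.0 * np.pi * frequency * u / W + phase))


def preprocess_corpus(patches: np.ndarray, d: int) -> tuple[PcaMap, np.ndarray]:
    """Mean-center a patch corpus and retain the top ``d`` PCA components.

    Returns the fitted :class:`PcaMap` and the corpus coordinates
    (``n`` x ``d``).  Explained variance is non-increasing across the
    retained components.
    """
    patches = np.asarray(patches, dtype=float)
    n = patches.shape[0]
    flat = patches.reshape(n, -1)
    if d > flat.shape[1]:
        raise ValueError("d exceeds the pixel dimension")
    if n <= d:
        raise ValueError("need more patches than retained components")
    pca = PCA(n_components=d, svd_solver="full")
    coords = pca.fit_transform(flat)
    pmap = PcaMap(mean=pca.mean_.copy(), components=pca.components_.copy())
    return pmap, coords
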
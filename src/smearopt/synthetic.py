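"""Synthetic blood-smear-like image generator.

Emulates the visual structure that separates leukemic from healthy smear
frames: a pale pink background scattered with faint red-blood-cell discs,
plus dark purple stained nuclei.  Diseased (lymphoblast-bearing) images
carry more, larger and more irregularly lobed nuclei than healthy ones;
the irregularity is a low-order harmonic perturbation of the nucleus
boundary radius, giving the lobed outline characteristic of blasts.

Generation is fully deterministic given the parameters and seed, so the
whole pipeline — augmentation, splitting, CNN training, Bayesian search —
is testable without downloading any real microscopy data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import disk as _disk
from skimage.draw import ellipse as _ellipse
from skimage.draw import polygon as _polygon

from .data import DISEASED, HEALTHY, DatasetBundle, LabeledImage

__all__ = ["SmearParams", "generate_image", "generate_dataset", "stained_fraction"]


@dataclass(frozen=True)
class SmearParams:
    """Generative knobs; per-class values are (healthy, diseased) pairs.

    Radii and counts are in pixels / objects at the given ``image_size``;
    use :meth:`for_size` to rescale the geometry to another raster size.
    """

    image_size: int = 256
    background_color_mean: tuple[float, float, float] = (244.0, 233.0, 237.0)
    rbc_color_mean: tuple[float, float, float] = (231.0, 172.0, 165.0)
    stain_color_mean: tuple[float, float, float] = (98.0, 48.0, 124.0)
    rbc_count_range: tuple[int, int] = (8, 16)
    rbc_radius_mean: float = 18.0
    nucleus_count_mean: dict[str, float] = field(
        default_factory=lambda: {HEALTHY: 1.5, DISEASED: 4.0}
    )
    nucleus_radius_mean: dict[str, float] = field(
        default_factory=lambda: {HEALTHY: 14.0, DISEASED: 26.0}
    )
    boundary_irregularity: dict[str, float] = field(
        default_factory=lambda: {HEALTHY: 0.03, DISEASED: 0.35}
    )
    pixel_noise_sd: float = 6.0

    def __post_init__(self) -> None:
        for d in (self.nucleus_count_mean, self.nucleus_radius_mean):
            if any(v < 0 for v in d.values()):
                raise ValueError("counts and radii must be non-negative")
        if max(self.nucleus_radius_mean.values()) * 2 >= self.image_size:
            raise ValueError("nucleus radius too large for the image size")
        dominated = (
            self.nucleus_count_mean[DISEASED] > self.nucleus_count_mean[HEALTHY]
            or self.nucleus_radius_mean[DISEASED] > self.nucleus_radius_mean[HEALTHY]
            or self.boundary_irregularity[DISEASED] > self.boundary_irregularity[HEALTHY]
        )
        if not dominated:
            raise ValueError(
                "diseased class must exceed healthy in count, radius or "
                "irregularity for the classes to be separable"
            )

    def for_size(self, image_size: int) -> "SmearParams":
        """Rescale all geometry to a different raster size."""
        s = image_size / self.image_size
        return replace(
            self,
            image_size=image_size,
            rbc_radius_mean=self.rbc_radius_mean * s,
            nucleus_radius_mean={
                k: v * s for k, v in self.nucleus_radius_mean.items()
            },
        )


def _nucleus_blob(canvas, cx, cy, radius, irregularity, color, rng):
    """Rasterize one stained nucleus with a harmonically perturbed boundary."""
    theta = np.linspace(0.0, 2.0 * np.pi, 120, endpoint=False)
    perturb = np.zeros_like(theta)
    for order in range(2, 7):  # low-order lobes, blast-like
        amp = rng.random() / order
        phase = rng.random() * 2.0 * np.pi
        perturb += amp * np.cos(order * theta + phase)
    r = radius * (1.0 + irregularity * perturb)
    r = np.clip(r, 1.0, None)
    rows = cy + r * np.sin(theta)
    cols = cx + r * np.cos(theta)
    rr, cc = _polygon(rows, cols, shape=canvas.shape[:2])
    jitter = rng.normal(0.0, 8.0, size=3)
    canvas[rr, cc] = np.clip(np.asarray(color) + jitter, 0, 255)


def generate_image(
    label: str,
    params: SmearParams,
    rng: np.random.Generator | int | None = None,
    with_meta: bool = False,
):
    """Render one synthetic smear frame for ``label``.

    Nucleus count is Poisson around the class mean (clamped to at least
    one nucleus per frame); nucleus radii are mildly jittered around the
    class mean; the boundary perturbation amplitude is the class
    irregularity.  Gaussian pixel noise is added last.

    With ``with_meta=True`` returns ``(image, meta)`` where ``meta``
    records the drawn nucleus count and centers (useful for validating
    the generative statistics).
    """
    if label not in (HEALTHY, DISEASED):
        raise ValueError(f"unknown label {label!r}")
    rng = np.random.default_rng(rng)
    size = params.image_size
    canvas = np.ones((size, size, 3), dtype=np.float64)
    canvas *= np.asarray(params.background_color_mean)

    # faint red-blood-cell discs
    n_rbc = int(rng.integers(params.rbc_count_range[0], params.rbc_count_range[1] + 1))
    for _ in range(n_rbc):
        cy, cx = rng.random(2) * size
        a = params.rbc_radius_mean * (0.7 + 0.6 * rng.random())
        b = a * (0.75 + 0.25 * rng.random())
        rr, cc = _ellipse(cy, cx, a, b, shape=(size, size),
                          rotation=rng.random() * np.pi)
        shade = np.asarray(params.rbc_color_mean) + rng.normal(0, 6, size=3)
        canvas[rr, cc] = 0.65 * canvas[rr, cc] + 0.35 * shade
        # pale center gives the biconcave look
        rr, cc = _disk((cy, cx), max(a * 0.45, 1.0), shape=(size, size))
        canvas[rr, cc] = 0.6 * canvas[rr, cc] + 0.4 * np.asarray(
            params.background_color_mean
        )

    # stained nuclei
    k = max(1, int(rng.poisson(params.nucleus_count_mean[label])))
    irregularity = params.boundary_irregularity[label]
    mean_radius = params.nucleus_radius_mean[label]
    centers = []
    for _ in range(k):
        radius = mean_radius * (0.8 + 0.4 * rng.random())
        margin = radius + 2
        cy = margin + rng.random() * (size - 2 * margin)
        cx = margin + rng.random() * (size - 2 * margin)
        centers.append((cy, cx, radius))
        _nucleus_blob(canvas, cx, cy, radius, irregularity,
                      params.stain_color_mean, rng)

    canvas += rng.normal(0.0, params.pixel_noise_sd, size=canvas.shape)
    pixels = np.clip(canvas, 0, 255).round().astype(np.uint8)
    image = LabeledImage(pixels=pixels, label=label, source_id="synthetic")
    if with_meta:
        return image, {"nucleus_count": k, "nucleus_centers": centers}
    return image


def generate_dataset(
    n_healthy: int,
    n_diseased: int,
    params: SmearParams | None = None,
    seed: int = 0,
) -> DatasetBundle:
    """Generate a bundle with exact class counts, deterministically.

    Source ids are ``syn_<label>_<index>`` so augmented variants can be
    grouped; two calls with the same seed produce identical bundles.
    """
    if n_healthy < 0 or n_diseased < 0:
        raise ValueError("counts must be non-negative")
    params = params or SmearParams()
    rng = np.random.default_rng(seed)
    images: list[LabeledImage] = []
    for label, count, tag in (
        (HEALTHY, n_healthy, "healthy"),
        (DISEASED, n_diseased, "diseased"),
    ):
        for i in range(count):
            im = generate_image(label, params, rng)
            images.append(replace(im, source_id=f"syn_{tag}_{i:04d}"))
    return DatasetBundle(images=images)


def stained_fraction(pixels: np.ndarray) -> float:
    """Fraction of pixels that look nucleus-stained (dark and blue-purple).

    A simple hand-crafted feature used to verify that the two synthetic
    classes are separable before any network is involved.
    """
    p = pixels.astype(np.float64)
    darkness = p.sum(axis=2) < 520.0
    purple = (p[..., 2] > p[..., 1] + 15.0) & (p[..., 0] < 180.0)
    return float(np.mean(darkness & purple))
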
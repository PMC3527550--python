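"""Rendered nuclei fields with four morphological phenotype classes.

Emulates a Hoechst-stained nuclei channel: interphase nuclei are smooth
ellipses, mitotic nuclei are compact condensed bright shapes, apoptotic
nuclei fragment into small scattered blobs, and "artefacts" are merged
odd shapes (e.g. two fused ellipses standing in for multi/binucleated
objects and debris).  Nuclei never overlap — centers are rejection-sampled
with a minimum-distance rule — so the segmentation ground truth is
unambiguous.  Intensities are 16-bit counts over a smooth background
gradient plus Gaussian read-out noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import draw, filters

from ..imagequant import ImageField

CLASSES = ("interphase", "mitosis", "apoptosis", "artefact")

#: 16-bit intensity budget
FULL_SCALE = 65535
BACKGROUND_LEVEL = 300.0
NUCLEUS_LEVEL = 6000.0


@dataclass
class NucleiFieldSpec:
    n_cells: int = 100
    image_shape: tuple[int, int] = (1024, 1024)
    class_mix: tuple[float, float, float, float] = (1.0, 0.0, 0.0, 0.0)
    background_gradient_amplitude: float = 150.0
    noise_sd: float = 40.0
    min_center_distance: float = 42.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if min(self.image_shape) < 64:
            raise ValueError("image_shape must be at least 64x64")
        if len(self.class_mix) != len(CLASSES):
            raise ValueError(f"class_mix needs {len(CLASSES)} proportions")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")


@dataclass
class NucleiGroundTruth:
    label_mask: np.ndarray  # 0 background, k>0 = nucleus k
    classes: list  # class name per label, index 0 <-> label 1
    centers: list = field(default_factory=list)

    @property
    def n_nuclei(self) -> int:
        return len(self.classes)


def _sample_centers(rng, n, shape, min_dist, margin=24, max_tries=20000):
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n and tries < max_tries:
        tries += 1
        r = rng.uniform(margin, shape[0] - margin)
        c = rng.uniform(margin, shape[1] - margin)
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_dist**2 for r0, c0 in centers):
            centers.append((r, c))
    if len(centers) < n:
        raise ValueError(
            f"could not place {n} nuclei at min distance {min_dist} in {shape}"
        )
    return centers


def _paint_ellipse(canvas, mask, label, center, a, b, angle, level, rng):
    rr, cc = draw.ellipse(center[0], center[1], a, b, shape=canvas.shape, rotation=angle)
    # mild within-nucleus shading for texture
    shading = rng.uniform(0.85, 1.15, size=rr.shape)
    canvas[rr, cc] = np.maximum(canvas[rr, cc], level * shading)
    mask[rr, cc] = label


def _paint_nucleus(canvas, mask, label, cls, center, rng):
    if cls == "interphase":
        a, b = rng.uniform(9, 13), rng.uniform(7, 10)
        _paint_ellipse(canvas, mask, label, center, a, b, rng.uniform(0, np.pi), NUCLEUS_LEVEL, rng)
    elif cls == "mitosis":
        # condensed chromatin: small and markedly brighter
        a, b = rng.uniform(4.5, 6.5), rng.uniform(3.5, 5.5)
        _paint_ellipse(canvas, mask, label, center, a, b, rng.uniform(0, np.pi), 2.2 * NUCLEUS_LEVEL, rng)
    elif cls == "apoptosis":
        # fragmented: several small bright blobs around the center
        n_frag = rng.integers(3, 6)
        for _ in range(n_frag):
            dr, dc = rng.uniform(-8, 8, size=2)
            rad = rng.uniform(2.0, 3.5)
            _paint_ellipse(
                canvas, mask, label,
                (center[0] + dr, center[1] + dc), rad, rad, 0.0, 1.6 * NUCLEUS_LEVEL, rng,
            )
    elif cls == "artefact":
        # merged/odd shape: two fused elongated ellipses
        angle = rng.uniform(0, np.pi)
        offset = rng.uniform(7, 10)
        dr, dc = offset * np.cos(angle), offset * np.sin(angle)
        for sign in (-1, 1):
            a, b = rng.uniform(10, 14), rng.uniform(5, 7)
            _paint_ellipse(
                canvas, mask, label,
                (center[0] + sign * dr / 2, center[1] + sign * dc / 2),
                a, b, angle + rng.uniform(-0.3, 0.3), NUCLEUS_LEVEL, rng,
            )
    else:  # pragma: no cover
        raise ValueError(f"unknown class {cls!r}")


def make_nuclei_field(spec: NucleiFieldSpec) -> tuple[ImageField, NucleiGroundTruth]:
    """Render one nuclei-channel field plus its ground truth.

    Returns the 16-bit image (wrapped in an :class:`ImageField` under the
    ``nuclei`` role) and a ground truth holding the label mask, the class
    of each label and the planted centers.
    """
    rng = np.random.default_rng(spec.rng_seed)
    shape = tuple(spec.image_shape)
    counts = rng.multinomial(spec.n_cells, spec.class_mix)
    classes: list[str] = []
    for cls, n in zip(CLASSES, counts):
        classes.extend([cls] * int(n))
    rng.shuffle(classes)  # type: ignore[arg-type]

    canvas = np.zeros(shape, dtype=np.float64)
    mask = np.zeros(shape, dtype=np.int32)
    centers = _sample_centers(rng, spec.n_cells, shape, spec.min_center_distance)
    for label, (cls, center) in enumerate(zip(classes, centers), start=1):
        _paint_nucleus(canvas, mask, label, cls, center, rng)

    # soften edges, then add background gradient and read-out noise
    canvas = filters.gaussian(canvas, sigma=1.0, preserve_range=True)
    rows = np.linspace(0, 1, shape[0])[:, None]
    cols = np.linspace(0, 1, shape[1])[None, :]
    gr, gc = rng.uniform(-1, 1, size=2)
    background = BACKGROUND_LEVEL + spec.background_gradient_amplitude * (
        0.5 + 0.5 * (gr * rows + gc * cols)
    )
    image = canvas + background + rng.normal(0, spec.noise_sd, size=shape)
    image = np.clip(np.rint(image), 0, FULL_SCALE).astype(np.uint16)

    field_ = ImageField({"nuclei": image}, source_id=f"synthetic_seed{spec.rng_seed}")
    return field_, NucleiGroundTruth(mask, classes, centers)


def fragment_count(mask: np.ndarray, label: int) -> int:
    """Connected components of one ground-truth label (apoptotic > 1)."""
    _, n = ndimage.label(mask == label)
    return int(n)
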
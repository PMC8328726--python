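"""Synthetic textured phantoms with ground-truth lesion masks.

Each phantom is a 2-D intensity image in [0, 1] holding an elliptical
"brain" support on a dark frame, with zero or more quasi-circular lesions
embedded inside the ellipse.  Lesion interiors are filled with a stationary
textured field: white Gaussian noise smoothed with an isotropic Gaussian
kernel whose standard deviation sets the spatial correlation length,
scaled to a target contrast and shifted in mean relative to the
background.  Two lesion classes ("A" and "B") differ only through these
three texture parameters, so downstream texture features carry a known,
tunable class signal.

The generator is a pure function of its spec: the same
:class:`PhantomSpec` always yields bit-identical arrays.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
from scipy.ndimage import binary_erosion, gaussian_filter

from .errors import PhantomSpecError

__all__ = [
    "ClassParams",
    "PhantomSpec",
    "PhantomSample",
    "generate_phantom",
    "generate_cohort",
    "default_spec",
    "child_seed",
]


@dataclass(frozen=True)
class ClassParams:
    """Texture descriptor of one lesion class.

    Parameters
    ----------
    correlation_length : float
        Standard deviation (pixels) of the Gaussian smoothing kernel
        applied to the white-noise field; larger values give coarser,
        more spatially correlated texture.
    contrast_scale : float
        Standard deviation (intensity units) of the textured field after
        smoothing and renormalisation.
    mean_shift : float
        Mean lesion intensity minus the background level.
    """

    correlation_length: float = 1.0
    contrast_scale: float = 0.08
    mean_shift: float = 0.18


#: Default per-class texture parameters.  Class B lesions are coarser
#: (longer correlation length), higher-contrast and brighter than class A,
#: so all three matrix families plus first-order statistics see signal.
DEFAULT_CLASS_PARAMS: Dict[str, ClassParams] = {
    "A": ClassParams(correlation_length=1.0, contrast_scale=0.08, mean_shift=0.18),
    "B": ClassParams(correlation_length=3.0, contrast_scale=0.12, mean_shift=0.26),
}


@dataclass(frozen=True)
class PhantomSpec:
    image_size: Tuple[int, int] = (64, 64)
    background_level: float = 0.35
    lesion_count: int = 1
    lesion_radius_range: Tuple[int, int] = (5, 12)
    texture_class: str = "A"
    class_params: Dict[str, ClassParams] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PARAMS)
    )
    noise_sigma: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_size
        if h < 16 or w < 16:
            raise PhantomSpecError(
                f"image_size {self.image_size} is degenerate; need >= 16 px per side"
            )
        rmin, rmax = self.lesion_radius_range
        if rmin < 3:
            raise PhantomSpecError(f"minimum lesion radius {rmin} < 3 px")
        if rmax < rmin:
            raise PhantomSpecError("lesion_radius_range max < min")
        if rmax >= min(h, w) / 4:
            raise PhantomSpecError(
                f"maximum lesion radius {rmax} does not fit: must be < min(image_size)/4"
            )
        if self.lesion_count < 0:
            raise PhantomSpecError("lesion_count must be >= 0")
        if self.noise_sigma < 0:
            raise PhantomSpecError("noise_sigma must be >= 0")
        if self.texture_class not in self.class_params:
            raise PhantomSpecError(
                f"texture_class {self.texture_class!r} has no entry in class_params"
            )


@dataclass(frozen=True)
class PhantomSample:
    image: np.ndarray
    lesion_mask: np.ndarray
    label: str
    spec: PhantomSpec


def _brain_ellipse(shape: Tuple[int, int]) -> np.ndarray:
    """Axis-aligned ellipse covering ~80% of the frame, fixed orientation."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    a, b = 0.4 * h, 0.4 * w  # semi-axes: 80% of each dimension
    return ((rr - cy) / a) ** 2 + ((cc - cx) / b) ** 2 <= 1.0


def _textured_field(
    shape: Tuple[int, int], params: ClassParams, background: float, rng: np.random.Generator
) -> np.ndarray:
    """Smoothed white noise with unit variance scaled to the class contrast."""
    noise = rng.standard_normal(shape)
    smooth = gaussian_filter(noise, sigma=params.correlation_length, mode="reflect")
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    return background + params.mean_shift + params.contrast_scale * smooth


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render one phantom image with its ground-truth lesion mask.

    Lesion centres are drawn uniformly among positions where the full
    disc fits inside the background ellipse; discs may overlap (the mask
    is their union).  Raises :class:`PhantomSpecError` if the spec is
    invalid or a lesion cannot be placed.
    """
    spec.validate()
    h, w = spec.image_size
    rng = np.random.default_rng(spec.seed)

    support = _brain_ellipse((h, w))
    image = np.zeros((h, w), dtype=np.float64)
    image[support] = spec.background_level

    params = spec.class_params[spec.texture_class]
    mask = np.zeros((h, w), dtype=bool)

    rr, cc = np.mgrid[0:h, 0:w]
    for _ in range(spec.lesion_count):
        radius = int(rng.integers(spec.lesion_radius_range[0], spec.lesion_radius_range[1] + 1))
        # candidate centres: disc of this radius fully inside the ellipse
        struct = (rr[: 2 * radius + 1, : 2 * radius + 1] - radius) ** 2 + (
            cc[: 2 * radius + 1, : 2 * radius + 1] - radius
        ) ** 2 <= radius**2
        allowed = binary_erosion(support, structure=struct, border_value=0)
        idx = np.flatnonzero(allowed)
        if idx.size == 0:
            raise PhantomSpecError(
                f"lesion of radius {radius} cannot fit inside the background ellipse"
            )
        centre = int(idx[int(rng.integers(idx.size))])
        cy, cx = divmod(centre, w)
        disc = (rr - cy) ** 2 + (cc - cx) ** 2 <= radius**2
        mask |= disc

    if mask.any():
        texture = _textured_field((h, w), params, spec.background_level, rng)
        image[mask] = texture[mask]

    if spec.noise_sigma > 0:
        image = image + spec.noise_sigma * rng.standard_normal((h, w))
    image = np.clip(image, 0.0, 1.0)

    return PhantomSample(image=image, lesion_mask=mask, label=spec.texture_class, spec=spec)


def child_seed(master_seed: int, index: int) -> int:
    """Deterministic per-sample seed derived from the master seed.

    Uses :class:`numpy.random.SeedSequence` keyed on ``(master_seed,
    index)`` so any individual sample can be regenerated in isolation.
    The result is kept below 2**31.
    """
    ss = np.random.SeedSequence((int(master_seed), int(index)))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(
    n_per_class: int, base_spec: PhantomSpec | None = None, seed: int = 0
) -> List[PhantomSample]:
    """Balanced labelled cohort: ``n_per_class`` phantoms per class.

    Samples alternate A, B, A, B, ... and each sample's seed is derived
    from ``seed`` via :func:`child_seed`, so two calls with the same
    arguments produce identical cohorts.
    """
    if n_per_class < 1:
        raise PhantomSpecError("n_per_class must be >= 1")
    if base_spec is None:
        base_spec = default_spec()
    classes = sorted(base_spec.class_params)
    samples: List[PhantomSample] = []
    for i in range(n_per_class * len(classes)):
        label = classes[i % len(classes)]
        spec = dataclasses.replace(base_spec, texture_class=label, seed=child_seed(seed, i))
        samples.append(generate_phantom(spec))
    return samples


def default_spec(class_gap: float = 1.0, **overrides) -> PhantomSpec:
    """The standard phantom conditions used throughout the test suite.

    ``class_gap`` scales the *difference* between class A and class B
    texture parameters around their midpoint; 1.0 is the default
    condition, 0.0 makes the classes identical.
    """
    a, b = DEFAULT_CLASS_PARAMS["A"], DEFAULT_CLASS_PARAMS["B"]

    def interp(x: float, y: float) -> Tuple[float, float]:
        mid, half = (x + y) / 2.0, (y - x) / 2.0
        return mid - class_gap * half, mid + class_gap * half

    cl_a, cl_b = interp(a.correlation_length, b.correlation_length)
    cs_a, cs_b = interp(a.contrast_scale, b.contrast_scale)
    ms_a, ms_b = interp(a.mean_shift, b.mean_shift)
    params = {
        "A": ClassParams(cl_a, cs_a, ms_a),
        "B": ClassParams(cl_b, cs_b, ms_b),
    }
    return PhantomSpec(class_params=params, **overrides)
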
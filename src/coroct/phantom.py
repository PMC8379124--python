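"""Digital coronary-lumen resolution phantom.

Renders a PMMA slab drilled with 110 contrast-filled holes (22 diameters
from 3.00 to 3.42 mm in 0.02 mm steps, five repeats each) as a 2-D HU
image for a given reconstruction energy, iodine concentration and simulated
patient size.  Holes are laid out on a deterministic grid ordered by
(diameter, repeat).  Rendering is: area-weighted antialiased disks on the
PMMA background, isotropic Gaussian PSF blur, then i.i.d. Gaussian noise
whose sigma depends on patient size (and a per-energy VMI factor).  Ground
truth records describe the exact pre-blur geometry.

Images round-trip through a plain-text JSON container (`write_image` /
`read_image`) with bit-exact pixels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .spectral import CONVENTIONAL, EnergySpec, SpectralModel, default_model

__all__ = [
    "PATIENT_SIZES",
    "PhantomSpec",
    "GroundTruthHole",
    "PhantomImage",
    "layout_holes",
    "render_phantom",
    "write_image",
    "read_image",
    "PhantomParseError",
]

PATIENT_SIZES = ("kg70", "kg120")

_DEFAULT_DIAMETERS = tuple(round(3.00 + 0.02 * i, 2) for i in range(22))


def _default_noise() -> dict[str, float]:
    return {"kg70": 20.0, "kg120": 40.0}


def _default_vmi_noise() -> dict[int, float]:
    # flat noise reduction on VMI relative to the conventional image
    from .spectral import VMI_LEVELS

    return {e: 0.8 for e in VMI_LEVELS}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and acquisition-noise knobs of the digital phantom."""

    diameters: tuple[float, ...] = _DEFAULT_DIAMETERS
    repeats: int = 5
    pixel_spacing: float = 0.4  # mm per pixel
    clearance: float = 8.0  # centre-to-centre hole pitch, mm
    margin: float = 8.0  # border around outermost centres, mm
    psf_sigma: float = 0.45  # mm
    noise_sigma_conventional: dict[str, float] = field(default_factory=_default_noise)
    vmi_noise_factor: dict[int, float] = field(default_factory=_default_vmi_noise)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "diameters", tuple(float(x) for x in self.diameters))
        d = np.asarray(self.diameters, dtype=float)
        if d.ndim != 1 or d.size < 1:
            raise ValueError("diameters must be a non-empty 1-D sequence")
        if np.any(d <= 0):
            raise ValueError("diameters must be positive")
        if np.any(np.diff(d) <= 0):
            raise ValueError("diameters must be strictly increasing")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be >= 0")
        if self.clearance < 2.0 * float(d.max()):
            raise ValueError(
                "hole clearance must be at least twice the largest diameter"
            )
        for size, sigma in self.noise_sigma_conventional.items():
            if size not in PATIENT_SIZES:
                raise ValueError(f"unknown patient size {size!r}")
            if sigma < 0:
                raise ValueError("noise sigma must be >= 0")

    @property
    def n_holes(self) -> int:
        return len(self.diameters) * self.repeats

    def noise_sigma(self, energy: EnergySpec, patient_size: str) -> float:
        sigma = self.noise_sigma_conventional[patient_size]
        if energy.mode == "vmi":
            sigma *= self.vmi_noise_factor[energy.level_keV]
        return sigma


@dataclass(frozen=True)
class GroundTruthHole:
    hole_id: int
    center_x: float  # mm, image frame
    center_y: float  # mm
    diameter: float  # mm
    true_area: float  # mm^2, pi * (d/2)^2

    @classmethod
    def at(cls, hole_id: int, x: float, y: float, diameter: float) -> "GroundTruthHole":
        return cls(hole_id, x, y, diameter, math.pi * (diameter / 2.0) ** 2)


@dataclass
class PhantomImage:
    pixels: np.ndarray  # 2-D float64 HU, [row, col]
    pixel_spacing: float  # mm
    energy: EnergySpec
    iodine_conc: float
    patient_size: str
    truth: list[GroundTruthHole]

    @property
    def condition(self) -> tuple[EnergySpec, float, str]:
        return (self.energy, self.iodine_conc, self.patient_size)


def layout_holes(spec: PhantomSpec) -> list[GroundTruthHole]:
    """Deterministic grid layout, row-major, ordered by (diameter, repeat).

    110 default holes fall on an 11 x 10 grid at ``spec.clearance`` pitch.
    """
    n = spec.n_holes
    n_cols = math.ceil(math.sqrt(n))
    holes: list[GroundTruthHole] = []
    i = 0
    for diameter in spec.diameters:
        for _ in range(spec.repeats):
            r, c = divmod(i, n_cols)
            x = spec.margin + c * spec.clearance
            y = spec.margin + r * spec.clearance
            holes.append(GroundTruthHole.at(i, x, y, diameter))
            i += 1
    # overlap guard (grid layouts cannot overlap, but custom specs might)
    pitch = spec.clearance
    if pitch <= max(spec.diameters):
        raise ValueError("holes overlap: pitch smaller than largest diameter")
    return holes


def _image_shape(spec: PhantomSpec) -> tuple[int, int]:
    n = spec.n_holes
    n_cols = math.ceil(math.sqrt(n))
    n_rows = math.ceil(n / n_cols)
    width = 2 * spec.margin + (n_cols - 1) * spec.clearance
    height = 2 * spec.margin + (n_rows - 1) * spec.clearance
    return (
        int(round(height / spec.pixel_spacing)),
        int(round(width / spec.pixel_spacing)),
    )


def _paint_disk(
    img: np.ndarray,
    spacing: float,
    hole: GroundTruthHole,
    value: float,
    background: float,
    supersample: int = 16,
) -> None:
    """Blend an antialiased disk into *img* using sub-pixel area weights."""
    r = hole.diameter / 2.0
    # pixel (i, j) centre sits at ((i + 0.5) * spacing, (j + 0.5) * spacing)
    j0 = int(np.floor((hole.center_x - r) / spacing)) - 1
    j1 = int(np.ceil((hole.center_x + r) / spacing)) + 1
    i0 = int(np.floor((hole.center_y - r) / spacing)) - 1
    i1 = int(np.ceil((hole.center_y + r) / spacing)) + 1
    if i0 < 0 or j0 < 0 or i1 >= img.shape[0] or j1 >= img.shape[1]:
        raise ValueError(f"hole {hole.hole_id} not fully inside the image")
    ii = np.arange(i0, i1 + 1)
    jj = np.arange(j0, j1 + 1)
    # sub-sample offsets within a pixel, cell midpoints
    off = (np.arange(supersample) + 0.5) / supersample
    ys = ((ii[:, None] + off[None, :]) * spacing).reshape(-1)  # (ni*ss,)
    xs = ((jj[:, None] + off[None, :]) * spacing).reshape(-1)
    dy2 = (ys - hole.center_y) ** 2
    dx2 = (xs - hole.center_x) ** 2
    inside = (dy2[:, None] + dx2[None, :]) <= r * r
    cov = inside.reshape(len(ii), supersample, len(jj), supersample).mean(axis=(1, 3))
    img[i0 : i1 + 1, j0 : j1 + 1] += cov * (value - background)


def render_phantom(
    spec: PhantomSpec,
    energy: EnergySpec = CONVENTIONAL,
    iodine_conc: float = 18.5,
    patient_size: str = "kg70",
    model: SpectralModel | None = None,
) -> PhantomImage:
    """Render the resolution module under one imaging condition.

    Deterministic for a fixed ``spec.seed`` and condition: repeated calls
    return bit-identical pixels.
    """
    if patient_size not in PATIENT_SIZES:
        raise ValueError(f"unknown patient size {patient_size!r}")
    model = model or default_model()
    background = model.attenuation("pmma", 0.0, energy)
    lumen = model.attenuation("iodine_mixture", iodine_conc, energy)

    holes = layout_holes(spec)
    shape = _image_shape(spec)
    img = np.full(shape, background, dtype=np.float64)
    for hole in holes:
        _paint_disk(img, spec.pixel_spacing, hole, lumen, background)

    if spec.psf_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=spec.psf_sigma / spec.pixel_spacing)

    sigma = spec.noise_sigma(energy, patient_size)
    if sigma > 0:
        rng = np.random.default_rng(
            [spec.seed, _condition_entropy(energy, iodine_conc, patient_size)]
        )
        img = img + rng.normal(0.0, sigma, size=img.shape)

    return PhantomImage(
        pixels=img,
        pixel_spacing=spec.pixel_spacing,
        energy=energy,
        iodine_conc=iodine_conc,
        patient_size=patient_size,
        truth=holes,
    )


def _condition_entropy(energy: EnergySpec, conc: float, size: str) -> int:
    """Stable small integer separating noise streams across conditions."""
    level = 0 if energy.mode == "conventional" else energy.level_keV
    return (level * 1000 + int(round(conc * 10))) * 10 + PATIENT_SIZES.index(size)


# -- plain-text container ------------------------------------------------


class PhantomParseError(ValueError):
    """Raised when a phantom container file cannot be parsed."""


_FORMAT = "coroct-phantom-v1"


def write_image(img: PhantomImage, path: str | Path) -> None:
    """Serialise to JSON.  Pixel floats round-trip bit-exactly."""
    doc = {
        "format": _FORMAT,
        "pixel_spacing": img.pixel_spacing,
        "energy": img.energy.key,
        "iodine_conc": img.iodine_conc,
        "patient_size": img.patient_size,
        "shape": list(img.pixels.shape),
        "pixels": img.pixels.tolist(),
        "truth": [
            {
                "hole_id": h.hole_id,
                "center_x_mm": h.center_x,
                "center_y_mm": h.center_y,
                "diameter_mm": h.diameter,
                "true_area_mm2": h.true_area,
            }
            for h in img.truth
        ],
    }
    Path(path).write_text(json.dumps(doc))


def read_image(path: str | Path) -> PhantomImage:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise PhantomParseError(
            f"{path}: invalid JSON at line {exc.lineno}, column {exc.colno}"
        ) from exc
    if not isinstance(doc, dict) or doc.get("format") != _FORMAT:
        raise PhantomParseError(f"{path}: not a {_FORMAT} container")
    try:
        pixels = np.asarray(doc["pixels"], dtype=np.float64)
        if list(pixels.shape) != list(doc["shape"]):
            raise PhantomParseError(f"{path}: pixel grid does not match declared shape")
        truth = [
            GroundTruthHole(
                int(h["hole_id"]),
                float(h["center_x_mm"]),
                float(h["center_y_mm"]),
                float(h["diameter_mm"]),
                float(h["true_area_mm2"]),
            )
            for h in doc["truth"]
        ]
        return PhantomImage(
            pixels=pixels,
            pixel_spacing=float(doc["pixel_spacing"]),
            energy=EnergySpec.parse(doc["energy"]),
            iodine_conc=float(doc["iodine_conc"]),
            patient_size=str(doc["patient_size"]),
            truth=truth,
        )
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, PhantomParseError):
            raise
        raise PhantomParseError(f"{path}: malformed field ({exc})") from exc
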
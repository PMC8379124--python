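"""Material attenuation as a function of reconstruction energy.

The model maps ``(material, iodine concentration, energy)`` to a mean CT
number (HU).  Tissue values (fat, muscle, trabecular bone) are tabulated
anchors looked up directly.  Iodine/saline mixtures are modelled as affine
in concentration at fixed energy,

    HU(c, E) = base + c * k(E),

where ``base`` is a flat carrier (blood/saline) baseline and the energy
scaling ``k(E)`` is derived from the pooled lumen attenuation anchors,
normalised so that the calibration mixture (18.5 mg I/mL) reads 400 HU on
the conventional reconstruction.  No interpolation between VMI levels is
performed: the energy grid is exactly the set of reconstructed levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "VMI_LEVELS",
    "MATERIALS",
    "EnergySpec",
    "CONVENTIONAL",
    "MaterialSpectrum",
    "CalibrationTable",
    "load_calibration",
    "SpectralModel",
    "attenuation",
    "default_model",
]

#: reconstructed virtual monochromatic levels (keV), 40-130 in 15 keV steps
VMI_LEVELS: tuple[int, ...] = (40, 55, 70, 85, 100, 115, 130)

MATERIALS = frozenset(
    {"iodine_mixture", "pmma", "fat", "muscle", "trabecular_bone", "water"}
)


@dataclass(frozen=True, order=True)
class EnergySpec:
    """A reconstruction energy: conventional 120 kVp or a VMI level in keV."""

    mode: str
    level_keV: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("conventional", "vmi"):
            raise ValueError(f"unknown energy mode {self.mode!r}")
        if self.mode == "conventional":
            if self.level_keV is not None:
                raise ValueError("conventional images carry no keV level")
        elif self.level_keV not in VMI_LEVELS:
            raise ValueError(
                f"VMI level {self.level_keV} keV not in reconstructed grid "
                f"{VMI_LEVELS} (no interpolation)"
            )

    @property
    def key(self) -> str:
        """Stable string key ('conventional' or 'vmi<level>')."""
        return "conventional" if self.mode == "conventional" else f"vmi{self.level_keV}"

    @classmethod
    def vmi(cls, level_keV: int) -> "EnergySpec":
        return cls("vmi", level_keV)

    @classmethod
    def parse(cls, text: str | int) -> "EnergySpec":
        """Parse 'conv', 'conventional', '55', 'vmi55' or an integer level."""
        if isinstance(text, int):
            return cls.vmi(text)
        s = str(text).strip().lower()
        if s in ("conv", "conventional", "ref", "120kvp"):
            return cls("conventional")
        if s.startswith("vmi"):
            s = s[3:]
        if s.endswith("kev"):
            s = s[:-3]
        try:
            return cls.vmi(int(s))
        except ValueError as exc:
            raise ValueError(f"cannot parse energy {text!r}") from exc

    def __str__(self) -> str:
        return self.key


CONVENTIONAL = EnergySpec("conventional")

#: every reconstruction in the study design, conventional first
ALL_ENERGIES: tuple[EnergySpec, ...] = (CONVENTIONAL,) + tuple(
    EnergySpec.vmi(e) for e in VMI_LEVELS
)


@dataclass(frozen=True)
class MaterialSpectrum:
    """CT number of one material/mixture at every reconstructed energy."""

    material: str
    iodine_conc: float
    hu_by_energy: Mapping[EnergySpec, float]


@dataclass(frozen=True)
class CalibrationTable:
    """Plain-text calibration anchors (see ``data/attenuation_anchors.yaml``)."""

    lumen_median: Mapping[str, float]
    lumen_segments: Mapping[str, Mapping[str, Mapping[str, float]]]
    tissues: Mapping[str, Mapping[str, Mapping[str, float]]]
    pmma: Mapping[str, float]
    blood_base_hu: float
    iodine_anchor_conc: float
    iodine_anchor_hu: float
    lumen_iqr: Mapping[str, float] = field(default_factory=dict)


def load_calibration(path: str | Path | None = None) -> CalibrationTable:
    """Load the anchor table from YAML (packaged default if *path* is None)."""
    if path is None:
        text = (
            resources.files("coroct.data")
            .joinpath("attenuation_anchors.yaml")
            .read_text()
        )
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    try:
        return CalibrationTable(
            lumen_median=dict(raw["lumen_median"]["median"]),
            lumen_iqr=dict(raw["lumen_median"].get("iqr", {})),
            lumen_segments={k: dict(v) for k, v in raw["lumen_segments"].items()},
            tissues={k: dict(v) for k, v in raw["tissues"].items()},
            pmma=dict(raw["pmma"]["median"]),
            blood_base_hu=float(raw["blood_base_hu"]),
            iodine_anchor_conc=float(raw["iodine_anchor"]["concentration_mg_ml"]),
            iodine_anchor_hu=float(raw["iodine_anchor"]["hu_conventional"]),
        )
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"calibration file missing section {exc}") from exc


class SpectralModel:
    """Attenuation lookup backed by a :class:`CalibrationTable`."""

    def __init__(self, calibration: CalibrationTable | None = None) -> None:
        self.calibration = calibration or load_calibration()

    # -- iodine scaling ---------------------------------------------------

    def iodine_slope(self, energy: EnergySpec) -> float:
        """HU gained per mg I/mL at *energy*.

        Derived from the pooled lumen anchors: subtract the carrier baseline
        at each energy, then normalise so the calibration mixture reproduces
        its anchor HU on the conventional image.
        """
        cal = self.calibration
        base = cal.blood_base_hu
        ref = cal.lumen_median["conventional"] - base
        if ref <= 0:
            raise ValueError("conventional lumen anchor at or below baseline")
        k_conv = (cal.iodine_anchor_hu - base) / cal.iodine_anchor_conc
        return k_conv * (cal.lumen_median[energy.key] - base) / ref

    # -- main lookup ------------------------------------------------------

    def attenuation(
        self,
        material: str,
        iodine_conc: float = 0.0,
        energy: EnergySpec = CONVENTIONAL,
    ) -> float:
        """Mean CT number (HU) of *material* at *energy*.

        ``iodine_conc`` (mg I/mL) is only meaningful for ``iodine_mixture``
        and must be zero otherwise.
        """
        if material not in MATERIALS:
            raise ValueError(f"unknown material {material!r}")
        if iodine_conc < 0:
            raise ValueError("iodine concentration must be >= 0")
        if material != "iodine_mixture" and iodine_conc != 0:
            raise ValueError(f"{material} cannot carry iodine")
        if not isinstance(energy, EnergySpec):
            energy = EnergySpec.parse(energy)

        cal = self.calibration
        if material == "water":
            return 0.0
        if material == "pmma":
            return float(cal.pmma[energy.key])
        if material in cal.tissues:
            return float(cal.tissues[material]["median"][energy.key])
        # iodine mixture
        return cal.blood_base_hu + iodine_conc * self.iodine_slope(energy)

    def material_spectrum(
        self, material: str, iodine_conc: float = 0.0
    ) -> MaterialSpectrum:
        """Tabulate one material over every reconstructed energy."""
        return MaterialSpectrum(
            material,
            iodine_conc,
            {e: self.attenuation(material, iodine_conc, e) for e in ALL_ENERGIES},
        )


@lru_cache(maxsize=1)
def default_model() -> SpectralModel:
    return SpectralModel()


def attenuation(
    material: str, iodine_conc: float = 0.0, energy: EnergySpec = CONVENTIONAL
) -> float:
    """Module-level convenience using the packaged calibration."""
    return default_model().attenuation(material, iodine_conc, energy)
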
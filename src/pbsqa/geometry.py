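"""Detector geometry for the repurposed daily-QA device.

The device carries a central-axis ionization chamber (det-CAX) used for
imaging/proton-beam isocenter coincidence ("centering") QA, four small
diodes at +/-10 cm on the left-right and sup-inf axes used for spot
positioning QA, and four corner ionization chambers under stepped acrylic
build-ups used for range and output constancy QA.

All lengths are millimetres unless a name says otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping

import yaml


class DetectorId(str, Enum):
    """Detectors of the array that participate in proton daily QA."""

    CAX = "CAX"
    T2 = "T2"
    L2 = "L2"
    R2 = "R2"
    B2 = "B2"
    TL = "TL"
    TR = "TR"
    BL = "BL"
    BR = "BR"


class DetectorRole(str, Enum):
    CENTERING_CHAMBER = "centering_chamber"
    POSITIONING_DIODE = "positioning_diode"
    RANGE_OUTPUT_CHAMBER = "range_output_chamber"


#: Diodes used for spot positioning.
POSITIONING_DIODES = (DetectorId.T2, DetectorId.L2, DetectorId.R2, DetectorId.B2)
#: Chambers in the SOBP plateau whose absolute signal monitors output.
OUTPUT_CHAMBERS = (DetectorId.BL, DetectorId.TR)
#: (distal, plateau) chamber pairs whose signal ratio monitors range.
RANGE_PAIRS = {"left_sobp": (DetectorId.TL, DetectorId.BL),
               "right_sobp": (DetectorId.BR, DetectorId.TR)}

#: Total water-equivalent thickness (cm) of the build-up above each chamber
#: for configuration 1, including the permanent 1 mm plastic-water slab.
CONFIG1_TOTAL_WET_CM = {
    DetectorId.TL: 28.7,
    DetectorId.BL: 27.6,
    DetectorId.TR: 8.1,
    DetectorId.BR: 11.4,
    DetectorId.CAX: 8.7,
}


@dataclass(frozen=True)
class SpotModel:
    """Isotropic 2D Gaussian proton spot at the detector plane.

    Parameters
    ----------
    sigma : float
        Spot standard deviation in mm, assumed equal in both axes (the
        measured ellipticity of in-air spots is below 1.1, so the mean of
        the two axes is used).
    """

    sigma: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValueError(f"spot sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class DetectorAperture:
    """Circular integration region representing a detector's sensitive area."""

    detector_id: DetectorId
    diameter: float
    role: DetectorRole

    def __post_init__(self) -> None:
        if not (self.diameter > 0):
            raise ValueError(f"aperture diameter must be positive, got {self.diameter}")

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter


@dataclass(frozen=True)
class OffsetVector:
    """2D offset between spot centre and detector centre (mm)."""

    dx: float
    dy: float

    @property
    def r(self) -> float:
        return math.hypot(self.dx, self.dy)


@dataclass(frozen=True)
class DetectorSpec:
    """Geometry and beam model attached to one detector."""

    detector_id: DetectorId
    diameter_mm: float
    sigma_mm: float
    role: DetectorRole

    @property
    def aperture(self) -> DetectorAperture:
        return DetectorAperture(self.detector_id, self.diameter_mm, self.role)

    @property
    def spot(self) -> SpotModel:
        return SpotModel(self.sigma_mm)


# Defaults: the CAX chamber has a 13.8 mm sensitive diameter and a large
# (4.8 mm sigma) low-energy spot is used there on purpose, to make the
# chamber signal sensitive to centering errors.  The diodes are modelled as
# 0.8 mm disks and see high-energy (2.2 mm sigma) spots.  The corner
# chambers never enter the spot model; their diameter is only a placeholder.
_DEFAULT_SPECS = (
    DetectorSpec(DetectorId.CAX, 13.8, 4.8, DetectorRole.CENTERING_CHAMBER),
    DetectorSpec(DetectorId.T2, 0.8, 2.2, DetectorRole.POSITIONING_DIODE),
    DetectorSpec(DetectorId.L2, 0.8, 2.2, DetectorRole.POSITIONING_DIODE),
    DetectorSpec(DetectorId.R2, 0.8, 2.2, DetectorRole.POSITIONING_DIODE),
    DetectorSpec(DetectorId.B2, 0.8, 2.2, DetectorRole.POSITIONING_DIODE),
    DetectorSpec(DetectorId.TL, 13.8, 4.8, DetectorRole.RANGE_OUTPUT_CHAMBER),
    DetectorSpec(DetectorId.BL, 13.8, 4.8, DetectorRole.RANGE_OUTPUT_CHAMBER),
    DetectorSpec(DetectorId.TR, 13.8, 4.8, DetectorRole.RANGE_OUTPUT_CHAMBER),
    DetectorSpec(DetectorId.BR, 13.8, 4.8, DetectorRole.RANGE_OUTPUT_CHAMBER),
)


@dataclass
class DetectorGeometry:
    """Full detector layout with per-detector aperture and spot sigma."""

    detectors: Mapping[DetectorId, DetectorSpec] = field(
        default_factory=lambda: {d.detector_id: d for d in _DEFAULT_SPECS}
    )

    def __getitem__(self, detector_id: DetectorId | str) -> DetectorSpec:
        return self.detectors[DetectorId(detector_id)]

    @property
    def positioning_diodes(self) -> list[DetectorSpec]:
        return [s for s in self.detectors.values()
                if s.role is DetectorRole.POSITIONING_DIODE]

    @classmethod
    def default(cls) -> "DetectorGeometry":
        return cls()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DetectorGeometry":
        """Load a geometry config.

        Schema: ``detectors`` is a mapping of detector id to a mapping with
        keys ``diameter_mm``, ``sigma_mm`` and ``role``.
        """
        raw = yaml.safe_load(Path(path).read_text())
        specs = {}
        for det_id, entry in raw["detectors"].items():
            did = DetectorId(det_id)
            specs[did] = DetectorSpec(
                did,
                float(entry["diameter_mm"]),
                float(entry["sigma_mm"]),
                DetectorRole(entry["role"]),
            )
        return cls(specs)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "detectors": {
                s.detector_id.value: {
                    "diameter_mm": s.diameter_mm,
                    "sigma_mm": s.sigma_mm,
                    "role": s.role.value,
                }
                for s in self.detectors.values()
            }
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
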
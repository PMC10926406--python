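"""Ecoclimatic parameter blocks (CLIMEX-style) and their YAML round-trip.

A :class:`ClimexParams` block holds the trapezoidal growth thresholds for
temperature (DV0-DV3, degC) and soil moisture (SM0-SM3, fraction of bucket
capacity), the four linear stress accumulators (cold/heat/dry/wet threshold +
weekly rate), the degree-day requirement per generation (PDD, degC-days above
DV0) and the soil-moisture bucket constants.

The shipped fall-armyworm default sets the limiting low temperature
DV0 = 8.7 degC, the laboratory minimum developmental threshold of the pest on
maize.  Every other value in ``faw_default()`` is a reconstructed working
parametrization in the range used by published CLIMEX studies of the species;
it is NOT a published parameter set and is marked as such in its YAML export.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import yaml

__all__ = ["ClimexParams", "faw_default", "load_params", "save_params"]


@dataclass(frozen=True)
class ClimexParams:
    # temperature growth trapezoid (degC)
    DV0: float = 8.7
    DV1: float = 18.0
    DV2: float = 32.0
    DV3: float = 38.0
    # soil-moisture growth trapezoid (fraction of bucket capacity, 0..2)
    SM0: float = 0.10
    SM1: float = 0.25
    SM2: float = 2.00
    SM3: float = 2.50
    # stress thresholds and accumulation rates (stress units per degC-week,
    # or per moisture-unit-week for the moisture stresses)
    TTCS: float = 5.0
    THCS: float = 1.5
    TTHS: float = 40.0
    THHS: float = 0.20
    SMDS: float = 0.15
    HDS: float = 20.0
    SMWS: float = 2.00
    HWS: float = 20.0
    # degree-days above DV0 per generation
    PDD: float = 455.0
    # soil-moisture bucket
    bucket_capacity: float = 100.0  # mm
    evap_coeff: float = 1.0  # mm per degC-week
    name: str = "unnamed"

    def __post_init__(self) -> None:
        if not (self.DV0 < self.DV1 <= self.DV2 < self.DV3):
            raise ValueError(
                f"temperature thresholds must satisfy DV0 < DV1 <= DV2 < DV3, "
                f"got {self.DV0}, {self.DV1}, {self.DV2}, {self.DV3}"
            )
        if not (self.SM0 < self.SM1 <= self.SM2 < self.SM3):
            raise ValueError(
                f"moisture thresholds must satisfy SM0 < SM1 <= SM2 < SM3, "
                f"got {self.SM0}, {self.SM1}, {self.SM2}, {self.SM3}"
            )
        for rate in ("THCS", "THHS", "HDS", "HWS"):
            if getattr(self, rate) < 0:
                raise ValueError(f"stress rate {rate} must be >= 0")
        if self.PDD <= 0:
            raise ValueError("PDD must be positive")
        if self.bucket_capacity <= 0:
            raise ValueError("bucket_capacity must be positive")
        if self.evap_coeff < 0:
            raise ValueError("evap_coeff must be >= 0")

    def replace(self, **kwargs) -> "ClimexParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


def faw_default() -> ClimexParams:
    """Default fall-armyworm parameter block.

    DV0 = 8.7 degC (laboratory developmental minimum on maize); the remaining
    values are reconstructed defaults, not a published parametrization.
    """
    return ClimexParams(name="faw_default")


def save_params(params: ClimexParams, path) -> None:
    doc = {
        "climex_params": params.to_dict(),
        "provenance": "reconstructed defaults; only DV0 is a published value",
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_params(path) -> ClimexParams:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    block = doc["climex_params"] if "climex_params" in doc else doc
    return ClimexParams(**block)
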
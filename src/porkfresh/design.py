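"""Study design and synthetic-generator configuration.

The default :class:`StudyDesign` mirrors a refrigerated-storage trial of
vacuum-packed pork loin: five storage days (1, 4, 13, 20, 27), five
chemistry replicates per day (n = 25 metabolite/quality rows) and four
hyperspectral observations per replicate (n = 100 spectra).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError

__all__ = ["StudyDesign", "Signature", "TrendSpec", "GeneratorConfig"]


@dataclass(frozen=True)
class StudyDesign:
    storage_days: tuple[int, ...] = (1, 4, 13, 20, 27)
    chem_replicates_per_day: int = 5
    observations_per_replicate: int = 4
    animals: int = 3
    sides: int = 2

    def __post_init__(self) -> None:
        days = tuple(self.storage_days)
        object.__setattr__(self, "storage_days", days)
        if not days:
            raise ConfigurationError("storage_days must be nonempty")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ConfigurationError("storage_days must be strictly increasing")
        for name in (
            "chem_replicates_per_day",
            "observations_per_replicate",
            "animals",
            "sides",
        ):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")

    @property
    def n_chem(self) -> int:
        """Chemistry rows: days x replicates (25 at defaults)."""
        return len(self.storage_days) * self.chem_replicates_per_day

    @property
    def n_spectra(self) -> int:
        """Spectral rows: chemistry rows x observations (100 at defaults)."""
        return self.n_chem * self.observations_per_replicate

    def day_progress(self, day: int) -> float:
        """Storage progress in [0, 1]: 0 at the first day, 1 at the last."""
        d0, d1 = self.storage_days[0], self.storage_days[-1]
        if d1 == d0:
            return 0.0
        return (day - d0) / (d1 - d0)


@dataclass(frozen=True)
class Signature:
    """A Gaussian reflectance band tied to one generating variable.

    ``variable`` may name a metabolite, a quality trait, or a latent
    per-spectrum nuisance factor (any name absent from the tables).
    """

    center_nm: float
    width_nm: float
    variable: str
    amplitude: float

    def __post_init__(self) -> None:
        if self.width_nm <= 0 or self.amplitude < 0:
            raise ConfigurationError(
                f"signature at {self.center_nm} nm needs width > 0 and "
                f"amplitude >= 0"
            )


@dataclass(frozen=True)
class TrendSpec:
    """Storage-day trajectory of one metabolite.

    ``direction`` is one of ``increase``/``decrease``/``flat``; the
    last-day mean moves by ``effect`` (mg/dL, signed by direction) away
    from ``baseline`` (first-day mean, mg/dL).  ``noise_sd`` overrides the
    global replicate-noise fraction with an absolute sd in mg/dL.
    """

    direction: str
    baseline: float
    effect: float
    noise_sd: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("increase", "decrease", "flat"):
            raise ConfigurationError(
                f"unknown trend direction {self.direction!r}"
            )
        if self.baseline < 0 or self.effect < 0:
            raise ConfigurationError("baseline and effect must be >= 0")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")

    @property
    def signed_effect(self) -> float:
        if self.direction == "increase":
            return self.effect
        if self.direction == "decrease":
            return -self.effect
        return 0.0


def _default_signatures() -> tuple[Signature, ...]:
    # Bands anchored at wavelengths where the freshness-linked variables
    # carry importance (721/947/1214 nm and the 1271-1599 nm window), plus
    # broad moisture/fat nuisance bands independent of freshness.
    return (
        Signature(460.0, 80.0, "lysine", 0.0040),
        Signature(947.0, 25.0, "lysine", 0.0030),
        Signature(1214.0, 30.0, "lysine", 0.0030),
        Signature(1500.0, 60.0, "lysine", 0.0035),
        Signature(540.0, 60.0, "malate", 0.0080),
        Signature(947.0, 25.0, "malate", 0.0050),
        Signature(1214.0, 30.0, "malate", 0.0060),
        Signature(1470.0, 50.0, "malate", 0.0070),
        Signature(947.0, 25.0, "methionine", 0.0030),
        Signature(1310.0, 45.0, "methionine", 0.0040),
        Signature(1550.0, 55.0, "methionine", 0.0040),
        Signature(1271.0, 35.0, "niacinamide", 0.0120),
        Signature(1441.0, 45.0, "niacinamide", 0.0100),
        Signature(721.0, 40.0, "moisture", 0.0500),
        Signature(970.0, 60.0, "moisture", 0.0500),
        Signature(1210.0, 60.0, "fat", 0.0400),
        Signature(1650.0, 80.0, "fat", 0.0300),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic generator; one seed fixes every output."""

    seed: int = 0
    metabolite_trends: Mapping[str, TrendSpec] | None = None
    metabolite_noise_frac: float = 0.12
    equation_noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {"TBC": 0.30, "VBN": 0.85}
    )
    signature_library: Sequence[Signature] = field(
        default_factory=_default_signatures
    )
    scatter_sd: float = 0.08
    baseline_slope_sd: float = 2.0e-5
    baseline_offset_sd: float = 0.02
    sensor_noise_sd: float = 0.004
    latent_sd: float = 0.30
    wavelength_start_nm: float = 278.0
    wavelength_end_nm: float = 1724.0
    n_bands: int = 640
    n_pixels: int = 4

    def __post_init__(self) -> None:
        for name in (
            "metabolite_noise_frac",
            "scatter_sd",
            "baseline_slope_sd",
            "baseline_offset_sd",
            "sensor_noise_sd",
            "latent_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if any(sd < 0 for sd in self.equation_noise_sd.values()):
            raise ConfigurationError("equation_noise_sd values must be >= 0")
        if self.n_bands < 2 or self.n_pixels < 1:
            raise ConfigurationError("n_bands >= 2 and n_pixels >= 1 required")
        if self.wavelength_end_nm <= self.wavelength_start_nm:
            raise ConfigurationError("wavelength range must be increasing")

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return np.linspace(
            self.wavelength_start_nm, self.wavelength_end_nm, self.n_bands
        )
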
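"""In-memory containers for spectral data.

Tabular data (metabolite and quality tables) are plain pandas DataFrames
indexed by ``sample_id``; spectra get a thin dataclass so the wavelength
axis, the reflectance matrix and per-sample metadata travel together.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .errors import ConfigurationError

if TYPE_CHECKING:  # pragma: no cover
    from .preprocess import PreprocessingTag

__all__ = ["RawScan", "SpectralDataset"]


@dataclass(frozen=True)
class RawScan:
    """One raw hypercube ROI with its dark and white reference frames.

    All three arrays are (pixels x bands) intensities; ``white`` must
    exceed ``dark`` everywhere for reflectance calibration to be defined.
    """

    sample: np.ndarray
    dark: np.ndarray
    white: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        s, d, w = (
            np.asarray(self.sample, float),
            np.asarray(self.dark, float),
            np.asarray(self.white, float),
        )
        if not (s.shape == d.shape == w.shape):
            raise ConfigurationError(
                f"scan {self.sample_id!r}: S/D/W shapes differ: "
                f"{s.shape}, {d.shape}, {w.shape}"
            )
        if np.any(s < 0):
            raise ConfigurationError(
                f"scan {self.sample_id!r}: negative sample intensities"
            )
        object.__setattr__(self, "sample", s)
        object.__setattr__(self, "dark", d)
        object.__setattr__(self, "white", w)


@dataclass(frozen=True)
class SpectralDataset:
    """Wavelength grid + reflectance matrix + per-sample metadata.

    ``meta`` is indexed by sample_id with columns day/replicate/observation;
    ``preprocessing`` records the transform that produced the values (None
    for raw reflectance).
    """

    wavelengths_nm: np.ndarray
    reflectance: np.ndarray
    meta: pd.DataFrame
    preprocessing: "PreprocessingTag | None" = field(default=None)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, float)
        refl = np.asarray(self.reflectance, float)
        if refl.ndim != 2 or refl.shape[1] != wl.size:
            raise ConfigurationError(
                f"reflectance shape {refl.shape} does not match "
                f"{wl.size} wavelengths"
            )
        if np.any(np.diff(wl) <= 0):
            raise ConfigurationError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(refl)):
            raise ConfigurationError("reflectance contains non-finite values")
        if len(self.meta) != refl.shape[0]:
            raise ConfigurationError(
                f"meta has {len(self.meta)} rows for {refl.shape[0]} spectra"
            )
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "reflectance", refl)

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.wavelengths_nm.size

    def with_reflectance(
        self,
        reflectance: np.ndarray,
        preprocessing: "PreprocessingTag | None" = None,
    ) -> "SpectralDataset":
        return replace(
            self, reflectance=reflectance, preprocessing=preprocessing
        )

    def subset(self, sample_ids) -> "SpectralDataset":
        """Row subset (and reorder) by sample_id."""
        pos = self.meta.index.get_indexer(sample_ids)
        if np.any(pos < 0):
            missing = [s for s, p in zip(sample_ids, pos) if p < 0]
            raise KeyError(f"sample ids not in dataset: {missing[:5]}")
        return replace(
            self,
            reflectance=self.reflectance[pos],
            meta=self.meta.iloc[pos],
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide table: meta columns then one column per wavelength (nm)."""
        spec = pd.DataFrame(
            self.reflectance,
            index=self.meta.index,
            columns=[f"{w:.10g}" for w in self.wavelengths_nm],
        )
        return pd.concat([self.meta, spec], axis=1)
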
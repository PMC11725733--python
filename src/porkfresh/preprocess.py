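"""Reflectance calibration, wavelength trimming and scatter correction.

Implements the spectral preprocessing grid compared by the pipeline:
raw, SNV (row standardization), unit-norm normalization and MSC against a
mean reference spectrum.  MSC is fit on the calibration set and the frozen
reference is reused for prediction data, so no information leaks across
the split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datasets import RawScan, SpectralDataset
from .errors import CalibrationError, ConfigurationError, DomainError

__all__ = [
    "PreprocessingTag",
    "PREPROCESSING_NAMES",
    "calibrate_reflectance",
    "trim_wavelengths",
    "roi_mean_spectrum",
    "snv",
    "msc",
    "l2_normalize",
    "apply_preprocessing",
]

PREPROCESSING_NAMES = ("raw", "snv", "normalize", "msc")

_MSC_GAIN_TOL = 1e-12


@dataclass(frozen=True)
class PreprocessingTag:
    """Which transform a spectra matrix went through.

    For MSC the reference spectrum (calibration-set column mean, unless
    given explicitly) is frozen on the tag so prediction data are corrected
    against the calibration reference.
    """

    name: str
    msc_reference: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.name not in PREPROCESSING_NAMES:
            raise ConfigurationError(
                f"unknown preprocessing {self.name!r}; "
                f"expected one of {PREPROCESSING_NAMES}"
            )
        if self.name != "msc" and self.msc_reference is not None:
            raise ConfigurationError(
                f"msc_reference only applies to 'msc', not {self.name!r}"
            )
        if self.msc_reference is not None:
            object.__setattr__(
                self, "msc_reference", np.asarray(self.msc_reference, float)
            )

    @property
    def is_fitted(self) -> bool:
        return self.name != "msc" or self.msc_reference is not None


def calibrate_reflectance(scan: RawScan) -> np.ndarray:
    """(S - D) / (W - D) per pixel-band; values are not clipped.

    Out-of-[0, 1] values are counted and reported through a warning; any
    pixel-band with white <= dark raises naming the first offending index.
    """
    denom = scan.white - scan.dark
    bad = denom <= 0
    if np.any(bad):
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise CalibrationError(
            f"white reference does not exceed dark reference at "
            f"(pixel, band) = {idx}"
        )
    refl = (scan.sample - scan.dark) / denom
    n_out = int(np.count_nonzero((refl < 0) | (refl > 1)))
    if n_out:
        warnings.warn(
            f"{n_out} calibrated reflectance values fall outside [0, 1]",
            stacklevel=2,
        )
    return refl


def trim_wavelengths(
    ds: SpectralDataset, low_nm: float, high_nm: float
) -> SpectralDataset:
    """Keep bands with low <= wavelength <= high; metadata unchanged."""
    if low_nm >= high_nm:
        raise DomainError(f"low ({low_nm}) must be below high ({high_nm})")
    keep = (ds.wavelengths_nm >= low_nm) & (ds.wavelengths_nm <= high_nm)
    if not np.any(keep):
        raise DomainError(
            f"no bands in [{low_nm}, {high_nm}] nm; grid spans "
            f"[{ds.wavelengths_nm[0]}, {ds.wavelengths_nm[-1]}]"
        )
    return SpectralDataset(
        ds.wavelengths_nm[keep],
        ds.reflectance[:, keep],
        ds.meta,
        ds.preprocessing,
    )


def roi_mean_spectrum(cube: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-band arithmetic mean over masked pixels of a (pixels x bands)
    calibrated cube."""
    cube = np.asarray(cube, float)
    mask = np.asarray(mask, bool)
    if mask.shape[0] != cube.shape[0]:
        raise DomainError(
            f"mask length {mask.shape[0]} != pixel count {cube.shape[0]}"
        )
    if not np.any(mask):
        raise DomainError("ROI mask selects no pixels")
    return cube[mask].mean(axis=0)


def snv(x: np.ndarray) -> np.ndarray:
    """Standard normal variate: each row centered and scaled to unit
    sample standard deviation (n-1 denominator)."""
    x = np.atleast_2d(np.asarray(x, float))
    sd = x.std(axis=1, ddof=1)
    if np.any(sd == 0):
        row = int(np.flatnonzero(sd == 0)[0])
        raise DomainError(f"SNV undefined for constant spectrum (row {row})")
    return (x - x.mean(axis=1, keepdims=True)) / sd[:, None]


def msc(x: np.ndarray, reference: np.ndarray | str = "mean") -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    Each row is regressed as x ~ a + b*reference by least squares and
    returned as (x - a)/b.  ``reference="mean"`` uses the column mean of x
    itself (calibration usage; for prediction data pass the stored
    calibration reference).  Rows with |b| below tolerance are flagged via
    a warning and returned intercept-centered only.
    """
    x = np.atleast_2d(np.asarray(x, float))
    if isinstance(reference, str):
        if reference != "mean":
            raise DomainError(f"unknown MSC reference {reference!r}")
        ref = x.mean(axis=0)
    else:
        ref = np.asarray(reference, float)
    if ref.shape != (x.shape[1],):
        raise DomainError(
            f"reference has {ref.size} bands, spectra have {x.shape[1]}"
        )
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom == 0:
        raise DomainError("MSC reference spectrum has zero variance")

    b = (x - x.mean(axis=1, keepdims=True)) @ ref_c / denom
    a = x.mean(axis=1) - b * ref.mean()
    out = np.empty_like(x)
    degenerate = np.abs(b) < _MSC_GAIN_TOL
    ok = ~degenerate
    out[ok] = (x[ok] - a[ok, None]) / b[ok, None]
    if np.any(degenerate):
        out[degenerate] = x[degenerate] - a[degenerate, None]
        warnings.warn(
            f"MSC gain below tolerance for {int(degenerate.sum())} row(s); "
            f"left reference-centered",
            stacklevel=2,
        )
    return out


def l2_normalize(x: np.ndarray) -> np.ndarray:
    """Scale each row to unit Euclidean norm."""
    x = np.atleast_2d(np.asarray(x, float))
    norm = np.linalg.norm(x, axis=1)
    if np.any(norm == 0):
        row = int(np.flatnonzero(norm == 0)[0])
        raise DomainError(f"cannot normalize all-zero spectrum (row {row})")
    return x / norm[:, None]


def apply_preprocessing(
    ds: SpectralDataset, tag: PreprocessingTag | str
) -> SpectralDataset:
    """Dispatch raw/snv/normalize/msc; the resolved tag is recorded on the
    returned dataset.

    An unfitted MSC tag (no stored reference) is fit on ``ds`` itself —
    calibration usage.  A fitted tag applies the stored reference, which is
    how prediction data must be transformed.
    """
    if isinstance(tag, str):
        tag = PreprocessingTag(tag)
    if tag.name == "raw":
        return ds.with_reflectance(ds.reflectance.copy(), tag)
    if tag.name == "snv":
        return ds.with_reflectance(snv(ds.reflectance), tag)
    if tag.name == "normalize":
        return ds.with_reflectance(l2_normalize(ds.reflectance), tag)
    # msc
    if tag.msc_reference is None:
        tag = PreprocessingTag("msc", ds.reflectance.mean(axis=0))
    return ds.with_reflectance(msc(ds.reflectance, tag.msc_reference), tag)
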
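"""Hyperspectral indices and the regression used to validate cover estimates.

Image-derived cover fractions are validated against two standard indices
computed from field reflectance spectra (350–2500 nm):

NDVI
    ``(rho_800 - rho_670) / (rho_800 + rho_670)`` — the normalized
    difference between near-infrared and red reflectance, a proxy for
    green biomass; regressed against extracted GV cover.

CAI
    ``100 * (0.5 * (rho_2030 + rho_2210) - rho_2100)`` — the depth of the
    2100 nm cellulose–lignin absorption feature relative to its shoulders,
    a proxy for dry plant material. Because CAI responds to *all*
    non-photosynthetic vegetation, it is regressed against SDM cover plus
    litter cover (NPV), not SDM alone.

Reflectance at a named wavelength is obtained by linear interpolation
between the bracketing samples; on 1 nm instrument grids this is exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SpectrumError

__all__ = ["Spectrum", "SpectralIndices", "RegressionResult", "ndvi", "cai",
           "spectral_indices", "validate_cover"]

WAVELENGTH_RANGE = (350.0, 2500.0)


@dataclass(frozen=True)
class Spectrum:
    """A wavelength (nm) → reflectance series.

    Wavelengths must be strictly increasing within 350–2500 nm;
    reflectance is dimensionless in [0, 1].
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    name: str | None = None

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=np.float64)
        rf = np.asarray(self.reflectance, dtype=np.float64)
        if wl.shape != rf.shape or wl.ndim != 1 or wl.size < 2:
            raise SpectrumError("wavelengths and reflectance must be equal-length 1-D")
        if np.any(np.diff(wl) <= 0):
            raise SpectrumError("wavelengths must be strictly increasing")
        if wl[0] < WAVELENGTH_RANGE[0] or wl[-1] > WAVELENGTH_RANGE[1]:
            raise SpectrumError(
                f"wavelengths must lie within {WAVELENGTH_RANGE} nm"
            )
        if rf.min() < 0 or rf.max() > 1:
            raise SpectrumError("reflectance must lie in [0, 1]")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "reflectance", rf)

    def value_at(self, wavelength: float) -> float:
        """Reflectance at a wavelength, linearly interpolated."""
        wl = self.wavelengths
        if wavelength < wl[0] or wavelength > wl[-1]:
            raise SpectrumError(
                f"{self.name or 'spectrum'}: wavelength {wavelength} nm outside "
                f"sampled range [{wl[0]}, {wl[-1]}]"
            )
        return float(np.interp(wavelength, wl, self.reflectance))

    @classmethod
    def from_file(cls, path: str | Path) -> "Spectrum":
        """Read a two-column (wavelength_nm, reflectance) text/CSV file.

        A single header line is detected and skipped automatically.
        """
        path = Path(path)
        try:
            df = pd.read_csv(path, sep=None, engine="python", header=None,
                             comment="#")
        except Exception as exc:
            raise SpectrumError(f"{path}: cannot parse spectrum ({exc})") from exc
        # drop a header row if the first row is not numeric
        try:
            float(df.iloc[0, 0])
        except (TypeError, ValueError):
            df = df.iloc[1:]
        if df.shape[1] < 2:
            raise SpectrumError(f"{path}: expected two columns")
        wl = df.iloc[:, 0].astype(float).to_numpy()
        rf = df.iloc[:, 1].astype(float).to_numpy()
        return cls(wavelengths=wl, reflectance=rf, name=path.stem)

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(
            {"wavelength_nm": self.wavelengths, "reflectance": self.reflectance}
        ).to_csv(path, index=False)
        return path


@dataclass(frozen=True)
class SpectralIndices:
    ndvi: float
    cai: float


def ndvi(spec: Spectrum) -> float:
    """Normalized difference vegetation index from 800 and 670 nm."""
    r800 = spec.value_at(800.0)
    r670 = spec.value_at(670.0)
    denom = r800 + r670
    if denom == 0:
        raise SpectrumError("NDVI undefined: rho_800 + rho_670 = 0")
    return (r800 - r670) / denom


def cai(spec: Spectrum) -> float:
    """Cellulose absorption index from 2030, 2100 and 2210 nm."""
    return 100.0 * (
        0.5 * (spec.value_at(2030.0) + spec.value_at(2210.0)) - spec.value_at(2100.0)
    )


def spectral_indices(spec: Spectrum) -> SpectralIndices:
    return SpectralIndices(ndvi=ndvi(spec), cai=cai(spec))


@dataclass(frozen=True)
class RegressionResult:
    """Ordinary least squares of cover on a spectral index."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def validate_cover(covers, indices) -> RegressionResult:
    """Regress cover (percent) on a spectral index across quadrats.

    The p-value is the two-sided t-test on the slope with n - 2 degrees
    of freedom.
    """
    y = np.asarray(covers, dtype=np.float64)
    x = np.asarray(indices, dtype=np.float64)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("covers and indices must be equal-length 1-D sequences")
    n = y.size
    if n < 3:
        raise ValueError(f"need at least 3 paired observations, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("index values are all equal (degenerate predictor)")
    if np.ptp(y) == 0:
        # constant response: slope 0, no explained variance
        return RegressionResult(
            slope=0.0, intercept=float(y[0]), r_squared=0.0, p_value=1.0, n=n
        )
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        p_value=float(fit.pvalue),
        n=n,
    )
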
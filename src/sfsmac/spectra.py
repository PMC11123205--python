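"""Spectrometer-frame data model and reflectance arithmetic.

A single-fiber spectrometer records a time x wavelength intensity matrix
(the tissue backscatter, Ib).  Reflectance is obtained by normalizing Ib
between two reference spectra taken with the fiber tip in glycerine
(index-matched, ~zero specular return, Ig) and in air (large index
mismatch, Ia):

    R(t, lambda) = (Ib(t, lambda) - Ig(lambda)) / (Ia(lambda) - Ig(lambda))

Reflectance is deliberately *not* clamped to [0, 1]: excursions outside
that range are exactly the motion-artifact phenomenon being measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectralFrame",
    "ReferenceSpectra",
    "ReflectanceSeries",
    "compute_reflectance",
    "band_sum",
    "resample_spectrum",
    "choose_reference",
    "read_frame_csv",
    "write_frame_csv",
    "read_reference_csv",
    "write_reference_csv",
]

#: fixed decimal formatting used by all CSV writers (bit-stable round trip)
CSV_FLOAT_FORMAT = "%.10g"


@dataclass
class SpectralFrame:
    """Time-resolved spectrometer frame: intensities indexed (time, wavelength).

    Attributes
    ----------
    wavelengths : strictly increasing grid in nm.
    times : non-decreasing sample timestamps in s.
    intensities : (n_times, n_wavelengths) detector counts.
    meta : free-form acquisition metadata (exposure_ms, spectra_averaged,
        sampling_rate_hz, ...).
    """

    wavelengths: np.ndarray
    times: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.ndim != 1 or self.times.ndim != 1:
            raise ValueError("wavelengths and times must be 1-D")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")
        if self.intensities.shape != (self.times.size, self.wavelengths.size):
            raise ValueError(
                f"intensities shape {self.intensities.shape} does not match "
                f"(n_times={self.times.size}, n_wavelengths={self.wavelengths.size})"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    @property
    def sampling_rate(self) -> float:
        """Sampling rate in Hz, from metadata or the median time step."""
        if "sampling_rate_hz" in self.meta:
            return float(self.meta["sampling_rate_hz"])
        if self.times.size < 2:
            raise ValueError("cannot infer sampling rate from fewer than 2 samples")
        dt = float(np.median(np.diff(self.times)))
        if dt <= 0:
            raise ValueError("cannot infer sampling rate from repeated timestamps")
        return 1.0 / dt

    def band_indices(self, lambda_p: float, lambda_q: float) -> np.ndarray:
        """Indices of grid wavelengths inside the closed band [lambda_p, lambda_q]."""
        if lambda_p > lambda_q:
            raise ValueError("band must satisfy lambda_p <= lambda_q")
        idx = np.nonzero(
            (self.wavelengths >= lambda_p) & (self.wavelengths <= lambda_q)
        )[0]
        if idx.size == 0:
            raise ValueError(
                f"band [{lambda_p:g}, {lambda_q:g}] nm contains no grid points; "
                f"grid spans [{self.wavelengths[0]:g}, {self.wavelengths[-1]:g}] nm"
            )
        return idx

    def column(self, lam: float) -> np.ndarray:
        """Intensity time series at the grid wavelength closest to ``lam``."""
        j = int(np.argmin(np.abs(self.wavelengths - lam)))
        return self.intensities[:, j]


@dataclass
class ReferenceSpectra:
    """Air and glycerine reference spectra on a common wavelength grid."""

    wavelengths: np.ndarray
    intensity_air: np.ndarray
    intensity_glycerine: np.ndarray

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensity_air = np.asarray(self.intensity_air, dtype=float)
        self.intensity_glycerine = np.asarray(self.intensity_glycerine, dtype=float)
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        n = self.wavelengths.size
        if self.intensity_air.shape != (n,) or self.intensity_glycerine.shape != (n,):
            raise ValueError("reference spectra must match the wavelength grid length")


@dataclass
class ReflectanceSeries:
    """Dimensionless reflectance, (time, wavelength); not clamped to [0, 1]."""

    wavelengths: np.ndarray
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("reflectance values must be finite")
        if self.values.shape != (self.times.size, self.wavelengths.size):
            raise ValueError("values shape must be (n_times, n_wavelengths)")


def resample_spectrum(values, from_grid, to_grid) -> np.ndarray:
    """Linearly interpolate a spectrum onto a new grid (no extrapolation).

    Exact at shared grid points; raises if ``to_grid`` leaves the closed
    hull of ``from_grid``.
    """
    values = np.asarray(values, dtype=float)
    from_grid = np.asarray(from_grid, dtype=float)
    to_grid = np.asarray(to_grid, dtype=float)
    if to_grid.min() < from_grid.min() or to_grid.max() > from_grid.max():
        raise ValueError(
            f"requested grid [{to_grid.min():g}, {to_grid.max():g}] nm extends "
            f"outside the source hull [{from_grid.min():g}, {from_grid.max():g}] nm; "
            "extrapolation is not performed"
        )
    return np.interp(to_grid, from_grid, values)


def _refs_on_grid(refs: ReferenceSpectra, grid: np.ndarray) -> ReferenceSpectra:
    if refs.wavelengths.shape == grid.shape and np.array_equal(refs.wavelengths, grid):
        return refs
    lo = max(refs.wavelengths[0], grid[0])
    hi = min(refs.wavelengths[-1], grid[-1])
    if lo > hi:
        raise ValueError("reference and frame wavelength grids do not overlap")
    if grid[0] < refs.wavelengths[0] or grid[-1] > refs.wavelengths[-1]:
        raise ValueError(
            "frame grid extends outside the reference grid; cannot interpolate "
            "references without extrapolation"
        )
    return ReferenceSpectra(
        grid,
        resample_spectrum(refs.intensity_air, refs.wavelengths, grid),
        resample_spectrum(refs.intensity_glycerine, refs.wavelengths, grid),
    )


def compute_reflectance(frame: SpectralFrame, refs: ReferenceSpectra) -> ReflectanceSeries:
    """Reflectance R = (Ib - Ig) / (Ia - Ig) on the frame's native grid.

    References are linearly interpolated onto the frame grid if needed (the
    frame carries the time-resolved signal of interest and is never
    resampled).  A vanishing denominator at any used wavelength is an error.
    """
    refs = _refs_on_grid(refs, frame.wavelengths)
    denom = refs.intensity_air - refs.intensity_glycerine
    bad = np.nonzero(denom == 0.0)[0]
    if bad.size:
        raise ZeroDivisionError(
            f"air and glycerine references coincide at "
            f"{frame.wavelengths[bad[0]]:g} nm (zero denominator)"
        )
    values = (frame.intensities - refs.intensity_glycerine) / denom
    return ReflectanceSeries(frame.wavelengths, frame.times, values)


def band_sum(frame: SpectralFrame, lambda_p: float, lambda_q: float) -> np.ndarray:
    """Sum of intensities over grid points in the closed band [lambda_p, lambda_q].

    Returns one value per time sample.  Band edges are inclusive.
    """
    idx = frame.band_indices(lambda_p, lambda_q)
    return frame.intensities[:, idx].sum(axis=1)


def plausibility_score(frame: SpectralFrame, refs: ReferenceSpectra) -> float:
    """Physical-plausibility score of a reference pair (lower is better).

    Fraction of reflectance values outside [0, 1.5] plus the mean negative
    excursion.  Serves as a documented proxy for the instrument's
    "lower fitting error" criterion, whose empirical tissue model is out of
    scope here; a custom criterion can be supplied to :func:`choose_reference`.
    """
    r = compute_reflectance(frame, refs).values
    outside = np.mean((r < 0.0) | (r > 1.5))
    negative = np.mean(np.maximum(0.0, -r))
    return float(outside + negative)


def choose_reference(
    frame: SpectralFrame,
    candidates: Sequence[ReferenceSpectra],
    criterion: Callable[[SpectralFrame, ReferenceSpectra], float] | None = None,
) -> ReferenceSpectra:
    """Pick the reference pair minimizing ``criterion`` (default plausibility).

    Deterministic tie-break: the first candidate in list order wins.
    """
    if len(candidates) == 0:
        raise ValueError("no reference candidates supplied")
    criterion = criterion or plausibility_score
    scores = [criterion(frame, c) for c in candidates]
    return candidates[int(np.argmin(scores))]


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

def _sep_for(path, sep):
    if sep is not None:
        return sep
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_frame_csv(path, sep: str | None = None) -> SpectralFrame:
    """Read a wide frame: header ``time_s,<w1>,<w2>,...`` (CSV or TSV)."""
    df = pd.read_csv(path, sep=_sep_for(path, sep))
    if df.columns[0] != "time_s":
        raise ValueError("wide frame files must start with a 'time_s' column")
    wavelengths = np.array([float(c) for c in df.columns[1:]])
    order = np.argsort(wavelengths)
    return SpectralFrame(
        wavelengths[order],
        df["time_s"].to_numpy(float),
        df.iloc[:, 1:].to_numpy(float)[:, order],
    )


def write_frame_csv(frame: SpectralFrame, path, sep: str | None = None) -> None:
    """Write the wide frame dialect with fixed decimal formatting."""
    df = pd.DataFrame(frame.intensities, columns=[f"{w:g}" for w in frame.wavelengths])
    df.insert(0, "time_s", frame.times)
    df.to_csv(path, sep=_sep_for(path, sep), index=False, float_format=CSV_FLOAT_FORMAT)


def read_reference_csv(path, sep: str | None = None) -> ReferenceSpectra:
    """Read ``wavelength_nm,intensity_air,intensity_glycerine``."""
    df = pd.read_csv(path, sep=_sep_for(path, sep))
    return ReferenceSpectra(
        df["wavelength_nm"].to_numpy(float),
        df["intensity_air"].to_numpy(float),
        df["intensity_glycerine"].to_numpy(float),
    )


def write_reference_csv(refs: ReferenceSpectra, path, sep: str | None = None) -> None:
    df = pd.DataFrame(
        {
            "wavelength_nm": refs.wavelengths,
            "intensity_air": refs.intensity_air,
            "intensity_glycerine": refs.intensity_glycerine,
        }
    )
    df.to_csv(path, sep=_sep_for(path, sep), index=False, float_format=CSV_FLOAT_FORMAT)
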
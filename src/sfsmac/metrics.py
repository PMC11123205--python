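"""Quantitative artifact and hemodynamics metrics.

The dissimilarity metric (DM) measures the normalized instantaneous
deviation of the hemodynamics-insensitive band intensity (670-680 nm by
default) from its local window mean:

    DM(i) = (S(i) - M(i)) / M(i),

with S the band-summed intensity and M the mean of S over a centered
window of N samples.  DM is exactly scale invariant, so detector gain and
exposure cancel; its standard deviation over a chunk (sigma_DM)
summarizes motion-artifact magnitude.

Spectral shifts are compared with the root-mean-square deviation
RMSD = sqrt(mean((test - ref)^2)); perfusion is tracked as the percent
change of backscatter relative to a baseline period, and correction
quality as region-wise mean squared error between percent-change traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import SpectralFrame, band_sum

__all__ = [
    "DMSeries",
    "SigmaDMReport",
    "RegionSpec",
    "dm_series",
    "sigma_dm",
    "rmsd",
    "percent_backscatter_change",
    "region_mse",
    "DEFAULT_BAND",
]

#: hemodynamics-insensitive reference band (nm)
DEFAULT_BAND = (670.0, 680.0)


@dataclass
class DMSeries:
    """Dissimilarity-metric time series with its computation parameters."""

    times: np.ndarray
    values: np.ndarray
    window_n: int
    band: tuple

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class SigmaDMReport:
    """Per-chunk standard deviation of DM."""

    chunk_starts: np.ndarray
    chunk_sigma: np.ndarray
    chunk_length: float

    def __post_init__(self):
        self.chunk_starts = np.asarray(self.chunk_starts, dtype=float)
        self.chunk_sigma = np.asarray(self.chunk_sigma, dtype=float)


@dataclass
class RegionSpec:
    """Ordered, non-overlapping analysis regions, half-open [start, end) in s."""

    boundaries: list

    def __post_init__(self):
        b = [(float(a), float(z)) for a, z in self.boundaries]
        for a, z in b:
            if z <= a:
                raise ValueError(f"region ({a:g}, {z:g}) has non-positive length")
        for (a1, z1), (a2, z2) in zip(b, b[1:]):
            if a2 < z1:
                raise ValueError("regions must be ordered and non-overlapping")
        self.boundaries = b


def _centered_window_mean(s: np.ndarray, window_n: int) -> np.ndarray:
    """Mean over a centered window of window_n samples, truncated at edges.

    For even window_n the extra sample is taken from the past.  The
    normalization always uses the actual in-window sample count.
    """
    n = s.size
    half_back = window_n // 2
    half_fwd = window_n - 1 - half_back
    csum = np.concatenate(([0.0], np.cumsum(s)))
    i = np.arange(n)
    lo = np.maximum(0, i - half_back)
    hi = np.minimum(n, i + half_fwd + 1)
    return (csum[hi] - csum[lo]) / (hi - lo)


def dm_series(
    frame: SpectralFrame,
    band: tuple = DEFAULT_BAND,
    window_n: int | None = None,
) -> DMSeries:
    """Dissimilarity metric of a frame over the reference band.

    ``window_n`` defaults to 1 s of samples at the frame's sampling rate.
    Raises on a zero window mean (normalization undefined).
    """
    if window_n is None:
        window_n = max(2, int(round(frame.sampling_rate)))
    if window_n < 2:
        raise ValueError("window_n must be >= 2")
    s = band_sum(frame, *band)
    m = _centered_window_mean(s, window_n)
    zero = np.nonzero(m == 0.0)[0]
    if zero.size:
        raise ZeroDivisionError(
            f"window mean of the band intensity is zero at sample {zero[0]}"
        )
    return DMSeries(frame.times, (s - m) / m, window_n, tuple(band))


def sigma_dm(
    dm: DMSeries,
    chunk_seconds: float,
    sampling_rate: float | None = None,
    stride_seconds: float | None = None,
) -> SigmaDMReport:
    """Standard deviation of DM over consecutive chunks.

    Chunks are non-overlapping by default (``stride_seconds`` exposes an
    overlapping stride); a trailing partial chunk is dropped.  Sample
    standard deviation (ddof=1) is used.
    """
    if chunk_seconds <= 0:
        raise ValueError("chunk_seconds must be positive")
    if sampling_rate is None:
        dt = np.diff(dm.times)
        if dt.size == 0 or np.median(dt) <= 0:
            raise ValueError("cannot infer sampling rate from DM timestamps")
        sampling_rate = 1.0 / float(np.median(dt))
    n_chunk = int(round(chunk_seconds * sampling_rate))
    if n_chunk < 2:
        raise ValueError("chunks must contain at least 2 DM samples")
    n_stride = n_chunk if stride_seconds is None else int(round(stride_seconds * sampling_rate))
    if n_stride < 1:
        raise ValueError("stride must be at least one sample")
    starts, sigmas = [], []
    for i0 in range(0, dm.values.size - n_chunk + 1, n_stride):
        seg = dm.values[i0 : i0 + n_chunk]
        starts.append(dm.times[i0])
        sigmas.append(np.std(seg, ddof=1))
    if not starts:
        raise ValueError("no complete chunk fits in the DM series")
    return SigmaDMReport(np.array(starts), np.array(sigmas), chunk_seconds)


def rmsd(test, ref, literal_printed_form: bool = False) -> float:
    """Root mean square deviation between two spectra on a shared grid.

    sqrt(mean((test - ref)^2)).  ``literal_printed_form`` instead evaluates
    sqrt((1/N) * (sum of deviations)^2) = |sum(test - ref)| / sqrt(N), kept
    only for comparison with a non-standard rendering of the formula.
    """
    test = np.asarray(test, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if test.shape != ref.shape:
        raise ValueError(f"length mismatch: {test.shape} vs {ref.shape}")
    if test.size == 0:
        raise ValueError("spectra must contain at least one point")
    d = test - ref
    if literal_printed_form:
        return float(abs(np.sum(d)) / np.sqrt(d.size))
    return float(np.sqrt(np.mean(d**2)))


def percent_backscatter_change(
    times,
    series,
    baseline: tuple,
    negate: bool = False,
) -> np.ndarray:
    """Percent change of a counts series relative to a baseline-interval mean.

    ``baseline`` is a half-open interval [t0, t1) in seconds.  ``negate``
    returns the negative (perfusion convention: increased perfusion lowers
    backscatter).
    """
    times = np.asarray(times, dtype=float)
    series = np.asarray(series, dtype=float)
    t0, t1 = baseline
    mask = (times >= t0) & (times < t1)
    if not mask.any():
        raise ValueError(f"baseline [{t0:g}, {t1:g}) s contains no samples")
    mu = series[mask].mean()
    if mu == 0.0:
        raise ZeroDivisionError("baseline mean is zero")
    pct = 100.0 * (series - mu) / mu
    return -pct if negate else pct


def region_mse(times, trace_a, trace_b, regions: RegionSpec) -> np.ndarray:
    """Mean squared difference between two traces within each region.

    Traces must share the sampling grid; regions are half-open [start, end).
    """
    times = np.asarray(times, dtype=float)
    a = np.asarray(trace_a, dtype=float)
    b = np.asarray(trace_b, dtype=float)
    if a.shape != b.shape or a.shape != times.shape:
        raise ValueError("traces and times must share one sampling grid")
    out = []
    for t0, t1 in regions.boundaries:
        mask = (times >= t0) & (times < t1)
        if not mask.any():
            raise ValueError(f"region [{t0:g}, {t1:g}) s contains no samples")
        out.append(np.mean((a[mask] - b[mask]) ** 2))
    return np.array(out)
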
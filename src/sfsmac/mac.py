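"""Regression-based motion-artifact correction (MAC) for single-fiber spectra.

Model
-----
The light measured by the fiber is the sum of Fresnel reflections at the
optical interfaces and the tissue backscatter:

    Ib = I*RaNf + I*TaNf*T*RfFb*T*TfNa + RSF*Iin*TbFf*T*TfNa,
    Iin = I*TaNf*T*TfFb,

where R/T are interface reflection/transmission coefficients (near/far
fiber ends; air/fiber/brain media), T the fiber transmission and RSF the
tissue reflectance.  In the 670-680 nm band tissue backscatter contributes
little, so intensity there tracks only the interface (Fresnel) terms — the
very terms perturbed by motion.  The mean-removed band intensity

    n_hat(t) = S_band(t) - <S_band>

is therefore a motion-artifact proxy, and each wavelength channel is
corrected by subtracting its least-squares projection on the proxy:

    Ic(lambda, t) = I(lambda, t) - m(lambda) * n_hat(t),

with m(lambda) the OLS slope of I(lambda, .) on the proxy (intercept
included).  Since n_hat is zero-mean, correction preserves the temporal
mean of every channel exactly.

:class:`MotionArtifactCorrector` implements this as a scikit-learn
transformer over (n_times, n_wavelengths) matrices; :func:`fit_mac` /
:func:`apply_mac` wrap it for :class:`~sfsmac.spectra.SpectralFrame`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .metrics import DEFAULT_BAND
from .spectra import SpectralFrame, band_sum

__all__ = [
    "InterfacePathModel",
    "MacModel",
    "MotionArtifactCorrector",
    "forward_intensity",
    "artifact_proxy",
    "fit_mac",
    "apply_mac",
]


# ---------------------------------------------------------------------------
# Optical-interface intensity model
# ---------------------------------------------------------------------------

@dataclass
class InterfacePathModel:
    """Per-wavelength interface coefficients of the fiber light path.

    All coefficients are dimensionless in [0, 1] except the incident
    spectrum.  Naming: R/T from medium x to y at location z (N = near fiber
    end, F = far end; a/f/b = air/fiber/brain).
    """

    incident_spectrum: np.ndarray
    near_reflection: np.ndarray        # RaNf
    near_transmission_in: np.ndarray   # TaNf
    near_transmission_out: np.ndarray  # TfNa
    far_reflection_brain: np.ndarray   # RfFb
    far_transmission_in: np.ndarray    # TfFb
    far_transmission_out: np.ndarray   # TbFf
    fiber_transmission: np.ndarray     # T
    tissue_reflectance: np.ndarray     # RSF

    def __post_init__(self):
        arrays = {
            name: np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            for name in (
                "incident_spectrum", "near_reflection", "near_transmission_in",
                "near_transmission_out", "far_reflection_brain",
                "far_transmission_in", "far_transmission_out",
                "fiber_transmission", "tissue_reflectance",
            )
        }
        n = arrays["incident_spectrum"].size
        for name, arr in arrays.items():
            if arr.size != n:
                raise ValueError(f"{name} is not on the shared wavelength grid")
            setattr(self, name, arr)
        for name in (
            "near_reflection", "near_transmission_in", "near_transmission_out",
            "far_reflection_brain", "far_transmission_in", "far_transmission_out",
            "fiber_transmission", "tissue_reflectance",
        ):
            arr = arrays[name]
            if np.any(arr < 0.0) or np.any(arr > 1.0):
                raise ValueError(f"coefficient {name} outside [0, 1]")
        if np.any(self.fiber_transmission <= 0.0):
            raise ValueError("fiber_transmission must be in (0, 1]")


def forward_intensity(model: InterfacePathModel):
    """Predicted measured intensity and its three interface terms.

    Returns ``(total, terms)`` where ``terms`` is a dict with the near-end
    specular term, the far-end Fresnel term and the tissue-backscatter term.
    """
    i0 = model.incident_spectrum
    t = model.fiber_transmission
    term_near = i0 * model.near_reflection
    term_far = (
        i0 * model.near_transmission_in * t * model.far_reflection_brain
        * t * model.near_transmission_out
    )
    i_in_brain = i0 * model.near_transmission_in * t * model.far_transmission_in
    term_tissue = (
        model.tissue_reflectance * i_in_brain * model.far_transmission_out
        * t * model.near_transmission_out
    )
    total = term_near + term_far + term_tissue
    return total, {
        "near_specular": term_near,
        "far_fresnel": term_far,
        "tissue_backscatter": term_tissue,
        "intensity_entering_brain": i_in_brain,
    }


# ---------------------------------------------------------------------------
# Proxy and correction
# ---------------------------------------------------------------------------

def artifact_proxy(frame: SpectralFrame, band: tuple = DEFAULT_BAND) -> np.ndarray:
    """Zero-mean motion-artifact proxy: band-summed intensity minus its mean."""
    s = band_sum(frame, *band)
    return s - s.mean()


@dataclass
class MacModel:
    """Fitted per-wavelength artifact scale factors m(lambda).

    ``proxy_mean`` is the temporal mean of the band-summed intensity at fit
    time; ``fit_diagnostics`` carries per-wavelength R^2 and residual scale.
    """

    band: tuple
    wavelengths: np.ndarray
    m: np.ndarray
    proxy_mean: float
    fit_diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.m = np.asarray(self.m, dtype=float)
        if not np.all(np.isfinite(self.m)):
            raise ValueError("scale factors m must be finite")

    def to_json(self, path=None) -> str:
        doc = {
            "band_nm": list(self.band),
            "wavelengths_nm": self.wavelengths.tolist(),
            "m": self.m.tolist(),
            "proxy_mean": self.proxy_mean,
            "fit_diagnostics": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.fit_diagnostics.items()
            },
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "MacModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        return cls(
            tuple(doc["band_nm"]),
            np.asarray(doc["wavelengths_nm"], dtype=float),
            np.asarray(doc["m"], dtype=float),
            float(doc["proxy_mean"]),
            doc.get("fit_diagnostics", {}),
        )


class MotionArtifactCorrector(TransformerMixin, BaseEstimator):
    """Common-mode motion-artifact removal as a scikit-learn transformer.

    Operates on matrices ``X`` of shape (n_times, n_wavelengths).  ``fit``
    regresses every wavelength channel on the zero-mean reference-band
    proxy; ``transform`` subtracts the scaled proxy recomputed from the
    input (so correction always preserves the input's temporal means).

    Parameters
    ----------
    wavelengths : array-like or None
        Grid in nm labelling the columns of ``X``.  If None, ``band`` is
        interpreted as a (start, stop) *column index* range instead.
    band : tuple, default (670, 680)
        Closed reference band in nm (or column indices, see above).  The
        band columns are corrected like any other channel.
    single_wavelength : bool, default False
        Use only the band's upper-edge column (the instrument convention
        "680 nm represents the range") instead of the band sum.
    robust : bool, default False
        Fit m with a Huber M-estimator instead of OLS; guards against the
        spike outliers known to defeat plain regression.
    sample_mask : array-like of bool or None
        Optional mask restricting the regression to artifact-rich samples.

    Attributes
    ----------
    m_ : ndarray of shape (n_wavelengths,) -- fitted scale factors.
    proxy_mean_ : float -- temporal mean of the band sum at fit time.
    r2_ : ndarray -- per-wavelength coefficient of determination.
    residual_scale_ : ndarray -- per-wavelength residual standard deviation.
    """

    def __init__(
        self,
        wavelengths=None,
        band: tuple = DEFAULT_BAND,
        single_wavelength: bool = False,
        robust: bool = False,
        sample_mask=None,
    ):
        self.wavelengths = wavelengths
        self.band = band
        self.single_wavelength = single_wavelength
        self.robust = robust
        self.sample_mask = sample_mask

    # -- helpers -----------------------------------------------------------
    def _band_columns(self, n_cols: int) -> np.ndarray:
        lo, hi = self.band
        if lo > hi:
            raise ValueError("band must satisfy lower <= upper")
        if self.wavelengths is None:
            cols = np.arange(int(lo), int(hi) + 1)
            cols = cols[(cols >= 0) & (cols < n_cols)]
        else:
            w = np.asarray(self.wavelengths, dtype=float)
            if w.size != n_cols:
                raise ValueError(
                    f"wavelength grid length {w.size} does not match X columns {n_cols}"
                )
            cols = np.nonzero((w >= lo) & (w <= hi))[0]
        if cols.size == 0:
            raise ValueError(f"reference band {self.band} selects no columns")
        if self.single_wavelength:
            cols = cols[-1:]
        return cols

    def _proxy(self, X: np.ndarray) -> np.ndarray:
        s = X[:, self._band_columns(X.shape[1])].sum(axis=1)
        return s

    @staticmethod
    def _validate(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_times, n_wavelengths)")
        if not np.all(np.isfinite(X)):
            raise ValueError("X must be finite")
        return X

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y=None):
        X = self._validate(X)
        if X.shape[0] < 3:
            raise ValueError("need at least 3 time samples to fit the regression")
        mask = (
            np.ones(X.shape[0], dtype=bool)
            if self.sample_mask is None
            else np.asarray(self.sample_mask, dtype=bool)
        )
        s = self._proxy(X)
        self.proxy_mean_ = float(s.mean())
        x = s[mask] - s[mask].mean()
        if np.allclose(x, 0.0):
            raise ValueError("no artifact signal to regress on (zero-variance proxy)")
        Y = X[mask]
        if self.robust:
            from sklearn.linear_model import HuberRegressor

            m = np.empty(X.shape[1])
            for j in range(X.shape[1]):
                m[j] = HuberRegressor().fit(x[:, None], Y[:, j]).coef_[0]
        else:
            # vectorized OLS with intercept: slope = cov(x, y) / var(x)
            xc = x - x.mean()
            m = xc @ (Y - Y.mean(axis=0)) / (xc @ xc)
        fitted = np.outer(x - x.mean(), m) + Y.mean(axis=0)
        resid = Y - fitted
        ss_res = (resid**2).sum(axis=0)
        ss_tot = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
        self.m_ = m
        self.r2_ = r2
        self.residual_scale_ = resid.std(axis=0, ddof=2 if Y.shape[0] > 2 else 0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "m_")
        X = self._validate(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} columns but the corrector was fitted "
                f"with {self.n_features_in_}"
            )
        s = self._proxy(X)
        n_hat = s - s.mean()
        return X - np.outer(n_hat, self.m_)

    # transformer leaves the wavelength grid unchanged
    def get_feature_names_out(self, input_features=None):
        if input_features is not None:
            return np.asarray(input_features, dtype=object)
        if self.wavelengths is not None:
            return np.asarray([f"{w:g}" for w in self.wavelengths], dtype=object)
        return np.asarray(
            [f"x{j}" for j in range(getattr(self, "n_features_in_", 0))], dtype=object
        )


# ---------------------------------------------------------------------------
# Frame-level wrappers
# ---------------------------------------------------------------------------

def fit_mac(
    frame: SpectralFrame,
    band: tuple = DEFAULT_BAND,
    single_wavelength: bool = False,
    robust: bool = False,
    sample_mask=None,
) -> MacModel:
    """Fit the per-wavelength artifact scale factors on a frame."""
    est = MotionArtifactCorrector(
        wavelengths=frame.wavelengths,
        band=band,
        single_wavelength=single_wavelength,
        robust=robust,
        sample_mask=sample_mask,
    ).fit(frame.intensities)
    return MacModel(
        tuple(band),
        frame.wavelengths,
        est.m_,
        est.proxy_mean_,
        {"r2": est.r2_, "residual_scale": est.residual_scale_},
    )


def apply_mac(frame: SpectralFrame, model: MacModel) -> SpectralFrame:
    """Apply a fitted correction: Ic = I - m(lambda) * n_hat(t).

    The proxy n_hat is recomputed from the input frame with the model's
    band, so the temporal mean of every channel is preserved exactly.
    """
    if frame.wavelengths.size != model.wavelengths.size or not np.allclose(
        frame.wavelengths, model.wavelengths
    ):
        raise ValueError("frame wavelength grid differs from the fit-time grid")
    n_hat = artifact_proxy(frame, model.band)
    corrected = frame.intensities - np.outer(n_hat, model.m)
    return SpectralFrame(frame.wavelengths, frame.times, corrected, dict(frame.meta))
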
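"""Wavelength-resolved optical properties of brain tissue and the fiber probe.

The tissue model follows the standard diffuse-reflectance parameterization:
absorption from whole-blood hemoglobin scaled by a blood-volume fraction,

    mu_a(lambda) = BV * (sO2 * mu_HbO(lambda) + (1 - sO2) * mu_Hb(lambda)),

scattering from a diluted intralipid power law with a Henyey-Greenstein
anisotropy that falls linearly with wavelength,

    g(lambda) = 1.1 - 0.58e-3 * lambda[nm],

and refractive indices from Cauchy's formula n = A + B/lambda^2 + C/lambda^4.

Hemoglobin extinction values are interpolated (PCHIP) from a bundled
compilation of published landmark values; see
``data/hemoglobin_extinction_synthetic.csv``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

__all__ = [
    "ExtinctionTable",
    "TissueOptics",
    "load_extinction_table",
    "load_optical_constants",
    "mu_a_static",
    "mu_s_intralipid",
    "anisotropy_g",
    "cauchy_index",
    "refractive_index",
    "fresnel_reflectance",
]

_LN10 = np.log(10.0)

#: validity window of the intralipid anisotropy/scattering fits (nm)
INTRALIPID_VALID_NM = (400.0, 790.0)


def load_optical_constants() -> dict:
    """Return the bundled optical-constants document (Cauchy + intralipid)."""
    with resources.files("sfsmac.data").joinpath("optical_constants.json").open() as fh:
        return json.load(fh)


class ExtinctionTable:
    """Molar extinction of oxy-/deoxyhemoglobin with smooth interpolation.

    Values are in cm^-1/M (decadic).  ``mu_hbo``/``mu_hb`` convert to
    whole-blood absorption coefficients in mm^-1 at the documented total
    hemoglobin concentration (150 g/L).
    """

    def __init__(self, wavelengths_nm, eps_hbo2, eps_hb, hb_molar: float):
        self.wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
        self.eps_hbo2 = np.asarray(eps_hbo2, dtype=float)
        self.eps_hb = np.asarray(eps_hb, dtype=float)
        self._hb_molar = float(hb_molar)
        self._f_hbo2 = PchipInterpolator(self.wavelengths_nm, self.eps_hbo2)
        self._f_hb = PchipInterpolator(self.wavelengths_nm, self.eps_hb)

    @property
    def lambda_min(self) -> float:
        return float(self.wavelengths_nm[0])

    @property
    def lambda_max(self) -> float:
        return float(self.wavelengths_nm[-1])

    def _check(self, lam) -> np.ndarray:
        lam = np.asarray(lam, dtype=float)
        if np.any(lam < self.lambda_min) or np.any(lam > self.lambda_max):
            raise ValueError(
                f"wavelength outside extinction table range "
                f"[{self.lambda_min:g}, {self.lambda_max:g}] nm"
            )
        return lam

    def epsilon_hbo2(self, lam):
        """Decadic molar extinction of HbO2 (cm^-1/M)."""
        return self._f_hbo2(self._check(lam))

    def epsilon_hb(self, lam):
        """Decadic molar extinction of Hb (cm^-1/M)."""
        return self._f_hb(self._check(lam))

    def mu_from_concentration(self, lam, c_hbo2_uM, c_hb_uM):
        """Absorption coefficient (mm^-1) for given species concentrations (uM)."""
        lam = self._check(lam)
        mu_cm = _LN10 * (
            self._f_hbo2(lam) * c_hbo2_uM * 1e-6 + self._f_hb(lam) * c_hb_uM * 1e-6
        )
        return mu_cm / 10.0

    def mu_hbo(self, lam):
        """Whole-blood absorption coefficient of fully oxygenated blood (mm^-1)."""
        return _LN10 * self.epsilon_hbo2(lam) * self._hb_molar / 10.0

    def mu_hb(self, lam):
        """Whole-blood absorption coefficient of fully deoxygenated blood (mm^-1)."""
        return _LN10 * self.epsilon_hb(lam) * self._hb_molar / 10.0


_TABLE: ExtinctionTable | None = None


def load_extinction_table() -> ExtinctionTable:
    """Load (and cache) the bundled hemoglobin extinction table."""
    global _TABLE
    if _TABLE is None:
        path = resources.files("sfsmac.data").joinpath(
            "hemoglobin_extinction_synthetic.csv"
        )
        with path.open() as fh:
            data = pd.read_csv(fh, comment="#")
        consts = load_optical_constants()["whole_blood"]
        hb_molar = consts["hemoglobin_g_per_L"] / consts["hemoglobin_molar_mass_g"]
        _TABLE = ExtinctionTable(
            data["wavelength_nm"], data["eps_hbo2_cm1_M"], data["eps_hb_cm1_M"],
            hb_molar,
        )
    return _TABLE


def mu_a_static(lam, rho: float, so2: float, table: ExtinctionTable | None = None):
    """Static tissue absorption mu_a = BV*(sO2*muHbO + (1-sO2)*muHb) in mm^-1.

    Parameters
    ----------
    lam : wavelength(s) in nm, within the extinction table range.
    rho : blood volume fraction in [0, 1].
    so2 : hemoglobin oxygen saturation in [0, 1].
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("blood volume fraction rho must be in [0, 1]")
    if not 0.0 <= so2 <= 1.0:
        raise ValueError("oxygen saturation so2 must be in [0, 1]")
    table = table or load_extinction_table()
    return rho * (so2 * table.mu_hbo(lam) + (1.0 - so2) * table.mu_hb(lam))


def mu_s_intralipid(lam, dilution: float | None = None):
    """Intralipid scattering coefficient (mm^-1) at the simulated dilution.

    Power law for the 10% stock, mu_s = 16 * (lambda/1000 nm)^-2.4 mm^-1,
    scaled by the configured lipid dilution (default 0.2, i.e. a 2%-lipid
    tissue phantom).  Warns outside the 400-790 nm validity window.
    """
    consts = load_optical_constants()["intralipid"]
    if dilution is None:
        dilution = consts["lipid_dilution"]
    lam = np.asarray(lam, dtype=float)
    lo, hi = INTRALIPID_VALID_NM
    if np.any(lam < lo) or np.any(lam > hi):
        warnings.warn(
            f"wavelength outside intralipid model validity [{lo:g}, {hi:g}] nm",
            stacklevel=2,
        )
    law = consts["mu_s_power_law"]
    mu = dilution * law["prefactor_mm1"] * (lam / 1000.0) ** law["exponent"]
    return mu if mu.ndim else float(mu)


def anisotropy_g(lam):
    """Henyey-Greenstein anisotropy g(lambda) = 1.1 - 0.58e-3 * lambda[nm]."""
    lam = np.asarray(lam, dtype=float)
    lo, hi = INTRALIPID_VALID_NM
    if np.any(lam < lo) or np.any(lam > hi):
        warnings.warn(
            f"wavelength outside anisotropy model validity [{lo:g}, {hi:g}] nm",
            stacklevel=2,
        )
    g = 1.1 - 0.58e-3 * lam
    if np.any(g <= -1.0) or np.any(g >= 1.0):
        raise ValueError("anisotropy g outside (-1, 1); wavelength far out of range")
    return g if g.ndim else float(g)


def cauchy_index(lam, coefficients):
    """Refractive index n = A + B/lambda^2 + C/lambda^4 (lambda in nm).

    ``coefficients`` is (A, B, C) or a mapping with keys A/B/C.
    """
    if isinstance(coefficients, dict):
        a, b, c = coefficients["A"], coefficients["B"], coefficients["C"]
    else:
        a, b, c = coefficients
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("wavelength must be positive")
    n = a + b / lam**2 + c / lam**4
    return n if n.ndim else float(n)


def refractive_index(lam, medium: str):
    """Cauchy index for a named medium: brain_tissue, fused_silica_fiber, glycerine, air."""
    coeffs = load_optical_constants()["cauchy_index"]
    if medium not in coeffs:
        raise KeyError(f"unknown medium {medium!r}; choose from {sorted(coeffs)}")
    return cauchy_index(lam, coeffs[medium])


def fresnel_reflectance(n1, n2, incidence_cosine):
    """Unpolarized Fresnel power reflectance for n1 -> n2 at cos(theta_i).

    Returns the average of the s- and p-polarized reflectances; total
    internal reflection returns 1.  Fully vectorized.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    ci = np.asarray(incidence_cosine, dtype=float)
    if np.any(n1 <= 0) or np.any(n2 <= 0):
        raise ValueError("refractive indices must be positive")
    if np.any(ci < 0) or np.any(ci > 1):
        raise ValueError("incidence cosine must be in [0, 1]")
    si2 = 1.0 - ci**2
    st2 = (n1 / n2) ** 2 * si2
    with np.errstate(invalid="ignore"):
        ct = np.sqrt(np.maximum(1.0 - st2, 0.0))
        rs = ((n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)) ** 2
        rp = ((n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)) ** 2
        r = 0.5 * (rs + rp)
    r = np.where(st2 >= 1.0, 1.0, r)
    return r if r.ndim else float(r)


@dataclass
class TissueOptics:
    """Homogeneous brain-tissue optical model probed by the fiber.

    Parameters
    ----------
    blood_volume_fraction : fraction of tissue volume occupied by whole blood.
    oxygen_saturation : hemoglobin sO2 in [0, 1].
    lipid_dilution : intralipid dilution setting the scattering magnitude.
    """

    blood_volume_fraction: float = 0.01
    oxygen_saturation: float = 0.35
    lipid_dilution: float = 0.2
    extinction_table: ExtinctionTable = field(default_factory=load_extinction_table)

    def __post_init__(self):
        if not 0.0 <= self.blood_volume_fraction <= 1.0:
            raise ValueError("blood_volume_fraction must be in [0, 1]")
        if not 0.0 <= self.oxygen_saturation <= 1.0:
            raise ValueError("oxygen_saturation must be in [0, 1]")

    def mu_a(self, lam):
        """Absorption coefficient (mm^-1)."""
        return mu_a_static(
            lam, self.blood_volume_fraction, self.oxygen_saturation,
            self.extinction_table,
        )

    def mu_s(self, lam):
        """Scattering coefficient (mm^-1)."""
        return mu_s_intralipid(lam, self.lipid_dilution)

    def g(self, lam):
        """Scattering anisotropy."""
        return anisotropy_g(lam)

    def n(self, lam):
        """Tissue refractive index."""
        return refractive_index(lam, "brain_tissue")

    def mean_free_path(self, lam):
        """1/(mu_a + mu_s) in mm."""
        mt = self.mu_a(lam) + self.mu_s(lam)
        return 1.0 / mt
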
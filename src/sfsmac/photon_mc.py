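"""Weighted Monte Carlo photon transport for an angled-tip fiber in tissue.

Geometry
--------
A homogeneous tissue block (absorbing outer boundaries) is probed by an
optical fiber entering through the top face, its angle-polished tip
embedded ``tip_depth`` below the surface.  The tip face is a tilted disc
(16 deg by default); photons are launched uniformly over the core within
the numerical-aperture cone, refracted through the face by Snell's law
with unpolarized Fresnel weight splitting.  The fiber body above the tip
plane is not modelled: photons crossing the tip plane outside the core
disc continue in tissue (documented approximation).

Transport
---------
Exponential step sampling at the mean free path 1/(mu_a+mu_s), continuous
absorption by the single-scattering albedo, Henyey-Greenstein deflection,
and Russian roulette below weight 1e-4 with survival probability 0.1.
Photon weight is conserved: detected + absorbed + escaped = launched
within the roulette tolerance on every run, and a fixed seed gives a
bit-identical result.

Detection
---------
Weight re-entering the core face within the fiber acceptance cone
(sin(theta) <= NA/n_fiber internally) is detected.  A transmission
coating at the fiber/brain interface multiplies every crossing weight by
tau, so the detected tissue return scales ~tau^2 (two crossings) while
the specular face reflection is unaffected -- the mechanistic model of a
motion artifact.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from . import optics
from .metrics import rmsd
from .optics import TissueOptics, refractive_index
from .spectra import ReferenceSpectra

__all__ = [
    "FiberGeometry",
    "CoatingSpec",
    "DetectionResult",
    "hg_sample",
    "specular_return",
    "simulate_backscatter",
    "simulate_references",
    "simulate_slab_transmission",
    "sensitivity_scan",
    "transmission_shift_experiment",
]

ROULETTE_WEIGHT = 1e-4
ROULETTE_SURVIVAL = 0.1
_MAX_STEPS = 500_000


@dataclass
class FiberGeometry:
    """Probe geometry: 400 um core, 0.53 NA, 16 deg polished tip by default."""

    core_diameter_um: float = 400.0
    numerical_aperture: float = 0.53
    tip_angle_deg: float = 16.0
    tip_depth_mm: float = 1.0
    block_mm: tuple = (10.0, 10.0, 10.0)
    fiber_medium: str = "fused_silica_fiber"

    def __post_init__(self):
        if not 0.0 <= self.tip_angle_deg < 45.0:
            raise ValueError("tip angle must be in [0, 45) degrees")
        n550 = refractive_index(550.0, self.fiber_medium)
        if self.numerical_aperture >= n550:
            raise ValueError("numerical aperture must be below the fiber index")
        if self.tip_depth_mm <= 0 or self.tip_depth_mm >= self.block_mm[2]:
            raise ValueError("fiber tip must lie inside the tissue block")

    @property
    def core_radius_mm(self) -> float:
        return self.core_diameter_um / 2000.0

    def n_fiber(self, lam):
        return refractive_index(lam, self.fiber_medium)

    def check_block(self, tissue: TissueOptics, lam: float) -> None:
        """Warn when the block is small relative to the transport envelope."""
        mfp = tissue.mean_free_path(lam)
        if min(self.block_mm) < 20.0 * mfp:
            warnings.warn(
                f"tissue block {self.block_mm} mm is smaller than 20 mean free "
                f"paths ({20 * mfp:.2f} mm) at {lam:g} nm",
                stacklevel=2,
            )


@dataclass
class CoatingSpec:
    """Transmission coating at the fiber/brain interface (motion-artifact model)."""

    transmission: float = 1.0
    location: str = "fiber_brain_interface"

    def __post_init__(self):
        if not 0.0 < self.transmission <= 1.0:
            raise ValueError("coating transmission must be in (0, 1]")


@dataclass
class DetectionResult:
    """Weight ledger of one simulation run (weights per launched photon count)."""

    launched_photons: int
    detected_weight: float
    detected_specular: float
    detected_diffuse: float
    absorbed_weight: float
    escaped_weight: float
    sum_w2_diffuse: float
    seed: int
    wavelength: float

    @property
    def ledger_error(self) -> float:
        """Relative imbalance of detected+absorbed+escaped vs launched."""
        total = self.detected_weight + self.absorbed_weight + self.escaped_weight
        return abs(total - self.launched_photons) / self.launched_photons

    @property
    def detected_fraction(self) -> float:
        return self.detected_weight / self.launched_photons

    @property
    def diffuse_std_error(self) -> float:
        """MC standard error of the diffuse detected fraction."""
        n = self.launched_photons
        mean = self.detected_diffuse / n
        var = self.sum_w2_diffuse / n - mean**2
        return math.sqrt(max(var, 0.0) / n)


# ---------------------------------------------------------------------------
# Elementary samplers
# ---------------------------------------------------------------------------

def hg_sample(g: float, rng: np.random.Generator, size=None):
    """Draw scattering deflection cosines from the Henyey-Greenstein law.

    For g = 0 the distribution is isotropic (cos uniform on [-1, 1]); the
    first moment is E[cos theta] = g.
    """
    if not -1.0 < g < 1.0:
        raise ValueError("anisotropy g must be in (-1, 1)")
    u = rng.random(size)
    if abs(g) < 1e-8:
        return 1.0 - 2.0 * u
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    return (1.0 + g * g - tmp * tmp) / (2.0 * g)


def specular_return(
    n_fiber: float,
    n_medium: float,
    tip_angle_deg: float,
    numerical_aperture: float,
    n_grid: int = 512,
) -> float:
    """Deterministic (quadrature) specular return of the angled tip face.

    Launch directions uniform in solid angle within the acceptance cone are
    Fresnel-reflected at the tilted face; the returned value is the weight
    fraction whose reflected direction stays within the acceptance cone.
    The angle polish displaces the specular lobe by twice the tip angle, so
    only part of the cone edge returns -- the reason angled tips suppress
    back-reflection.
    """
    beta = math.radians(tip_angle_deg)
    sin_acc = numerical_aperture / n_fiber
    cos_max = math.sqrt(1.0 - sin_acc**2)
    # midpoint grid over (cos theta, phi), uniform in solid angle
    mu = cos_max + (np.arange(n_grid) + 0.5) / n_grid * (1.0 - cos_max)
    phi = (np.arange(n_grid) + 0.5) / n_grid * 2.0 * np.pi
    mu, phi = np.meshgrid(mu, phi, indexing="ij")
    st = np.sqrt(1.0 - mu**2)
    d = np.stack([st * np.cos(phi), st * np.sin(phi), mu])
    nrm = np.array([math.sin(beta), 0.0, math.cos(beta)])
    ci = np.einsum("i,i...->...", nrm, d)
    r_frac = optics.fresnel_reflectance(n_fiber, n_medium, np.clip(ci, 0.0, 1.0))
    # reflected direction and acceptance test (travelling back along -z)
    rz = d[2] - 2.0 * ci * nrm[2]
    accepted = -rz >= cos_max
    return float(np.mean(np.where(accepted, r_frac, 0.0)))


# ---------------------------------------------------------------------------
# Transport kernel
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _transport_kernel(
    seed, n_photons, mu_a, mu_s, g, n_med, n_fib,
    core_radius, beta, cos_acc, tip_z, hx, hy, lz, tau,
):  # pragma: no cover - exercised via python wrappers
    np.random.seed(seed)
    mu_t = mu_a + mu_s
    albedo = mu_s / mu_t if mu_t > 0.0 else 1.0
    nx = math.sin(beta)
    nz = math.cos(beta)
    e1x = math.cos(beta)
    e1z = -math.sin(beta)
    sin_max_f = math.sqrt(max(0.0, 1.0 - cos_acc * cos_acc))
    det_spec = 0.0
    det_diff = 0.0
    absorbed = 0.0
    escaped = 0.0
    sum_w2 = 0.0
    eps = 1e-9
    for _ in range(n_photons):
        # --- launch position on the tilted core disc
        r = core_radius * math.sqrt(np.random.random())
        ang = 2.0 * math.pi * np.random.random()
        ux = r * math.cos(ang)
        uy = r * math.sin(ang)
        px = ux * e1x
        py = uy
        pz = tip_z + ux * e1z
        # --- launch direction inside the fiber (uniform solid angle in cone)
        mu = cos_acc + np.random.random() * (1.0 - cos_acc)
        st = math.sqrt(max(0.0, 1.0 - mu * mu))
        phi = 2.0 * math.pi * np.random.random()
        dx = st * math.cos(phi)
        dy = st * math.sin(phi)
        dz = mu
        # --- refraction through the face (fiber -> medium)
        ci = dx * nx + dz * nz
        sin_t2 = (n_fib / n_med) ** 2 * (1.0 - ci * ci)
        if sin_t2 >= 1.0:
            # total internal reflection: stays in fiber
            rz = dz - 2.0 * ci * nz
            if -rz >= cos_acc:
                det_spec += 1.0
            else:
                escaped += 1.0
            continue
        ct = math.sqrt(1.0 - sin_t2)
        rs = (n_fib * ci - n_med * ct) / (n_fib * ci + n_med * ct)
        rp = (n_fib * ct - n_med * ci) / (n_fib * ct + n_med * ci)
        refl = 0.5 * (rs * rs + rp * rp)
        # specular part reflected back inside the fiber
        rz = dz - 2.0 * ci * nz
        if -rz >= cos_acc:
            det_spec += refl
        else:
            escaped += refl
        # coating loss on the way in
        escaped += (1.0 - refl) * (1.0 - tau)
        w = (1.0 - refl) * tau
        if w <= 0.0:
            continue
        eta = n_fib / n_med
        k = eta * ci - ct
        dx = eta * dx - k * nx
        dz = eta * dz - k * nz
        dy = eta * dy
        nrm_d = math.sqrt(dx * dx + dy * dy + dz * dz)
        dx /= nrm_d
        dy /= nrm_d
        dz /= nrm_d
        px += eps * nx
        pz += eps * nz
        # --- random walk in tissue
        alive = True
        steps = 0
        while alive:
            steps += 1
            if steps > 500000:
                absorbed += w
                break
            if mu_t > 0.0:
                xi = np.random.random()
                while xi <= 0.0:
                    xi = np.random.random()
                s = -math.log(xi) / mu_t
            else:
                s = 1.0e9
            # distance to block boundary
            t_exit = 1.0e30
            if dx > 0.0:
                t_exit = min(t_exit, (hx - px) / dx)
            elif dx < 0.0:
                t_exit = min(t_exit, (-hx - px) / dx)
            if dy > 0.0:
                t_exit = min(t_exit, (hy - py) / dy)
            elif dy < 0.0:
                t_exit = min(t_exit, (-hy - py) / dy)
            if dz > 0.0:
                t_exit = min(t_exit, (lz - pz) / dz)
            elif dz < 0.0:
                t_exit = min(t_exit, (0.0 - pz) / dz)
            # distance to the tip face plane (only when heading into it)
            dn = dx * nx + dz * nz
            t_face = 1.0e30
            if dn < 0.0:
                dist = (px - 0.0) * nx + (pz - tip_z) * nz
                if dist > 0.0:
                    tf = dist / (-dn)
                    fx = px + tf * dx
                    fy = py + tf * dy
                    fz = pz + tf * dz
                    rho2 = (fx * fx) + fy * fy + (fz - tip_z) * (fz - tip_z)
                    # rho measured in the face plane through (0,0,tip_z)
                    if rho2 <= core_radius * core_radius:
                        t_face = tf
            if t_face <= s and t_face <= t_exit:
                # fiber/brain interface from the tissue side
                px += t_face * dx
                py += t_face * dy
                pz += t_face * dz
                ci2 = -dn
                sin_t2 = (n_med / n_fib) ** 2 * (1.0 - ci2 * ci2)
                ct2 = math.sqrt(max(0.0, 1.0 - sin_t2))
                rs = (n_med * ci2 - n_fib * ct2) / (n_med * ci2 + n_fib * ct2)
                rp = (n_med * ct2 - n_fib * ci2) / (n_med * ct2 + n_fib * ci2)
                refl2 = 0.5 * (rs * rs + rp * rp)
                trans = w * (1.0 - refl2) * tau
                escaped += w * (1.0 - refl2) * (1.0 - tau)
                # refract into the fiber and test the acceptance cone
                eta2 = n_med / n_fib
                k2 = eta2 * ci2 - ct2
                tdx = eta2 * dx + k2 * nx
                tdz = eta2 * dz + k2 * nz
                tdy = eta2 * dy
                nrm_t = math.sqrt(tdx * tdx + tdy * tdy + tdz * tdz)
                if -tdz / nrm_t >= cos_acc:
                    det_diff += trans
                    sum_w2 += trans * trans
                else:
                    escaped += trans
                w *= refl2
                dx -= 2.0 * dn * nx
                dz -= 2.0 * dn * nz
                px += eps * nx
                pz += eps * nz
                if w < 1e-4:
                    if np.random.random() < 0.1:
                        w /= 0.1
                    else:
                        absorbed += w
                        alive = False
                continue
            if t_exit < s:
                escaped += w
                break
            # scattering event
            px += s * dx
            py += s * dy
            pz += s * dz
            absorbed += w * (1.0 - albedo)
            w *= albedo
            if abs(g) < 1e-8:
                cth = 1.0 - 2.0 * np.random.random()
            else:
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * np.random.random())
                cth = (1.0 + g * g - tmp * tmp) / (2.0 * g)
            sth = math.sqrt(max(0.0, 1.0 - cth * cth))
            psi = 2.0 * math.pi * np.random.random()
            cpsi = math.cos(psi)
            spsi = math.sin(psi)
            if abs(dz) > 0.99999:
                dx = sth * cpsi
                dy = sth * spsi
                dz = cth if dz > 0.0 else -cth
            else:
                den = math.sqrt(1.0 - dz * dz)
                ndx = sth * (dx * dz * cpsi - dy * spsi) / den + dx * cth
                ndy = sth * (dy * dz * cpsi + dx * spsi) / den + dy * cth
                ndz = -sth * cpsi * den + dz * cth
                dx, dy, dz = ndx, ndy, ndz
            if w < 1e-4:
                if np.random.random() < 0.1:
                    w /= 0.1
                else:
                    absorbed += w
                    alive = False
    return det_spec, det_diff, absorbed, escaped, sum_w2


@njit(cache=True, fastmath=True)
def _pathlength_kernel(
    seed, n_photons, mu_s, g, n_med, n_fib,
    core_radius, beta, cos_acc, tip_z, hx, hy, lz,
):  # pragma: no cover - exercised via python wrappers
    """Analog-scattering transport recording detected packet pathlengths.

    Steps are sampled at the scattering length 1/mu_s and no absorption is
    applied in flight; each detected packet records its geometric weight
    and total tissue pathlength L, so the detected weight for *any*
    absorption coefficient follows by weighting with exp(-mu_a * L)
    (continuous-absorption estimator).  This pairs absorbing and
    scattering-only conditions on identical photon paths.
    """
    np.random.seed(seed)
    nx = math.sin(beta)
    nz = math.cos(beta)
    e1x = math.cos(beta)
    e1z = -math.sin(beta)
    det_spec = 0.0
    escaped = 0.0
    absorbed = 0.0
    cap = n_photons
    pk_w = np.zeros(cap)
    pk_l = np.zeros(cap)
    n_pk = 0
    lost_pk = 0.0
    eps = 1e-9
    for _ in range(n_photons):
        r = core_radius * math.sqrt(np.random.random())
        ang = 2.0 * math.pi * np.random.random()
        ux = r * math.cos(ang)
        uy = r * math.sin(ang)
        px = ux * e1x
        py = uy
        pz = tip_z + ux * e1z
        mu = cos_acc + np.random.random() * (1.0 - cos_acc)
        st = math.sqrt(max(0.0, 1.0 - mu * mu))
        phi = 2.0 * math.pi * np.random.random()
        dx = st * math.cos(phi)
        dy = st * math.sin(phi)
        dz = mu
        ci = dx * nx + dz * nz
        sin_t2 = (n_fib / n_med) ** 2 * (1.0 - ci * ci)
        if sin_t2 >= 1.0:
            rz = dz - 2.0 * ci * nz
            if -rz >= cos_acc:
                det_spec += 1.0
            else:
                escaped += 1.0
            continue
        ct = math.sqrt(1.0 - sin_t2)
        rs = (n_fib * ci - n_med * ct) / (n_fib * ci + n_med * ct)
        rp = (n_fib * ct - n_med * ci) / (n_fib * ct + n_med * ci)
        refl = 0.5 * (rs * rs + rp * rp)
        rz = dz - 2.0 * ci * nz
        if -rz >= cos_acc:
            det_spec += refl
        else:
            escaped += refl
        w = 1.0 - refl
        eta = n_fib / n_med
        k = eta * ci - ct
        dx = eta * dx - k * nx
        dz = eta * dz - k * nz
        dy = eta * dy
        nrm_d = math.sqrt(dx * dx + dy * dy + dz * dz)
        dx /= nrm_d
        dy /= nrm_d
        dz /= nrm_d
        px += eps * nx
        pz += eps * nz
        path = 0.0
        alive = True
        steps = 0
        while alive:
            steps += 1
            if steps > 500000:
                absorbed += w
                break
            if mu_s > 0.0:
                xi = np.random.random()
                while xi <= 0.0:
                    xi = np.random.random()
                s = -math.log(xi) / mu_s
            else:
                s = 1.0e9
            t_exit = 1.0e30
            if dx > 0.0:
                t_exit = min(t_exit, (hx - px) / dx)
            elif dx < 0.0:
                t_exit = min(t_exit, (-hx - px) / dx)
            if dy > 0.0:
                t_exit = min(t_exit, (hy - py) / dy)
            elif dy < 0.0:
                t_exit = min(t_exit, (-hy - py) / dy)
            if dz > 0.0:
                t_exit = min(t_exit, (lz - pz) / dz)
            elif dz < 0.0:
                t_exit = min(t_exit, (0.0 - pz) / dz)
            dn = dx * nx + dz * nz
            t_face = 1.0e30
            if dn < 0.0:
                dist = px * nx + (pz - tip_z) * nz
                if dist > 0.0:
                    tf = dist / (-dn)
                    fx = px + tf * dx
                    fy = py + tf * dy
                    fz = pz + tf * dz
                    rho2 = fx * fx + fy * fy + (fz - tip_z) * (fz - tip_z)
                    if rho2 <= core_radius * core_radius:
                        t_face = tf
            if t_face <= s and t_face <= t_exit:
                px += t_face * dx
                py += t_face * dy
                pz += t_face * dz
                path += t_face
                ci2 = -dn
                sin_t2 = (n_med / n_fib) ** 2 * (1.0 - ci2 * ci2)
                ct2 = math.sqrt(max(0.0, 1.0 - sin_t2))
                rs = (n_med * ci2 - n_fib * ct2) / (n_med * ci2 + n_fib * ct2)
                rp = (n_med * ct2 - n_fib * ci2) / (n_med * ct2 + n_fib * ci2)
                refl2 = 0.5 * (rs * rs + rp * rp)
                trans = w * (1.0 - refl2)
                eta2 = n_med / n_fib
                k2 = eta2 * ci2 - ct2
                tdx = eta2 * dx + k2 * nx
                tdz = eta2 * dz + k2 * nz
                tdy = eta2 * dy
                nrm_t = math.sqrt(tdx * tdx + tdy * tdy + tdz * tdz)
                if -tdz / nrm_t >= cos_acc:
                    if n_pk < cap:
                        pk_w[n_pk] = trans
                        pk_l[n_pk] = path
                        n_pk += 1
                    else:
                        lost_pk += trans
                else:
                    escaped += trans
                w *= refl2
                dx -= 2.0 * dn * nx
                dz -= 2.0 * dn * nz
                px += eps * nx
                pz += eps * nz
                if w < 1e-4:
                    if np.random.random() < 0.1:
                        w /= 0.1
                    else:
                        absorbed += w
                        alive = False
                continue
            if t_exit < s:
                escaped += w
                break
            px += s * dx
            py += s * dy
            pz += s * dz
            path += s
            if abs(g) < 1e-8:
                cth = 1.0 - 2.0 * np.random.random()
            else:
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * np.random.random())
                cth = (1.0 + g * g - tmp * tmp) / (2.0 * g)
            sth = math.sqrt(max(0.0, 1.0 - cth * cth))
            psi = 2.0 * math.pi * np.random.random()
            cpsi = math.cos(psi)
            spsi = math.sin(psi)
            if abs(dz) > 0.99999:
                dx = sth * cpsi
                dy = sth * spsi
                dz = cth if dz > 0.0 else -cth
            else:
                den = math.sqrt(1.0 - dz * dz)
                ndx = sth * (dx * dz * cpsi - dy * spsi) / den + dx * cth
                ndy = sth * (dy * dz * cpsi + dx * spsi) / den + dy * cth
                ndz = -sth * cpsi * den + dz * cth
                dx, dy, dz = ndx, ndy, ndz
            if w < 1e-4:
                if np.random.random() < 0.1:
                    w /= 0.1
                else:
                    absorbed += w
                    alive = False
    return det_spec, pk_w[:n_pk], pk_l[:n_pk], absorbed, escaped, lost_pk


@njit(cache=True, fastmath=True)
def _slab_kernel(seed, n_photons, mu_a, mu_s, g, thickness):  # pragma: no cover
    """Collimated beam on a slab; returns ballistic transmitted weight."""
    np.random.seed(seed)
    mu_t = mu_a + mu_s
    trans = 0.0
    for _ in range(n_photons):
        if mu_t <= 0.0:
            trans += 1.0
            continue
        xi = np.random.random()
        while xi <= 0.0:
            xi = np.random.random()
        s = -math.log(xi) / mu_t
        if s >= thickness:
            trans += 1.0
    return trans


# ---------------------------------------------------------------------------
# Run wrappers
# ---------------------------------------------------------------------------

def _seed_array(seed: int, n: int) -> np.ndarray:
    """Deterministic per-run 31-bit seeds derived from one master seed."""
    return np.random.SeedSequence(seed).generate_state(n) >> 1


def simulate_backscatter(
    geom: FiberGeometry,
    tissue: TissueOptics,
    lam: float,
    n_photons: int = 1_000_000,
    coating: CoatingSpec | None = None,
    seed: int = 0,
    mu_a_override: float | None = None,
) -> DetectionResult:
    """One weighted-MC backscatter run at a single wavelength.

    ``mu_a_override`` replaces the static tissue absorption (used by the
    dynamic hemodynamics engine); everything else comes from the tissue and
    geometry models.  Deterministic given ``seed``.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    geom.check_block(tissue, lam)
    mu_a = tissue.mu_a(lam) if mu_a_override is None else float(mu_a_override)
    tau = 1.0 if coating is None else coating.transmission
    hx, hy, lz = geom.block_mm[0] / 2.0, geom.block_mm[1] / 2.0, geom.block_mm[2]
    n_fib = float(geom.n_fiber(lam))
    cos_acc = math.sqrt(1.0 - (geom.numerical_aperture / n_fib) ** 2)
    det_spec, det_diff, absorbed, escaped, sum_w2 = _transport_kernel(
        np.uint32(seed), int(n_photons),
        float(mu_a), float(tissue.mu_s(lam)), float(tissue.g(lam)),
        float(tissue.n(lam)), n_fib,
        geom.core_radius_mm, math.radians(geom.tip_angle_deg), cos_acc,
        geom.tip_depth_mm, hx, hy, lz, float(tau),
    )
    return DetectionResult(
        launched_photons=int(n_photons),
        detected_weight=det_spec + det_diff,
        detected_specular=det_spec,
        detected_diffuse=det_diff,
        absorbed_weight=absorbed,
        escaped_weight=escaped,
        sum_w2_diffuse=sum_w2,
        seed=int(seed),
        wavelength=float(lam),
    )


def simulate_references(
    geom: FiberGeometry,
    lam_grid,
    mode: str = "analytic",
    n_photons: int = 100_000,
    seed: int = 0,
) -> ReferenceSpectra:
    """Reference spectra with the fiber tip in air and in glycerine.

    The far face sits in a non-scattering, non-absorbing medium, so the
    collected light is the specular Fresnel return of the angled face.
    ``mode='analytic'`` (default) evaluates it by deterministic quadrature;
    ``mode='mc'`` runs the transport kernel with mu_a = mu_s = 0 -- the two
    agree within MC error.
    """
    lam_grid = np.atleast_1d(np.asarray(lam_grid, dtype=float))
    air = np.empty_like(lam_grid)
    gly = np.empty_like(lam_grid)
    if mode == "analytic":
        for i, lam in enumerate(lam_grid):
            n_f = float(geom.n_fiber(lam))
            air[i] = specular_return(
                n_f, refractive_index(lam, "air"),
                geom.tip_angle_deg, geom.numerical_aperture,
            )
            gly[i] = specular_return(
                n_f, refractive_index(lam, "glycerine"),
                geom.tip_angle_deg, geom.numerical_aperture,
            )
    elif mode == "mc":
        seeds = _seed_array(seed, 2 * lam_grid.size)
        for i, lam in enumerate(lam_grid):
            for j, medium in enumerate(("air", "glycerine")):
                n_fib = float(geom.n_fiber(lam))
                cos_acc = math.sqrt(1.0 - (geom.numerical_aperture / n_fib) ** 2)
                hx, hy, lz = (
                    geom.block_mm[0] / 2.0, geom.block_mm[1] / 2.0, geom.block_mm[2],
                )
                out = _transport_kernel(
                    np.uint32(seeds[2 * i + j]), int(n_photons),
                    0.0, 0.0, 0.0, float(refractive_index(lam, medium)), n_fib,
                    geom.core_radius_mm, math.radians(geom.tip_angle_deg), cos_acc,
                    geom.tip_depth_mm, hx, hy, lz, 1.0,
                )
                value = (out[0] + out[1]) / n_photons
                if medium == "air":
                    air[i] = value
                else:
                    gly[i] = value
    else:
        raise ValueError("mode must be 'analytic' or 'mc'")
    return ReferenceSpectra(lam_grid, air, gly)


def simulate_slab_transmission(
    mu_a: float, mu_s: float, thickness: float,
    n_photons: int = 100_000, seed: int = 0,
) -> float:
    """Planar-slab validation mode: ballistic transmitted weight fraction.

    A collimated beam enters a slab of the given optical thickness with no
    detector aperture; the unscattered transmitted fraction follows the
    Beer-Lambert law exp(-(mu_a + mu_s) * L).
    """
    t = _slab_kernel(np.uint32(seed), int(n_photons), float(mu_a), float(mu_s), 0.0,
                     float(thickness))
    return t / n_photons


class PathlengthRun:
    """Detected-packet record of one analog-scattering transport run.

    Holds the specular return, per-packet geometric weights and tissue
    pathlengths; :meth:`detected_fraction` evaluates the collected weight
    for any absorption coefficient by continuous-absorption weighting
    exp(-mu_a * L).  One run therefore serves a whole family of absorbing
    conditions on *identical* photon paths, which removes the shared path
    variance from absorbing-vs-nonabsorbing comparisons.
    """

    def __init__(self, det_spec, weights, lengths, absorbed, escaped,
                 lost, n_photons, seed, wavelength):
        self.detected_specular = float(det_spec)
        self.weights = np.asarray(weights)
        self.lengths = np.asarray(lengths)
        self.absorbed_weight = float(absorbed)
        self.escaped_weight = float(escaped)
        self.lost_packet_weight = float(lost)
        self.launched_photons = int(n_photons)
        self.seed = int(seed)
        self.wavelength = float(wavelength)

    def detected_fraction(self, mu_a: float = 0.0) -> float:
        """Collected weight fraction at absorption mu_a (mm^-1)."""
        w = self.weights * np.exp(-mu_a * self.lengths)
        return (self.detected_specular + w.sum()) / self.launched_photons

    def diffuse_fraction(self, mu_a: float = 0.0) -> float:
        """Tissue-return (non-specular) weight fraction at absorption mu_a."""
        w = self.weights * np.exp(-mu_a * self.lengths)
        return w.sum() / self.launched_photons

    def diffuse_std_error(self, mu_a: float = 0.0) -> float:
        """MC standard error of the diffuse fraction at mu_a."""
        w = self.weights * np.exp(-mu_a * self.lengths)
        n = self.launched_photons
        mean = w.sum() / n
        var = (w**2).sum() / n - mean**2
        return math.sqrt(max(var, 0.0) / n)


def simulate_pathlengths(
    geom: FiberGeometry,
    tissue: TissueOptics,
    lam: float,
    n_photons: int = 1_000_000,
    seed: int = 0,
) -> PathlengthRun:
    """Run the analog-scattering kernel and return the packet record."""
    geom.check_block(tissue, lam)
    hx, hy, lz = geom.block_mm[0] / 2.0, geom.block_mm[1] / 2.0, geom.block_mm[2]
    n_fib = float(geom.n_fiber(lam))
    cos_acc = math.sqrt(1.0 - (geom.numerical_aperture / n_fib) ** 2)
    out = _pathlength_kernel(
        np.uint32(seed), int(n_photons),
        float(tissue.mu_s(lam)), float(tissue.g(lam)),
        float(tissue.n(lam)), n_fib,
        geom.core_radius_mm, math.radians(geom.tip_angle_deg), cos_acc,
        geom.tip_depth_mm, hx, hy, lz,
    )
    return PathlengthRun(*out, n_photons, seed, lam)


def sensitivity_scan(
    geom: FiberGeometry,
    tissue: TissueOptics,
    wavelengths,
    n_photons: int = 1_000_000,
    n_repeats: int = 10,
    seed: int = 0,
    method: str = "paired",
) -> "pd.DataFrame":
    """Per-wavelength hemodynamic sensitivity of the collected light.

    Sensitivity is 100 * |W_abs - W_scat| / W_scat between the absorbing
    (configured BV/sO2) and scattering-only (mu_a = 0) cases, averaged over
    ``n_repeats`` independently seeded runs.

    ``method='paired'`` (default) evaluates both cases on identical photon
    paths via the continuous-absorption estimator, so the shared path
    variance cancels; ``method='independent'`` runs separate
    albedo-weighted simulations per case, the direct but noisier scheme.
    """
    import pandas as pd

    wavelengths = np.atleast_1d(np.asarray(wavelengths, dtype=float))
    seeds = _seed_array(seed, 2 * n_repeats * wavelengths.size).reshape(
        wavelengths.size, 2, n_repeats
    )
    scat_only = TissueOptics(
        blood_volume_fraction=0.0,
        oxygen_saturation=tissue.oxygen_saturation,
        lipid_dilution=tissue.lipid_dilution,
        extinction_table=tissue.extinction_table,
    )
    rows = []
    for i, lam in enumerate(wavelengths):
        mu_a = float(tissue.mu_a(lam))
        if method == "paired":
            runs = [
                simulate_pathlengths(geom, tissue, lam, n_photons, seeds[i, 0, r])
                for r in range(n_repeats)
            ]
            w_abs = float(np.mean([r.detected_fraction(mu_a) for r in runs]))
            w_scat = float(np.mean([r.detected_fraction(0.0) for r in runs]))
        elif method == "independent":
            w_abs = float(np.mean([
                simulate_backscatter(geom, tissue, lam, n_photons, None,
                                     seeds[i, 0, r]).detected_fraction
                for r in range(n_repeats)
            ]))
            w_scat = float(np.mean([
                simulate_backscatter(geom, scat_only, lam, n_photons, None,
                                     seeds[i, 1, r]).detected_fraction
                for r in range(n_repeats)
            ]))
        else:
            raise ValueError("method must be 'paired' or 'independent'")
        if w_scat == 0.0:
            raise ZeroDivisionError(
                f"no light detected in the scattering-only case at {lam:g} nm"
            )
        rows.append(
            {
                "wavelength_nm": lam,
                "detected_absorbing": w_abs,
                "detected_scattering_only": w_scat,
                "sensitivity_pct": 100.0 * abs(w_abs - w_scat) / w_scat,
            }
        )
    return pd.DataFrame(rows)


def transmission_shift_experiment(
    geom: FiberGeometry,
    tissue: TissueOptics,
    lam_grid,
    transmissions=(0.96, 0.92, 0.90, 0.80),
    n_photons: int = 1_000_000,
    seed: int = 0,
):
    """Coated-interface experiment: reflectance spectra and RMSD vs nominal.

    Simulates the tissue backscatter with each transmission coating and
    with no coating, normalizes against analytic air/glycerine references,
    and reports the RMSD of each coated reflectance spectrum against the
    nominal one.  Per-wavelength seeds are shared across coatings (common
    random numbers), so the coating effect is isolated from MC noise.

    Returns a dict with the wavelength grid, per-condition reflectance
    spectra (key = transmission, 1.0 = nominal), the reference spectra and
    an RMSD table (pandas DataFrame).
    """
    import pandas as pd

    lam_grid = np.atleast_1d(np.asarray(lam_grid, dtype=float))
    transmissions = list(transmissions)
    if any(not 0.0 < t <= 1.0 for t in transmissions):
        raise ValueError("transmissions must lie in (0, 1]")
    refs = simulate_references(geom, lam_grid, mode="analytic")
    denom = refs.intensity_air - refs.intensity_glycerine
    seeds = _seed_array(seed, lam_grid.size)
    spectra: dict[float, np.ndarray] = {}
    for tau in [1.0] + transmissions:
        coat = None if tau == 1.0 else CoatingSpec(tau)
        ib = np.array(
            [
                simulate_backscatter(
                    geom, tissue, lam, n_photons, coat, seeds[i]
                ).detected_fraction
                for i, lam in enumerate(lam_grid)
            ]
        )
        spectra[tau] = (ib - refs.intensity_glycerine) / denom
    table = pd.DataFrame(
        {
            "transmission": transmissions,
            "rmsd_vs_nominal": [
                rmsd(spectra[tau], spectra[1.0]) for tau in transmissions
            ],
        }
    )
    return {
        "wavelengths_nm": lam_grid,
        "reflectance": spectra,
        "references": refs,
        "rmsd_table": table,
    }
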
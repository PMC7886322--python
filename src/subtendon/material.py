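"""Compressible neo-Hookean constitutive model for tendon tissue.

The strain-energy density is the common displacement-based FE form

    W(F) = C10 (I1_bar - 3) + (1/D1) (J - 1)^2,

with J = det F, I1_bar = J^(-2/3) tr(F^T F).  The model is parameterised from
an *initial* (small-strain) Young's modulus E and Poisson's ratio nu via

    C10 = E / (4 (1 + nu)),        D1 = 6 (1 - 2 nu) / E,

so that the small-strain shear modulus is 2*C10 and the bulk modulus 2/D1.
Tendon is nearly incompressible; nu defaults to 0.49.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import optimize

from .core import SubTendonID, TestCurve

DEFAULT_POISSON = 0.49

__all__ = [
    "NeoHookeanParams",
    "MaterialMap",
    "neo_hookean_from_modulus",
    "default_material_map",
    "strain_energy",
    "pk1_stress",
    "pk1_tangent",
    "cauchy_from_pk1",
    "uniaxial_nominal_stress",
    "fit_initial_modulus",
]


@dataclass(frozen=True)
class NeoHookeanParams:
    """Material constants of the compressible neo-Hookean model (MPa units)."""

    C10: float
    D1: float
    E: float
    nu: float

    def __post_init__(self) -> None:
        if self.C10 <= 0 or self.D1 <= 0:
            raise ValueError("C10 and D1 must be positive")
        if not (0 <= self.nu < 0.5):
            raise ValueError("Poisson ratio must lie in [0, 0.5)")
        if not np.isclose(self.E, 4 * self.C10 * (1 + self.nu), rtol=1e-10):
            raise ValueError("inconsistent parameters: E must equal 4*C10*(1+nu)")


MaterialMap = Mapping[SubTendonID, NeoHookeanParams]

#: Initial moduli (MPa) used to parameterise the FE simulations.  These are
#: the values fitted from the in vitro axial tensile tests, which differ from
#: the per-specimen tabulated Young's moduli; the simulation uses the fitted
#: set because it is the one that parameterises the solver.
FE_INITIAL_MODULI: dict[SubTendonID, float] = {
    SubTendonID.LG: 226.7,
    SubTendonID.MG: 143.2,
    SubTendonID.SOL: 103.1,
}


def neo_hookean_from_modulus(E: float, nu: float = DEFAULT_POISSON) -> NeoHookeanParams:
    """Convert an initial Young's modulus to neo-Hookean constants.

    Parameters
    ----------
    E : float
        Initial (small-strain) Young's modulus, MPa. Must be positive.
    nu : float
        Poisson's ratio in [0, 0.5). nu = 0.5 (incompressible) is not
        representable in this compressible form.
    """
    if E <= 0:
        raise ValueError("E must be positive")
    if not (0 <= nu < 0.5):
        raise ValueError("nu must lie in [0, 0.5); the incompressible limit "
                         "nu = 0.5 is not representable")
    c10 = E / (4.0 * (1.0 + nu))
    d1 = 6.0 * (1.0 - 2.0 * nu) / E
    return NeoHookeanParams(C10=c10, D1=d1, E=E, nu=nu)


def default_material_map(nu: float = DEFAULT_POISSON) -> dict[SubTendonID, NeoHookeanParams]:
    """Material map with the packaged default initial moduli."""
    return {st: neo_hookean_from_modulus(E, nu) for st, E in FE_INITIAL_MODULI.items()}


# ----------------------------------------------------------------------------
# Continuum response, vectorised over leading axes of F (..., 3, 3).
# ----------------------------------------------------------------------------

def strain_energy(F: np.ndarray, c10, d1) -> np.ndarray:
    """Strain-energy density W(F); broadcasts over leading axes."""
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    I1 = np.einsum("...ij,...ij->...", F, F)
    return c10 * (J ** (-2.0 / 3.0) * I1 - 3.0) + (1.0 / d1) * (J - 1.0) ** 2


def pk1_stress(F: np.ndarray, c10, d1) -> np.ndarray:
    """First Piola-Kirchhoff stress P = dW/dF; broadcasts over leading axes.

    ``c10``/``d1`` may be scalars or arrays broadcastable against the leading
    axes of ``F``.
    """
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    Finv = np.linalg.inv(F)
    FinvT = np.swapaxes(Finv, -1, -2)
    I1 = np.einsum("...ij,...ij->...", F, F)
    c10 = np.asarray(c10, dtype=float)
    d1 = np.asarray(d1, dtype=float)
    pprime = 2.0 * c10 * J ** (-2.0 / 3.0)
    q = (2.0 / d1) * (J - 1.0)
    return (
        pprime[..., None, None] * (F - (I1 / 3.0)[..., None, None] * FinvT)
        + (q * J)[..., None, None] * FinvT
    )


def pk1_tangent(F: np.ndarray, c10, d1) -> np.ndarray:
    """First elasticity tensor A_iJkL = d P_iJ / d F_kL (..., 3, 3, 3, 3)."""
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    Finv = np.linalg.inv(F)
    G = np.swapaxes(Finv, -1, -2)  # F^{-T}
    I1 = np.einsum("...ij,...ij->...", F, F)
    c10 = np.asarray(c10, dtype=float)
    d1 = np.asarray(d1, dtype=float)
    pprime = 2.0 * c10 * J ** (-2.0 / 3.0)
    q = (2.0 / d1) * (J - 1.0)

    eye = np.eye(3)
    dev = F - (I1 / 3.0)[..., None, None] * G  # F - (I1/3) F^{-T}

    # d(pprime)/dF = -(2/3) pprime F^{-T}
    A = -(2.0 / 3.0) * pprime[..., None, None, None, None] * np.einsum(
        "...kL,...iJ->...iJkL", G, dev
    )
    # pprime * d(dev)/dF
    A = A + pprime[..., None, None, None, None] * (
        np.einsum("ik,JL->iJkL", eye, eye)
        - (2.0 / 3.0) * np.einsum("...kL,...iJ->...iJkL", F, G)
        + (I1 / 3.0)[..., None, None, None, None]
        * np.einsum("...kJ,...iL->...iJkL", G, G)
    )
    # volumetric part: d(q J F^{-T})/dF
    A = A + ((2.0 / d1) * J**2 + q * J)[..., None, None, None, None] * np.einsum(
        "...kL,...iJ->...iJkL", G, G
    )
    A = A - (q * J)[..., None, None, None, None] * np.einsum(
        "...kJ,...iL->...iJkL", G, G
    )
    return A


def cauchy_from_pk1(F: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Cauchy stress sigma = P F^T / J; broadcasts over leading axes."""
    J = np.linalg.det(F)
    return np.einsum("...iJ,...kJ->...ik", P, F) / J[..., None, None]


# ----------------------------------------------------------------------------
# Uniaxial response (analytic oracle for fitting and solver verification)
# ----------------------------------------------------------------------------

def _lateral_stretch(params: NeoHookeanParams, stretch: np.ndarray) -> np.ndarray:
    """Lateral stretch solving the zero-lateral-stress condition.

    Solved per axial stretch by a vectorised, safeguarded Newton iteration on
    P_22(lam_ax, lam_lat) = 0, with a bisection fallback; converges to 1e-10.
    """
    stretch = np.atleast_1d(np.asarray(stretch, dtype=float))
    if np.any(stretch <= 0):
        raise ValueError("stretch must be positive")
    c10, d1 = params.C10, params.D1

    def p22(lam, lat):
        F = np.zeros(lam.shape + (3, 3))
        F[..., 0, 0] = lam
        F[..., 1, 1] = lat
        F[..., 2, 2] = lat
        return pk1_stress(F, c10, d1)[..., 1, 1]

    # initial guess: small-strain-consistent lateral stretch
    lat = stretch ** (-params.nu)
    lo = np.full_like(stretch, 1e-3)
    hi = np.maximum(2.0 * stretch, 2.0)
    for _ in range(100):
        r = p22(stretch, lat)
        # maintain bracket
        lo = np.where(r < 0, np.maximum(lo, lat), lo)
        hi = np.where(r > 0, np.minimum(hi, lat), hi)
        if np.all(np.abs(r) < 1e-10 * max(params.E, 1.0)):
            break
        h = 1e-7 * np.maximum(lat, 1.0)
        drdlat = (p22(stretch, lat + h) - r) / h
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(np.abs(drdlat) > 0, -r / drdlat, 0.0)
        new = lat + step
        bad = ~np.isfinite(new) | (new <= lo) | (new >= hi)
        new = np.where(bad, 0.5 * (lo + hi), new)
        lat = new
    else:
        raise RuntimeError("lateral-stretch root-find did not converge")
    return lat


def uniaxial_nominal_stress(params: NeoHookeanParams, stretch) -> np.ndarray | float:
    """Nominal (first Piola) stress of unconfined uniaxial extension.

    The lateral faces are traction free; the lateral stretch is solved from
    the zero-lateral-stress condition.  Accepts scalar or array stretch.
    """
    scalar = np.isscalar(stretch) or np.ndim(stretch) == 0
    lam = np.atleast_1d(np.asarray(stretch, dtype=float))
    lat = _lateral_stretch(params, lam)
    F = np.zeros(lam.shape + (3, 3))
    F[..., 0, 0] = lam
    F[..., 1, 1] = lat
    F[..., 2, 2] = lat
    P11 = pk1_stress(F, params.C10, params.D1)[..., 0, 0]
    return float(P11[0]) if scalar else P11


def initial_tangent_modulus(params: NeoHookeanParams, h: float = 1e-5) -> float:
    """Small-strain uniaxial tangent d(stress)/d(stretch) at stretch 1."""
    s = uniaxial_nominal_stress(params, np.array([1.0 - h, 1.0 + h]))
    return float((s[1] - s[0]) / (2 * h))


# ----------------------------------------------------------------------------
# Modulus fitting from tensile test curves
# ----------------------------------------------------------------------------

def fit_initial_modulus(
    curve: TestCurve,
    nu: float = DEFAULT_POISSON,
    force_band: tuple[float, float] = (0.2, 0.8),
    min_samples: int = 20,
):
    """Least-squares fit of the initial modulus from a tensile test curve.

    The uniaxial neo-Hookean nominal-stress model is fitted to the measured
    stress-strain data over the pre-failure region between ``force_band``
    fractions of the failure force.  A strain-offset nuisance parameter
    absorbs the toe region (the model is evaluated at strain - e0), which real
    tendon curves always show.

    Returns
    -------
    (E, diagnostics) : tuple[float, dict]
        Fitted initial modulus (MPa) and a diagnostics dict with the residual
        norm, the strain offset and the number of points fitted.
    """
    if len(curve.force_n) < min_samples:
        raise ValueError(f"curve must have at least {min_samples} samples")
    stress = curve.stress_mpa
    strain = curve.strain
    if strain.max() < 0.02:
        raise ValueError("curve must span strain > 2%")
    i_peak = int(np.argmax(curve.force_n))
    fmax = curve.force_n[i_peak] - curve.preload_n
    if fmax <= 0:
        raise ValueError("curve carries no load above the preload")
    net = curve.force_n[: i_peak + 1] - curve.preload_n
    sel = np.flatnonzero((net >= force_band[0] * fmax) & (net <= force_band[1] * fmax))
    if len(sel) < 5:
        raise ValueError("fewer than 5 samples in the fitting band")
    x = strain[sel]
    y = stress[sel]

    # guard against gross non-monotonicity (beyond a 5% noise band)
    drop = (np.maximum.accumulate(y) - y) / max(y.max(), 1e-12)
    if np.any(drop > 0.3):
        raise ValueError("stress is non-monotone beyond the configured noise band")

    e_guess = max((y[-1] - y[0]) / (x[-1] - x[0]), 1e-3)

    def model(theta):
        logE, e0 = theta
        p = neo_hookean_from_modulus(float(np.exp(logE)), nu)
        lam = np.maximum(1.0 + (x - e0), 0.2)
        return uniaxial_nominal_stress(p, lam)

    def resid(theta):
        return model(theta) - y

    res = optimize.least_squares(
        resid, x0=[np.log(e_guess), 0.0], method="lm", xtol=1e-12, ftol=1e-12
    )
    if not res.success:
        raise RuntimeError(f"modulus fit did not converge: {res.message}")
    E = float(np.exp(res.x[0]))
    diag = {
        "residual_norm": float(np.linalg.norm(res.fun)),
        "strain_offset": float(res.x[1]),
        "n_points": int(len(sel)),
        "nu": nu,
    }
    return E, diag
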
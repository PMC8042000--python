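"""Optimality theory for leaf photosynthetic capacity.

Two eco-evolutionary optimality hypotheses are combined to predict the
maximum rate of Rubisco carboxylation from the physical growth environment
of C3 plants:

* the **least-cost hypothesis** — stomata regulate the ratio chi = Ci/Ca so
  that the combined unit costs of maintaining transpiration and
  carboxylation capacity are minimised.  The optimum is

      chi_opt = G*/Ca + (1 - G*/Ca) * xi / (xi + sqrt(D)),
      xi      = sqrt(beta * (K + G*) / (1.6 * eta*))

  where G* is the photorespiratory CO2 compensation point (Pa), K the
  effective Michaelis-Menten coefficient of Rubisco (Pa), D the vapour
  pressure deficit (Pa), eta* the viscosity of water relative to 25 degC
  and beta the carboxylation/transpiration unit-cost ratio (146).

* the **coordination hypothesis** — carboxylation and electron transport
  are co-limiting under typical daytime growth conditions, giving

      Vcmax_opt = phi0 * Iabs * (Ci + K) / (Ci + 2 G*)

  with phi0 the intrinsic quantum efficiency of photosynthesis and Iabs
  the absorbed photosynthetic photon flux density.

Predicted Vcmax at growth temperature is standardized to 25 degC with the
Arrhenius equation, giving Vcmax25.  Enzyme-kinetic parameters (G*, Kc,
Ko) follow in-vivo tobacco measurements; G*, Ca and O scale in direct
proportion to atmospheric pressure with elevation.

All temperatures are degrees Celsius, pressures Pa, fluxes
umol m-2 s-1.  D is Pa *inside* this module; I/O boundaries use kPa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GAS_CONSTANT",
    "P_SEALEVEL",
    "T_REF_K",
    "KineticParams",
    "BERNACCHI",
    "EnvConditions",
    "OptimalPrediction",
    "DegenerateEnvironmentError",
    "arrhenius_scale",
    "gamma_star",
    "michaelis_k",
    "water_viscosity",
    "eta_star",
    "phi0",
    "chi_opt",
    "vcmax_opt",
    "elasticities",
]

GAS_CONSTANT = 8.314  # J mol-1 K-1
P_SEALEVEL = 101325.0  # Pa
T_REF_K = 298.15  # 25 degC in K


class DegenerateEnvironmentError(ValueError):
    """Environment where the optimality equations are undefined (Ca <= G*)."""


@dataclass(frozen=True)
class KineticParams:
    """Enzyme-kinetic and cost constants of the optimality model.

    Defaults are the in-vivo tobacco kinetics (Bernacchi constant set),
    with the 25 degC Michaelis-Menten coefficients and compensation point
    converted from mole fractions to partial pressures at sea level:
    G*25 = 42.75 umol/mol, Kc25 = 404.9 umol/mol, Ko25 = 278.4 mmol/mol.

    Attributes
    ----------
    gammastar25, kc25, ko25 : float
        Values at 25 degC and sea-level pressure, Pa.
    dha_gammastar, dha_kc, dha_ko, dha_vcmax, dha_jmax : float
        Arrhenius activation energies, J mol-1.
    beta : float
        Ratio of unit costs of carboxylation vs transpiration capacity.
    phi0_coeffs : tuple
        Coefficients (c0, c1, c2) of the quantum-efficiency polynomial
        phi0 = (c0 + c1*Tg + c2*Tg^2) / 8.
    rd_frac : float
        Day respiration as a fraction of Vcmax (used by the one-point
        method without a respiration measurement).
    e2f : float
        Energy-to-flux conversion for shortwave radiation, umol J-1.
    """

    gammastar25: float = 42.75e-6 * P_SEALEVEL
    kc25: float = 404.9e-6 * P_SEALEVEL
    ko25: float = 278.4e-3 * P_SEALEVEL
    dha_gammastar: float = 37830.0
    dha_kc: float = 79430.0
    dha_ko: float = 36380.0
    dha_vcmax: float = 65330.0
    dha_jmax: float = 43900.0
    beta: float = 146.0
    phi0_coeffs: tuple = (0.352, 0.021, -3.4e-4)
    rd_frac: float = 0.015
    e2f: float = 2.04

    def __post_init__(self) -> None:
        for name in ("gammastar25", "kc25", "ko25", "dha_gammastar",
                     "dha_kc", "dha_ko", "dha_vcmax", "dha_jmax",
                     "beta", "rd_frac", "e2f"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v!r}")

    def with_overrides(self, **kwargs) -> "KineticParams":
        return replace(self, **kwargs)


#: The default constant set.
BERNACCHI = KineticParams()


@dataclass(frozen=True)
class EnvConditions:
    """Physical environment at which the optimality equations are evaluated.

    Attributes
    ----------
    tg : float
        Mean daytime growth temperature, degC.
    d : float
        Vapour pressure deficit, Pa (note: Pa, not kPa).
    ppfd : float
        Photosynthetic photon flux density absorbed by the leaf,
        umol photons m-2 s-1.
    z : float
        Elevation, m.
    patm : float
        Atmospheric pressure, Pa.
    ca : float
        Ambient CO2 partial pressure, Pa.
    o2 : float
        O2 partial pressure, Pa.
    """

    tg: float
    d: float
    ppfd: float
    z: float = 0.0
    patm: float = P_SEALEVEL
    ca: float = 400e-6 * P_SEALEVEL
    o2: float = 0.20946 * P_SEALEVEL

    def __post_init__(self) -> None:
        if not (-25.0 < self.tg < 60.0):
            raise ValueError(f"tg={self.tg} outside (-25, 60) degC")
        if self.d < 0:
            raise ValueError("D must be >= 0")
        if self.ppfd < 0:
            raise ValueError("PPFD must be >= 0")
        if self.patm <= 0 or self.ca <= 0 or self.o2 < 0:
            raise ValueError("patm, ca must be > 0 and o2 >= 0")

    @classmethod
    def from_climate(cls, tg_c: float, d_kpa: float, ppfd: float,
                     elevation_m: float = 0.0, ca_ppm: float = 400.0,
                     o2_frac: float = 0.20946) -> "EnvConditions":
        """Build from I/O-convention units (D in kPa, CO2 as ppm mole fraction).

        Ca and O are converted to partial pressures at the barometric
        pressure for the given elevation, so they scale in direct
        proportion to atmospheric pressure.
        """
        from .climate import patm_from_elevation

        patm = patm_from_elevation(elevation_m)
        return cls(tg=tg_c, d=d_kpa * 1000.0, ppfd=ppfd, z=elevation_m,
                   patm=patm, ca=ca_ppm * 1e-6 * patm, o2=o2_frac * patm)


@dataclass(frozen=True)
class OptimalPrediction:
    """Result of the optimality prediction at one environment."""

    chi: float            # Ci/Ca, dimensionless
    ci: float             # Pa
    xi: float             # sensitivity parameter, Pa^0.5
    k: float              # effective Michaelis-Menten coefficient, Pa
    gammastar: float      # Pa
    eta_star: float       # relative viscosity of water
    phi0: float           # mol C mol-1 photons
    vcmax: float = math.nan    # at growth temperature, umol m-2 s-1
    vcmax25: float = math.nan  # standardized to 25 degC, umol m-2 s-1


def _check_finite(**kwargs) -> None:
    for name, v in kwargs.items():
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{name} must be finite, got {v!r}")


def arrhenius_scale(rate_at_25, dha, t_c):
    """Scale a rate from 25 degC to ``t_c`` with the Arrhenius equation.

    rate(T) = rate25 * exp[(dHa/R) * (1/298.15 - 1/T_K)].
    """
    _check_finite(rate_at_25=rate_at_25, dha=dha, t_c=t_c)
    if np.any(np.asarray(rate_at_25) <= 0):
        raise ValueError("rate_at_25 must be positive")
    if np.any(np.asarray(t_c) <= -273.15):
        raise ValueError("temperature below absolute zero")
    return rate_at_25 * arrhenius_factor(dha, t_c)


def arrhenius_factor(dha, t_c):
    """The multiplicative Arrhenius factor from 25 degC to ``t_c``."""
    tk = np.asarray(t_c, dtype=float) + 273.15
    f = np.exp(dha / GAS_CONSTANT * (1.0 / T_REF_K - 1.0 / tk))
    return float(f) if np.isscalar(t_c) or np.ndim(t_c) == 0 else f


def gamma_star(t_c, patm=P_SEALEVEL, params: KineticParams = BERNACCHI):
    """Photorespiratory CO2 compensation point G* (Pa) at ``t_c`` and ``patm``.

    G* scales in direct proportion to atmospheric pressure.
    """
    if np.any(np.asarray(patm) <= 0):
        raise ValueError("patm must be positive")
    return arrhenius_scale(params.gammastar25, params.dha_gammastar, t_c) * (
        np.asarray(patm) / P_SEALEVEL if np.ndim(patm) else patm / P_SEALEVEL)


def michaelis_k(t_c, patm=P_SEALEVEL, params: KineticParams = BERNACCHI,
                o2=None):
    """Effective Michaelis-Menten coefficient K = Kc * (1 + O/Ko), Pa.

    Kc and Ko are Arrhenius-scaled to ``t_c``; the O2 partial pressure
    defaults to 20.946 % of ``patm`` (proportional to pressure), and Kc,
    Ko themselves also scale with pressure because they are defined from
    mole fractions.
    """
    if np.any(np.asarray(patm) <= 0):
        raise ValueError("patm must be positive")
    pr = patm / P_SEALEVEL
    if o2 is None:
        o2 = 0.20946 * patm
    if np.any(np.asarray(o2) < 0):
        raise ValueError("o2 must be >= 0")
    kc = arrhenius_scale(params.kc25, params.dha_kc, t_c) * pr
    ko = arrhenius_scale(params.ko25, params.dha_ko, t_c) * pr
    return kc * (1.0 + o2 / ko)


# Vogel (Vogel-Fulcher-Tammann) correlation for the dynamic viscosity of
# liquid water, eta = A * 10^(B / (T_K - C)), mPa s.  Agrees with tabulated
# values to <1 % over 0-40 degC; encapsulated so it can be swapped.
_VOGEL_A = 0.02414  # mPa s
_VOGEL_B = 247.8    # K
_VOGEL_C = 140.0    # K


def water_viscosity(t_c):
    """Dynamic viscosity of liquid water at ``t_c``, mPa s (Vogel equation)."""
    tk = np.asarray(t_c, dtype=float) + 273.15
    v = _VOGEL_A * 10.0 ** (_VOGEL_B / (tk - _VOGEL_C))
    return float(v) if np.ndim(t_c) == 0 else v


def eta_star(t_c):
    """Viscosity of water relative to its value at 25 degC (dimensionless)."""
    t = np.asarray(t_c, dtype=float)
    if np.any(t < 0.0) or np.any(t > 60.0):
        raise ValueError("eta_star valid for 0 <= T <= 60 degC (liquid water)")
    return water_viscosity(t_c) / water_viscosity(25.0)


def phi0(tg_c, params: KineticParams = BERNACCHI):
    """Intrinsic quantum efficiency of photosynthesis, mol C mol-1 photons.

    Follows the temperature dependency of electron transport in
    light-adapted leaves: phi0 = (c0 + c1*Tg + c2*Tg^2) / 8.
    """
    c0, c1, c2 = params.phi0_coeffs
    poly = c0 + c1 * np.asarray(tg_c, dtype=float) + c2 * np.asarray(tg_c, dtype=float) ** 2
    if np.any(poly <= 0):
        raise ValueError(f"quantum-efficiency polynomial non-positive at Tg={tg_c}")
    out = poly / 8.0
    return float(out) if np.ndim(tg_c) == 0 else out


def chi_opt(env: EnvConditions, params: KineticParams = BERNACCHI) -> OptimalPrediction:
    """Optimal Ci/Ca ratio from the least-cost hypothesis.

    Returns an :class:`OptimalPrediction` with chi, ci, xi, K, G* and
    eta* filled in (vcmax fields NaN).  chi lies in [G*/Ca, 1], equals 1
    at D = 0 and tends to G*/Ca as D grows.
    """
    gs = gamma_star(env.tg, env.patm, params)
    if env.ca <= gs:
        raise DegenerateEnvironmentError(
            f"Ca = {env.ca:.3f} Pa <= compensation point {gs:.3f} Pa")
    k = michaelis_k(env.tg, env.patm, params, o2=env.o2)
    es = eta_star(env.tg)
    xi = math.sqrt(params.beta * (k + gs) / (1.6 * es))
    g_over_ca = gs / env.ca
    chi = g_over_ca + (1.0 - g_over_ca) * xi / (xi + math.sqrt(env.d))
    return OptimalPrediction(chi=chi, ci=chi * env.ca, xi=xi, k=k,
                             gammastar=gs, eta_star=es,
                             phi0=phi0(env.tg, params))


def vcmax_opt(env: EnvConditions, params: KineticParams = BERNACCHI) -> OptimalPrediction:
    """Optimal Vcmax at growth temperature and standardized to 25 degC.

    Vcmax_opt = phi0(Tg) * PPFD * (Ci + K) / (Ci + 2 G*), with Ci from
    the least-cost chi; Vcmax25 divides out the Arrhenius factor for
    Vcmax at Tg.  Strictly proportional to PPFD; zero at PPFD = 0.
    """
    pred = chi_opt(env, params)
    vc = pred.phi0 * env.ppfd * (pred.ci + pred.k) / (pred.ci + 2.0 * pred.gammastar)
    vc25 = vc / arrhenius_factor(params.dha_vcmax, env.tg)
    return replace(pred, vcmax=vc, vcmax25=vc25)


def _ln_vcmax25(env: EnvConditions, params: KineticParams,
                phi0_fixed: float | None) -> float:
    pred = chi_opt(env, params)
    p0 = pred.phi0 if phi0_fixed is None else phi0_fixed
    vc = p0 * env.ppfd * (pred.ci + pred.k) / (pred.ci + 2.0 * pred.gammastar)
    return math.log(vc / arrhenius_factor(params.dha_vcmax, env.tg))


def elasticities(env: EnvConditions, params: KineticParams = BERNACCHI,
                 include_phi0_response: bool = False,
                 rel_step: float = 1e-5, tg_step: float = 0.005):
    """Climate sensitivities of ln Vcmax25 by central finite differences.

    Returns ``(d ln Vcmax25 / d ln PPFD, d ln Vcmax25 / d Tg,
    d ln Vcmax25 / d ln D)`` — dimensionless, K-1, dimensionless.

    The PPFD elasticity is exactly 1 (Vcmax_opt is linear in PPFD and
    the 25 degC correction is PPFD-independent).  By default the quantum
    efficiency phi0 is held fixed at its value for ``env.tg`` while
    differentiating with respect to Tg, treating it as a calibrated
    constant rather than an acclimating response;
    ``include_phi0_response=True`` differentiates through the phi0
    polynomial as well (see the methods note for why fixed phi0 is the
    default).

    Steps are halved (up to 10 times) if an evaluation point leaves the
    validity domain of the kinetics or viscosity correlations.
    """
    if env.ppfd <= 0 or env.d <= 0:
        raise ValueError("elasticities need strictly positive PPFD and D")
    phi0_fixed = None if include_phi0_response else phi0(env.tg, params)

    def _diff(make_env, step, halvings=10):
        h = step
        for _ in range(halvings):
            try:
                up = _ln_vcmax25(make_env(+h), params, phi0_fixed)
                dn = _ln_vcmax25(make_env(-h), params, phi0_fixed)
                return (up - dn) / (2.0 * h)
            except ValueError:
                h /= 2.0
        raise ArithmeticError("finite-difference step could not be placed "
                              "inside the model's validity domain")

    e_ppfd = _diff(lambda h: replace(env, ppfd=env.ppfd * math.exp(h)), rel_step)
    e_tg = _diff(lambda h: replace(env, tg=env.tg + h), tg_step)
    e_d = _diff(lambda h: replace(env, d=env.d * math.exp(h)), rel_step)
    return e_ppfd, e_tg, e_d
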
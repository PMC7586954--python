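"""Soil texture to hydraulic properties.

Converts texture (clay/sand/silt fractions, bulk density, porosity) into
Brooks-Corey retention and conductivity parameters through the
Rawls-Brakensiek regression family, the most widely reproduced Brooks-Corey
pedotransfer set.  Predictors are clay percent C, sand percent S and porosity
phi; coefficients are stored as data tables keyed by monomial exponents
(C_pow, S_pow, phi_pow) so an alternative variant can be swapped by config.

Retention follows Brooks-Corey:

    psi(theta) = psi_e * S_e**(-1/lambda),   S_e = (theta - theta_r)/(theta_s - theta_r)

for psi <= psi_e, with theta = theta_s above air entry.  Unsaturated
conductivity uses the Campbell/Brooks-Corey power law
K(theta) = K_s * S_e**(3 + 2/lambda).

Units: matric potential is MPa everywhere (-33 kPa = -0.033 MPa) so the soil
side matches the plant side; conductivity is m s-1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SoilTexture",
    "SoilHydraulicParams",
    "pedotransfer",
    "theta_to_psi",
    "psi_to_theta",
    "retention",
    "unsat_conductivity",
    "fc_pwp",
    "PSI_FC",
    "PSI_PWP",
]

#: matric potentials defining field capacity and permanent wilting point (MPa)
PSI_FC = -0.033
PSI_PWP = -1.5

CM_H2O_TO_MPA = 9.80665e-5
CM_PER_HR_TO_M_PER_S = 0.01 / 3600.0


@dataclass(frozen=True)
class SoilTexture:
    """Mineral texture plus structure of one soil (or one layer)."""

    clay: float
    sand: float
    silt: float
    bulk_density: float = 1.5   # Mg m-3
    porosity: float | None = None  # m3 m-3; default 1 - bd/2.65
    d_gmean_mm: float = 0.1     # geometric mean particle diameter, mm
    gsd: float = 10.0           # geometric standard deviation of particle size

    def __post_init__(self) -> None:
        total = self.clay + self.sand + self.silt
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"fractions must sum to 1, got {total:.6f}")
        for name in ("clay", "sand", "silt"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} fraction out of [0, 1]: {v}")
        if not (0.9 <= self.bulk_density <= 2.0):
            raise ValueError(f"bulk density out of range: {self.bulk_density}")
        if self.porosity is None:
            object.__setattr__(self, "porosity", 1.0 - self.bulk_density / 2.65)
        if not (0.2 <= self.porosity <= 0.7):
            raise ValueError(f"porosity out of range: {self.porosity}")


@dataclass(frozen=True)
class SoilHydraulicParams:
    """Brooks-Corey retention/conductivity parameter set."""

    psi_e: float        # air-entry matric potential, MPa (< 0)
    lambda_bc: float    # pore-size distribution index (> 0)
    ks_soil: float      # saturated conductivity, m s-1
    theta_s: float      # saturated water content, m3 m-3
    theta_r: float      # residual water content, m3 m-3
    d_gmean_mm: float = 0.1

    def __post_init__(self) -> None:
        if not (self.psi_e < 0):
            raise ValueError("air-entry potential must be negative")
        if not (self.lambda_bc > 0):
            raise ValueError("lambda must be positive")
        if not (self.ks_soil > 0):
            raise ValueError("Ks must be positive")
        if not (0.0 <= self.theta_r < self.theta_s):
            raise ValueError("need 0 <= theta_r < theta_s")


# ---------------------------------------------------------------------------
# Rawls-Brakensiek (1985) regression coefficients.
# Terms are {(C_pow, S_pow, phi_pow): coefficient}; C = clay %, S = sand %,
# phi = porosity fraction.  hb in cm of water, lambda dimensionless, Ks in
# cm h-1, theta_r in m3 m-3; hb, lambda and Ks regressions are on log scale.
# ---------------------------------------------------------------------------

_RB_BUBBLING_CM = {
    (0, 0, 0): 5.3396738,
    (1, 0, 0): 0.1845038,
    (0, 0, 1): -2.48394546,
    (2, 0, 0): -0.00213853,
    (0, 1, 1): -0.04356349,
    (1, 0, 1): -0.61745089,
    (0, 2, 2): 0.00143598,
    (2, 0, 2): -0.00855375,
    (1, 2, 0): -0.00001282,
    (2, 0, 1): 0.00895359,
    (0, 2, 1): -0.00072472,
    (2, 1, 0): 0.0000054,
    (1, 0, 2): 0.50028060,
}

_RB_LAMBDA = {
    (0, 0, 0): -0.7842831,
    (0, 1, 0): 0.0177544,
    (0, 0, 1): -1.062498,
    (0, 2, 0): -0.00005304,
    (2, 0, 0): -0.00273493,
    (0, 0, 2): 1.11134946,
    (0, 1, 1): -0.03088295,
    (0, 2, 2): 0.00026587,
    (2, 0, 2): -0.00610522,
    (1, 2, 0): -0.00000235,
    (2, 0, 1): 0.00798746,
    (1, 0, 2): -0.00674491,
}

_RB_THETA_R = {
    (0, 0, 0): -0.0182482,
    (0, 1, 0): 0.00087269,
    (1, 0, 0): 0.00513488,
    (0, 0, 1): 0.02939286,
    (2, 0, 0): -0.00015395,
    (0, 1, 1): -0.0010827,
    (2, 0, 2): -0.00018233,
    (2, 0, 1): 0.00030703,
    (1, 0, 2): -0.0023584,
}

_RB_KS_CM_HR = {
    (0, 0, 0): -8.96847,
    (0, 0, 1): 19.52348,
    (1, 0, 0): -0.028212,
    (0, 2, 0): 0.00018107,
    (2, 0, 0): -0.0094125,
    (0, 0, 2): -8.395215,
    (0, 1, 1): 0.077718,
    (0, 2, 2): -0.00298,
    (2, 0, 2): -0.019492,
    (1, 2, 0): 0.0000173,
    (2, 0, 1): 0.02733,
    (0, 2, 1): 0.001434,
    (2, 1, 0): -0.0000035,
}


def _poly(coeffs: dict, clay_pct: float, sand_pct: float, phi: float) -> float:
    return sum(k * clay_pct ** i * sand_pct ** j * phi ** m
               for (i, j, m), k in coeffs.items())


def pedotransfer(texture: SoilTexture) -> SoilHydraulicParams:
    """Derive Brooks-Corey hydraulic parameters from texture.

    Inputs outside the regression's calibration envelope (clay > 0.60 or
    sand > 0.95) are clamped with a warning.  ``theta_s`` is set to porosity;
    ``theta_r`` from the regression, clipped into [0, 0.75 * theta_s].
    """
    clay, sand = texture.clay, texture.sand
    if clay > 0.60 or sand > 0.95 or clay < 0.05 or sand < 0.05:
        warnings.warn("texture outside pedotransfer calibration range; clamping",
                      stacklevel=2)
        clay = min(max(clay, 0.05), 0.60)
        sand = min(max(sand, 0.05), 0.95)
    c_pct, s_pct, phi = 100.0 * clay, 100.0 * sand, texture.porosity

    hb_cm = math.exp(_poly(_RB_BUBBLING_CM, c_pct, s_pct, phi))
    lam = math.exp(_poly(_RB_LAMBDA, c_pct, s_pct, phi))
    ks = math.exp(_poly(_RB_KS_CM_HR, c_pct, s_pct, phi)) * CM_PER_HR_TO_M_PER_S
    theta_s = phi
    theta_r = float(np.clip(_poly(_RB_THETA_R, c_pct, s_pct, phi),
                            0.0, 0.75 * theta_s))
    return SoilHydraulicParams(
        psi_e=-hb_cm * CM_H2O_TO_MPA,
        lambda_bc=lam,
        ks_soil=ks,
        theta_s=theta_s,
        theta_r=theta_r,
        d_gmean_mm=texture.d_gmean_mm,
    )


# ---------------------------------------------------------------------------
# retention and conductivity
# ---------------------------------------------------------------------------

def _effective_saturation(params: SoilHydraulicParams, theta):
    th = np.asarray(theta, dtype=float)
    return (th - params.theta_r) / (params.theta_s - params.theta_r)


def theta_to_psi(params: SoilHydraulicParams, theta):
    """Matric potential (MPa) at volumetric water content ``theta``.

    theta <= theta_r maps to the -inf sentinel via a ValueError; theta above
    theta_s is invalid.
    """
    th = np.asarray(theta, dtype=float)
    if np.any(th > params.theta_s + 1e-12):
        raise ValueError("theta exceeds theta_s")
    if np.any(th <= params.theta_r):
        raise ValueError("theta at or below theta_r: matric potential diverges")
    se = np.clip(_effective_saturation(params, th), None, 1.0)
    psi = params.psi_e * se ** (-1.0 / params.lambda_bc)
    return float(psi) if np.ndim(theta) == 0 else psi


def psi_to_theta(params: SoilHydraulicParams, psi):
    """Water content at matric potential ``psi`` (MPa); psi > psi_e maps to
    saturation (the retention curve is flat above air entry)."""
    p = np.asarray(psi, dtype=float)
    if np.any(p > 0):
        raise ValueError("matric potential must be <= 0 MPa")
    se = np.where(p >= params.psi_e, 1.0,
                  (p / params.psi_e) ** (-params.lambda_bc))
    theta = params.theta_r + se * (params.theta_s - params.theta_r)
    return float(theta) if np.ndim(psi) == 0 else theta


def retention(params: SoilHydraulicParams, value, direction: str):
    """Dispatch between the two retention branches.

    ``direction='theta_to_psi'`` maps water content to potential;
    ``'psi_to_theta'`` is the exact inverse.
    """
    if direction == "theta_to_psi":
        return theta_to_psi(params, value)
    if direction == "psi_to_theta":
        return psi_to_theta(params, value)
    raise ValueError(f"unknown direction {direction!r}")


def unsat_conductivity(params: SoilHydraulicParams, theta):
    """Unsaturated hydraulic conductivity K(theta), m s-1.

    Brooks-Corey/Campbell power law with exponent 3 + 2/lambda; equals
    ks_soil at saturation and is strictly increasing in theta.
    """
    se = np.clip(_effective_saturation(params, theta), 0.0, 1.0)
    k = params.ks_soil * se ** (3.0 + 2.0 / params.lambda_bc)
    return float(k) if np.ndim(theta) == 0 else k


def fc_pwp(params: SoilHydraulicParams) -> tuple[float, float]:
    """Field capacity and permanent wilting point water contents,
    evaluated at -33 kPa and -1500 kPa matric potential."""
    theta_fc = psi_to_theta(params, PSI_FC)
    theta_pwp = psi_to_theta(params, PSI_PWP)
    return theta_fc, theta_pwp
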
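"""Supply-demand plant hydraulic core.

The soil-plant pathway is a network of conducting elements: one rhizosphere
element and one Weibull root element per soil layer, joined in parallel at a
root-crown node, with a single Weibull shoot element above it.  Flux through a
Weibull element between two water potentials uses the Kirchhoff transform of
the conductivity function,

    Phi(x) = k_sat * b * Gamma(1 + 1/c) * P(1/c, (x/b)**c),   x = -psi >= 0,

where P is the regularized lower incomplete gamma function, so element fluxes
are closed-form (E = Phi(x_down) - Phi(x_up)) and the only iteration is on
node potentials.  The supply function E(psi_leaf) is nondecreasing and
saturates at a finite critical transpiration E_crit = the crossing of root
inflow and residual shoot capacity; demand beyond a configurable fraction of
E_crit is capped, representing stomatal closure that prevents runaway
cavitation.

All plant-side fluxes are mmol H2O m-2 leaf s-1 and conductances
mmol m-2 leaf s-1 MPa-1; water potentials are MPa (tensions x = -psi are used
internally).  The saturated whole-plant conductance k_max = E_sat/(psi_pd -
psi_md) is partitioned between shoot and root so the series combination of
saturated plant elements equals k_max exactly; rhizosphere resistance is
additional and vanishes in wet soil.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammainc, gammaincinv

from .soilphys import SoilHydraulicParams, theta_to_psi, unsat_conductivity
from .vcurves import VulnerabilityCurve

__all__ = [
    "GenotypeParams",
    "ContinuumState",
    "WeibullElement",
    "HydraulicNetwork",
    "kmax_saturated",
    "build_continuum",
    "supply_function",
    "solve_demand",
    "stomatal_demand",
    "canopy_temperature",
]

MPA_TO_M_HEAD = 101.97        # m of water column per MPa
MMOL_PER_M3_WATER = 5.5508e7  # mmol H2O per m3 liquid water
CP_AIR_MOLAR = 29.3           # J mol-1 K-1
LAMBDA_VAP = 44.0e3           # J mol-1, latent heat of vaporization


@dataclass(frozen=True)
class GenotypeParams:
    """Hydraulic trait set of one (in-silico) genotype.

    ``gsref`` is stomatal conductance at VPD = 1 kPa (mol m-2 s-1), ``e_sat``
    the transpiration rate at saturated hydraulic conductance
    (mmol m-2 leaf s-1), and ``psi_pd_sat``/``psi_md_sat`` the predawn and
    midday leaf water potentials under fully charged conditions (MPa).
    """

    gsref: float
    e_sat: float
    psi_pd_sat: float
    psi_md_sat: float
    vc_shoot: VulnerabilityCurve
    vc_root: VulnerabilityCurve
    root_to_leaf_area: float = 2.5
    sla: float = 30.5  # m2 leaf kg-1 C, metadata only
    name: str = "species"

    def __post_init__(self) -> None:
        if not (self.psi_md_sat < self.psi_pd_sat < 0):
            raise ValueError("need psi_md_sat < psi_pd_sat < 0")
        if self.e_sat <= 0 or self.gsref <= 0:
            raise ValueError("e_sat and gsref must be positive")


@dataclass
class ContinuumState:
    """Solved state of the continuum at one instant."""

    psi_leaf: float
    e_c: float
    e_crit: float
    k_plant: float
    layer_uptake: np.ndarray
    psi_soil_eff: float
    flagged: bool = False


def kmax_saturated(params: GenotypeParams) -> float:
    """Saturated whole-plant hydraulic conductance,
    k_max = E_sat / (psi_pd - psi_md), mmol m-2 s-1 MPa-1."""
    drop = params.psi_pd_sat - params.psi_md_sat
    if drop == 0:
        raise ZeroDivisionError("psi_pd_sat equals psi_md_sat; k_max undefined")
    return params.e_sat / drop


class WeibullElement:
    """A cavitating conduit with Weibull vulnerability.

    ``k_sat`` is the saturated conductance; the local relative conductivity at
    tension x is exp(-(x/b)**c).
    """

    def __init__(self, k_sat: float, b: float, c: float):
        if k_sat <= 0:
            raise ValueError("element conductance must be positive")
        self.k_sat = float(k_sat)
        self.b = float(b)
        self.c = float(c)
        self._inv_c = 1.0 / self.c
        self._gamma = math.gamma(1.0 + self._inv_c)
        #: Kirchhoff transform at infinite tension (MPa-equivalent length)
        self.phi_max = self.b * self._gamma

    def conductivity(self, x):
        """Relative conductivity (0..1) at tension x (MPa, >= 0)."""
        return np.exp(-((np.asarray(x, dtype=float) / self.b) ** self.c))

    def phi(self, x):
        """Kirchhoff transform integral_0^x exp(-(t/b)^c) dt; increasing,
        bounded by phi_max."""
        x = np.asarray(x, dtype=float)
        return self.phi_max * gammainc(self._inv_c, (x / self.b) ** self.c)

    def phi_inv(self, phi_val: float) -> float:
        """Tension at which the Kirchhoff transform equals ``phi_val``."""
        p = phi_val / self.phi_max
        if p >= 1.0:
            return math.inf
        if p <= 0.0:
            return 0.0
        return self.b * gammaincinv(self._inv_c, p) ** self._inv_c

    def flux(self, x_up: float, x_down: float) -> float:
        """Steady flux from the wetter end (tension x_up) to the drier end
        (x_down >= x_up); never negative."""
        if x_down <= x_up:
            return 0.0
        return self.k_sat * float(self.phi(x_down) - self.phi(x_up))


@dataclass
class _Layer:
    root: WeibullElement
    g_rhiz: float          # linear rhizosphere conductance, same units as k
    x_soil: float          # soil tension, MPa
    frac: float            # root-area fraction

    _RHIZ_INF_RATIO = 1e7  # above this g/k ratio the rhizosphere is treated as ideal


class HydraulicNetwork:
    """Shoot element over parallel (rhizosphere + root) layer branches."""

    def __init__(self, shoot: WeibullElement, layers: Sequence[_Layer],
                 k_max: float, cap_fraction: float = 0.9):
        if not layers:
            raise ValueError("network needs at least one soil layer")
        self.shoot = shoot
        self.layers = list(layers)
        self.k_max = float(k_max)
        self.cap_fraction = float(cap_fraction)
        self.x_soil_min = min(l.x_soil for l in self.layers)

    # -- per-layer flux ----------------------------------------------------
    def _layer_flux(self, layer: _Layer, x_crown: float) -> float:
        if x_crown <= layer.x_soil:
            return 0.0
        root, g = layer.root, layer.g_rhiz
        phi_c = float(root.phi(x_crown))
        phi_s = float(root.phi(layer.x_soil))
        e_ideal = root.k_sat * (phi_c - phi_s)  # flux with ideal rhizosphere
        if e_ideal <= 0.0:
            return 0.0
        if g >= layer._RHIZ_INF_RATIO * root.k_sat:
            return e_ideal

        # solve the series balance in flux space (well-conditioned even for
        # extreme rhizosphere conductances): E = k_r (Phi_c - Phi(x_s + E/g))
        def bal(e):
            return e - root.k_sat * (phi_c
                                     - float(root.phi(layer.x_soil + e / g)))

        return brentq(bal, 0.0, e_ideal, xtol=1e-12, rtol=8.9e-16)

    def inflow(self, x_crown: float) -> float:
        """Total root-crown inflow at crown tension ``x_crown``; increasing."""
        return sum(self._layer_flux(l, x_crown) for l in self.layers)

    def layer_fluxes(self, x_crown: float) -> np.ndarray:
        return np.array([self._layer_flux(l, x_crown) for l in self.layers])

    # -- critical transpiration -------------------------------------------
    def e_crit(self, return_crown: bool = False):
        """Supremum of the supply function: crossing of the increasing root
        inflow and the decreasing residual shoot capacity."""
        sh = self.shoot

        def h(x_c):
            return self.inflow(x_c) - sh.k_sat * (sh.phi_max - float(sh.phi(x_c)))

        lo = self.x_soil_min
        if h(lo) >= 0.0:  # fully dry / no capacity
            return (0.0, lo) if return_crown else 0.0
        hi = lo + 1.0
        while h(hi) < 0.0 and hi < lo + 1e4:
            hi = lo + (hi - lo) * 2.0
        if h(hi) < 0.0:  # pragma: no cover - pathological
            return (0.0, lo) if return_crown else 0.0
        x_c = brentq(h, lo, hi, xtol=1e-10, rtol=8.9e-16)
        e_val = sh.k_sat * (sh.phi_max - float(sh.phi(x_c)))
        return (e_val, x_c) if return_crown else e_val

    # -- supply function ---------------------------------------------------
    def supply(self, psi_leaf: float) -> float:
        """Transpiration sustainable at leaf water potential ``psi_leaf``."""
        x_l = -float(psi_leaf)
        if x_l <= self.x_soil_min:
            return 0.0
        sh = self.shoot
        phi_l = float(sh.phi(x_l))

        def h(x_c):
            return self.inflow(x_c) - sh.k_sat * (phi_l - float(sh.phi(x_c)))

        lo, hi = self.x_soil_min, x_l
        if h(lo) >= 0.0:
            return 0.0
        if h(hi) <= 0.0:  # shoot not limiting at all within [lo, x_l]
            return self.inflow(hi)
        x_c = brentq(h, lo, hi, xtol=1e-10, rtol=8.9e-16)
        return sh.k_sat * (phi_l - float(sh.phi(x_c)))

    # -- demand solve ------------------------------------------------------
    def saturated_layer_weights(self) -> np.ndarray:
        """Series conductance of each layer branch at its current rhizosphere
        state, used to weight soil potentials at zero flux."""
        w = []
        for l in self.layers:
            g = min(l.g_rhiz, l._RHIZ_INF_RATIO * l.root.k_sat)
            w.append(1.0 / (1.0 / l.root.k_sat + 1.0 / g))
        return np.asarray(w)

    def solve(self, e_target: float) -> ContinuumState:
        """Find the continuum state transporting ``e_target`` (or the capped
        flux if the target exceeds the regulated supply limit)."""
        if e_target < 0:
            raise ValueError("e_target must be >= 0")
        e_crit, x_crit = self.e_crit(return_crown=True)
        cap = self.cap_fraction * e_crit
        flagged = e_target >= cap and e_target > 0.0
        e_c = min(e_target, cap)

        if e_c <= 0.0 or e_crit <= 0.0:
            w = self.saturated_layer_weights()
            x_soil = np.array([l.x_soil for l in self.layers])
            x_eff = float(np.average(x_soil, weights=w))
            k_sat_net = 1.0 / (1.0 / self.shoot.k_sat + 1.0 / w.sum())
            return ContinuumState(
                psi_leaf=-x_eff, e_c=0.0, e_crit=e_crit, k_plant=k_sat_net,
                layer_uptake=w / w.sum(), psi_soil_eff=-x_eff, flagged=flagged)

        def g(x_c):
            return self.inflow(x_c) - e_c

        x_c = brentq(g, self.x_soil_min, x_crit, xtol=1e-10, rtol=8.9e-16)
        fluxes = self.layer_fluxes(x_c)
        total = fluxes.sum()
        uptake = fluxes / total if total > 0 else fluxes
        x_soil = np.array([l.x_soil for l in self.layers])
        x_eff = float(np.dot(uptake, x_soil))

        sh = self.shoot
        x_l = sh.phi_inv(float(sh.phi(x_c)) + e_c / sh.k_sat)
        if not math.isfinite(x_l):  # capped exactly at shoot capacity edge
            x_l = sh.phi_inv((1.0 - 1e-12) * sh.phi_max)
        drawdown = x_l - x_eff
        k_plant = e_c / drawdown if drawdown > 0 else self.k_max
        return ContinuumState(
            psi_leaf=-x_l, e_c=e_c, e_crit=e_crit, k_plant=k_plant,
            layer_uptake=uptake, psi_soil_eff=-x_eff, flagged=flagged)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def rhizosphere_conductance(soil: SoilHydraulicParams, theta: float,
                            root_area_index: float, lai: float,
                            geometry_factor: float = 50.0) -> float:
    """Linear rhizosphere conductance on a leaf-area basis.

    K(theta) over a characteristic length set by the geometric mean particle
    diameter times ``geometry_factor``, scaled by the absorbing root area per
    ground area and converted to mmol m-2 leaf s-1 MPa-1.  Very large in wet
    soil (the plant limits); collapses nonlinearly as the soil dries.
    """
    k_soil = unsat_conductivity(soil, theta)  # m s-1
    d_char = geometry_factor * soil.d_gmean_mm * 1e-3  # m
    g_ground = k_soil * (MPA_TO_M_HEAD / d_char) * MMOL_PER_M3_WATER * root_area_index
    return min(g_ground / lai, 1e12)


def build_continuum(
    params: GenotypeParams,
    soil_layers: Sequence[tuple[SoilHydraulicParams, float]],
    lai: float,
    root_profile: Sequence[float],
    resistance_split: float = 0.5,
    cap_fraction: float = 0.9,
    rhiz_geometry_factor: float = 50.0,
) -> HydraulicNetwork:
    """Assemble the element network for one genotype on a layered soil.

    ``soil_layers`` is a sequence of (hydraulic params, theta) per layer;
    ``root_profile`` gives root-area fractions summing to 1.
    ``resistance_split`` is the shoot share of the saturated whole-plant
    resistance (0.5 = the equal-split default).
    """
    fracs = np.asarray(root_profile, dtype=float)
    if len(fracs) != len(soil_layers):
        raise ValueError("root_profile length must match soil_layers")
    if abs(fracs.sum() - 1.0) > 1e-8:
        raise ValueError("root_profile must sum to 1")
    if np.all(fracs <= 0.0):
        raise ValueError("zero root area in all layers")
    if not (0.0 < resistance_split < 1.0):
        raise ValueError("resistance_split must be in (0, 1)")

    k_max = kmax_saturated(params)
    k_shoot = k_max / resistance_split
    k_root_total = k_max / (1.0 - resistance_split)

    shoot = WeibullElement(k_shoot, params.vc_shoot.b, params.vc_shoot.c)
    layers = []
    for frac, (soil, theta) in zip(fracs, soil_layers):
        if frac <= 0.0:
            continue
        psi_soil = theta_to_psi(soil, min(theta, soil.theta_s)) \
            if theta > soil.theta_r else -50.0
        g = rhizosphere_conductance(
            soil, theta, lai * params.root_to_leaf_area * frac, lai,
            geometry_factor=rhiz_geometry_factor)
        layers.append(_Layer(
            root=WeibullElement(k_root_total * frac,
                                params.vc_root.b, params.vc_root.c),
            g_rhiz=max(g, 1e-12), x_soil=-psi_soil, frac=float(frac)))
    return HydraulicNetwork(shoot, layers, k_max, cap_fraction=cap_fraction)


# functional wrappers mirroring the operation-level API --------------------

def supply_function(network: HydraulicNetwork, psi_leaf_grid=None):
    """Tabulate the supply curve E(psi_leaf) and return it with E_crit."""
    e_crit = network.e_crit()
    if psi_leaf_grid is None:
        x0 = network.x_soil_min
        psi_leaf_grid = -(x0 + np.linspace(0.0, 8.0, 81) ** 1.5)
    e_vals = np.array([network.supply(p) for p in psi_leaf_grid])
    return np.asarray(psi_leaf_grid), e_vals, e_crit


def solve_demand(network: HydraulicNetwork, e_target: float) -> ContinuumState:
    return network.solve(e_target)


# ---------------------------------------------------------------------------
# stomatal demand and canopy temperature
# ---------------------------------------------------------------------------

def stomatal_demand(params: GenotypeParams, vpd: float, lai: float,
                    par: float = 2000.0, patm: float = 101.3,
                    oren_m: float = 0.6, par_ref: float = 2000.0,
                    par_half: float = 250.0) -> float:
    """Unregulated transpiration demand on a ground-area basis
    (mmol H2O m-2 ground s-1).

    Stomatal conductance follows the Oren logarithmic VPD response
    G_s(D) = max(0, G_sref (1 - m ln D)) scaled by a saturating light factor
    normalized to 1 at the cuvette reference PAR.
    """
    if vpd <= 0:
        raise ValueError("vpd must be positive (kPa)")
    g_s = max(0.0, params.gsref * (1.0 - oren_m * math.log(vpd)))
    light = (par / (par + par_half)) / (par_ref / (par_ref + par_half))
    g_s *= max(0.0, light)
    return g_s * (vpd / patm) * lai * 1e3


def boundary_layer_conductance(wind: float, lai: float,
                               leaf_dim: float = 0.1) -> float:
    """Two-sided canopy heat conductance, mol m-2 ground s-1 (flat-plate
    forced convection, 0.135 sqrt(u/d) per side per unit leaf area)."""
    u = max(wind, 0.1)
    g_per_leaf = 1.4 * 0.135 * math.sqrt(u / leaf_dim)
    return g_per_leaf * lai


def canopy_temperature(t_air: float, par: float, wind: float,
                       e_c_ground: float, lai: float,
                       rad_absorb: float = 0.283,
                       leaf_dim: float = 0.1) -> float:
    """Single-leaf (big-leaf) energy balance canopy temperature, deg C.

    T_c = T_air + (R_n_abs - lambda E) / (rho_a c_p g_H); absorbed net
    radiation is taken proportional to PAR (``rad_absorb`` W m-2 per
    umol m-2 s-1) and latent flux from transpiration ``e_c_ground``
    (mmol m-2 ground s-1).  A transpiring canopy in high advective demand can
    be cooler than the air.
    """
    g_h = boundary_layer_conductance(wind, max(lai, 0.1), leaf_dim)
    if g_h <= 0:
        raise ValueError("boundary-layer conductance must be positive")
    rn_abs = rad_absorb * par
    latent = LAMBDA_VAP * e_c_ground * 1e-3
    return t_air + (rn_abs - latent) / (CP_AIR_MOLAR * g_h)
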
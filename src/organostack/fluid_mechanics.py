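"""Pressure and geometry primitives for fluid-walled stacked-module culture.

Aqueous towers confined by an immiscible fluorocarbon (FC40) on a Petri dish
are shaped by two competing forces: hydrostatic pressure ``P = rho*g*h`` and
the Laplace pressure jump ``2*gamma/R`` across each curved medium:FC40
interface.  Because FC40 is denser than medium, a *taller* stack of medium
sits under a smaller head of fluorocarbon, and differences in effective head
between two connected stacks drive pump-free flow; spherical caps pinned on
stack openings oppose or assist that flow through their Laplace pressures.

Everything here is in SI units (m, kg, s, Pa).  Convenience constants carry
the platform's default working fluids: cell-growth medium (DMEM + 10% FBS)
under FC40.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "InvalidGeometryError",
    "ConfigurationError",
    "Liquid",
    "SphericalCap",
    "AnnularElement",
    "StackSpec",
    "Environment",
    "FlowDirection",
    "GapStability",
    "MEDIUM",
    "FC40_DENSITY",
    "GAMMA_MEDIUM_FC40",
    "STANDARD_GRAVITY",
    "DEFAULT_ENVIRONMENT",
    "FLOW_TOLERANCE_PA",
    "GAP_STABLE_MAX",
    "GAP_UNSTABLE_MIN",
    "hydrostatic_pressure",
    "laplace_pressure",
    "cap_from_height",
    "cap_from_volume",
    "laplace_at_angle",
    "flow_direction",
    "boundary_delta_h",
    "bud_volume",
    "gap_stability",
]


class InvalidGeometryError(ValueError):
    """A geometric argument (height, radius, ...) is outside its valid range."""


class ConfigurationError(ValueError):
    """A circuit/stack description is inconsistent or incomplete."""


# --- default physical parameters -------------------------------------------
#: gravitational acceleration, m/s^2
STANDARD_GRAVITY = 9.81
#: FC40 density, kg/m^3 (~1.8x water; configurable)
FC40_DENSITY = 1855.0
#: interfacial tension of DMEM+10% FBS against FC40, N/m
GAMMA_MEDIUM_FC40 = 0.023
#: |net pressure| below this is reported as indeterminate, Pa
FLOW_TOLERANCE_PA = 0.1
#: gap_stability calibration: buoyancy/pinning ratio thresholds (dimensionless)
GAP_STABLE_MAX = 0.7
GAP_UNSTABLE_MIN = 1.3


@dataclass(frozen=True)
class Liquid:
    """A working liquid and the constants every pressure computation needs.

    ``gamma_vs_fc40`` is the interfacial tension against FC40 and is ``None``
    for FC40 itself.
    """

    name: str
    density: float  # kg/m^3
    viscosity: float  # Pa*s
    gamma_vs_fc40: Optional[float] = None  # N/m

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")
        if self.viscosity <= 0:
            raise ValueError(f"viscosity must be positive, got {self.viscosity}")
        if self.gamma_vs_fc40 is not None and self.gamma_vs_fc40 <= 0:
            raise ValueError("gamma_vs_fc40 must be positive when present")


#: DMEM + 10% FBS at 25 C under FC40
MEDIUM = Liquid("medium", density=998.0, viscosity=0.89e-3,
                gamma_vs_fc40=GAMMA_MEDIUM_FC40)


@dataclass(frozen=True)
class SphericalCap:
    """A spherical cap of medium pinned on a circular opening.

    The cap is pinned at the opening's inner edge (base radius ``a``); its
    height ``h`` above the rim fixes the curvature radius
    ``R = (a^2 + h^2) / (2h)``, the contact angle ``theta = 2*atan(h/a)``
    (degrees; 90 deg at the hemisphere ``h = a``) and the volume
    ``V = pi*h*(3a^2 + h^2)/6``.  Build instances with :func:`cap_from_height`.
    """

    base_radius: float  # m
    height: float  # m
    curvature_radius: float  # m; inf for a flat cap
    contact_angle: float  # degrees, 0..180
    volume: float  # m^3


@dataclass(frozen=True)
class AnnularElement:
    """One washer/module layer in a stack (annulus seen from above)."""

    outer_diameter: float  # m
    inner_diameter: float  # m
    thickness: float  # m
    material: str = "hydrophilic"  # or "hydrophobic"
    permeability: Optional[float] = None  # m^2; None = open bore

    def __post_init__(self) -> None:
        if not self.inner_diameter < self.outer_diameter:
            raise ValueError("inner_diameter must be < outer_diameter")
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")
        if self.material not in ("hydrophilic", "hydrophobic"):
            raise ValueError(f"unknown material {self.material!r}")


@dataclass(frozen=True)
class StackSpec:
    """A vertical stack of annular elements, optionally topped by a cap."""

    elements: tuple[AnnularElement, ...]
    cap: Optional[SphericalCap] = None
    label: str = ""

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("a stack needs at least one element")

    @property
    def stack_height(self) -> float:
        """Total height (sum of element thicknesses), m."""
        return sum(e.thickness for e in self.elements)

    @property
    def opening_diameter(self) -> float:
        """Inner diameter of the topmost element (the cap opening), m."""
        return self.elements[-1].inner_diameter


@dataclass(frozen=True)
class Environment:
    """Dish-level context shared by every pressure computation."""

    gravity: float = STANDARD_GRAVITY
    fc40_density: float = FC40_DENSITY
    dish_height: float = 13e-3  # max FC40 fill of a 60 mm dish, m
    medium: Liquid = field(default_factory=lambda: MEDIUM)

    def __post_init__(self) -> None:
        if self.gravity <= 0:
            raise ValueError("gravity must be positive")
        if self.fc40_density <= self.medium.density:
            raise ValueError("FC40 must be denser than the medium")

    @property
    def density_difference(self) -> float:
        """rho_FC40 - rho_medium, kg/m^3 (drives the head-difference term)."""
        return self.fc40_density - self.medium.density

    @property
    def gamma(self) -> float:
        g = self.medium.gamma_vs_fc40
        if g is None:
            raise ConfigurationError(
                f"liquid {self.medium.name!r} has no interfacial tension vs FC40")
        return g


DEFAULT_ENVIRONMENT = Environment()


class FlowDirection(str, enum.Enum):
    A_TO_B = "a_to_b"
    B_TO_A = "b_to_a"
    INDETERMINATE = "indeterminate"


class GapStability(str, enum.Enum):
    STABLE = "stable"
    MARGINAL = "marginal"
    UNSTABLE = "unstable"


# --- elementary pressures ---------------------------------------------------

def hydrostatic_pressure(density: float, height: float,
                         gravity: float = STANDARD_GRAVITY) -> float:
    """Hydrostatic head ``rho*g*h`` in Pa.

    Raises :class:`InvalidGeometryError` for a negative column height.
    """
    if density <= 0:
        raise ValueError(f"density must be positive, got {density}")
    if height < 0:
        raise InvalidGeometryError(f"column height must be >= 0, got {height}")
    return density * gravity * height


def laplace_pressure(gamma: float, curvature_radius: float) -> float:
    """Young-Laplace pressure jump ``2*gamma/R`` across a spherical interface.

    ``curvature_radius`` may be ``inf`` (flat interface, zero jump).
    """
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    if math.isinf(curvature_radius):
        return 0.0
    if curvature_radius <= 0:
        raise InvalidGeometryError(
            f"curvature radius must be positive, got {curvature_radius}")
    return 2.0 * gamma / curvature_radius


# --- spherical-cap geometry --------------------------------------------------

def cap_from_height(base_radius: float, height: float) -> SphericalCap:
    """Construct the spherical cap of height ``height`` pinned at ``base_radius``.

    ``height`` runs from 0 (flat interface: infinite curvature radius, zero
    volume) through the hemisphere at ``height == base_radius`` (90 deg) up to
    the full-sphere limit at twice the base radius; anything taller would have
    detached and is rejected.
    """
    if base_radius <= 0:
        raise InvalidGeometryError(f"base radius must be positive, got {base_radius}")
    if height < 0:
        raise InvalidGeometryError(f"cap height must be >= 0, got {height}")
    if height > 2.0 * base_radius:
        raise InvalidGeometryError(
            f"cap height {height} exceeds opening diameter {2 * base_radius}")
    a, h = base_radius, height
    if h == 0.0:
        return SphericalCap(a, 0.0, math.inf, 0.0, 0.0)
    R = (a * a + h * h) / (2.0 * h)
    theta = math.degrees(2.0 * math.atan2(h, a))
    V = math.pi * h * (3.0 * a * a + h * h) / 6.0
    return SphericalCap(a, h, R, theta, V)


def cap_from_volume(base_radius: float, volume: float) -> SphericalCap:
    """Invert the cap volume relation: the cap holding ``volume`` at ``base_radius``.

    Solves the depressed cubic ``h^3 + 3 a^2 h - 6V/pi = 0`` (single real
    root, by Cardano) and defers to :func:`cap_from_height`.
    """
    if volume < 0:
        raise InvalidGeometryError(f"cap volume must be >= 0, got {volume}")
    if volume == 0.0:
        return cap_from_height(base_radius, 0.0)
    a = base_radius
    p = 3.0 * a * a
    q = -6.0 * volume / math.pi
    disc = math.sqrt(q * q / 4.0 + p ** 3 / 27.0)
    h = math.cbrt(-q / 2.0 + disc) + math.cbrt(-q / 2.0 - disc)
    return cap_from_height(a, h)


def laplace_at_angle(gamma: float, base_radius: float,
                     contact_angle: float) -> float:
    """Laplace pressure of a pinned cap expressed through its contact angle.

    For a cap pinned at opening radius ``a`` the curvature radius is
    ``R = a / sin(theta)``, so the pressure is ``2*gamma*sin(theta)/a`` -
    zero for a flat interface and maximal at 90 deg (hemisphere), where it
    equals ``2*gamma/a``.
    """
    if not 0.0 <= contact_angle <= 180.0:
        raise InvalidGeometryError(
            f"contact angle must be in [0, 180] deg, got {contact_angle}")
    if base_radius <= 0:
        raise InvalidGeometryError(f"base radius must be positive, got {base_radius}")
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    return 2.0 * gamma * math.sin(math.radians(contact_angle)) / base_radius


# --- flow-direction criterion ------------------------------------------------

def _cap_pressure(stack: StackSpec, gamma: float) -> float:
    if stack.cap is None:
        raise ConfigurationError(
            f"stack {stack.label or '?'} has no cap but mode='current_caps'")
    return laplace_at_angle(gamma, stack.cap.base_radius, stack.cap.contact_angle) \
        if stack.cap.height > 0 else 0.0


def flow_direction(stack_a: StackSpec, stack_b: StackSpec,
                   env: Environment = DEFAULT_ENVIRONMENT,
                   mode: str = "worst_case",
                   density_convention: str = "difference",
                   tolerance: float = FLOW_TOLERANCE_PA,
                   ) -> tuple[FlowDirection, float]:
    """Which way does medium flow between two stacks sharing a wetted base?

    The net driving pressure (positive pushes A -> B) is::

        rho_eff * g * (h_B - h_A) + (P_cap_A - P_cap_B)

    A taller stack B displaces more of the dense FC40 above it, lowering
    the pressure at its base; with ``density_convention="difference"``
    (default) ``rho_eff = rho_FC40 - rho_medium``, the physically correct
    head for fully submerged stacks.  ``density_convention="medium"``
    reproduces the bare-``rho`` convention sometimes used for the boundary
    curve.

    ``mode="worst_case"`` asks whether either direction is *guaranteed*:
    for each candidate direction the opposing cap is taken at its 90-deg
    Laplace maximum and the assisting cap flat, giving the worst-case
    margins ``m_ab = head - P90_B`` and ``m_ba = -head - P90_A``.  A margin
    above ``tolerance`` fixes the direction (the returned net pressure is
    that signed margin); otherwise the result is ``INDETERMINATE`` with the
    symmetric mid-estimate ``head + (P90_A - P90_B)/2``.
    ``mode="current_caps"`` uses the caps as given (both stacks need one)
    and the sign of the net pressure decides.
    Returns ``(direction, net_pressure_Pa)``.
    """
    if density_convention == "difference":
        rho_eff = env.density_difference
    elif density_convention == "medium":
        rho_eff = env.medium.density
    else:
        raise ValueError(f"unknown density_convention {density_convention!r}")
    gamma = env.gamma
    head = rho_eff * env.gravity * (stack_b.stack_height - stack_a.stack_height)

    if mode == "worst_case":
        max_a = laplace_at_angle(gamma, stack_a.opening_diameter / 2, 90.0)
        max_b = laplace_at_angle(gamma, stack_b.opening_diameter / 2, 90.0)
        m_ab = head - max_b  # cap A flat, cap B fully opposing
        m_ba = -head - max_a  # cap B flat, cap A fully opposing
        if m_ab > tolerance:
            return FlowDirection.A_TO_B, m_ab
        if m_ba > tolerance:
            return FlowDirection.B_TO_A, -m_ba
        return FlowDirection.INDETERMINATE, head + (max_a - max_b) / 2.0
    if mode == "current_caps":
        net = head + _cap_pressure(stack_a, gamma) - _cap_pressure(stack_b, gamma)
        if abs(net) < tolerance:
            return FlowDirection.INDETERMINATE, net
        return (FlowDirection.A_TO_B if net > 0 else FlowDirection.B_TO_A), net
    raise ValueError(f"unknown mode {mode!r}")


def boundary_delta_h(inner_diameter: float,
                     gamma: float = GAMMA_MEDIUM_FC40,
                     density: float = MEDIUM.density,
                     gravity: float = STANDARD_GRAVITY) -> float:
    """Stack-height difference at which hydrostatic and Laplace drives balance.

    With the opposing cap at its 90-deg maximum (``R = ID/2``) and the
    assisting cap flat, the worst-case opposing Laplace pressure ``4*gamma/ID``
    equals the head difference ``rho*g*dh`` at::

        dh* = 4*gamma / (rho * g * ID)

    Flow in the intended direction is guaranteed whenever ``dh > dh*``.
    ``density`` is whichever convention the caller adopts (bare medium
    density for the published curve, or the FC40-medium difference).
    """
    if min(inner_diameter, gamma, density, gravity) <= 0:
        raise ValueError("all arguments must be positive")
    return 4.0 * gamma / (density * gravity * inner_diameter)


# --- stability heuristics -----------------------------------------------------

def bud_volume(inner_diameter: float,
               gamma: float = GAMMA_MEDIUM_FC40,
               density_difference: float = FC40_DENSITY - MEDIUM.density,
               gravity: float = STANDARD_GRAVITY) -> float:
    """Cap volume beyond which an over-filled cap buds off and floats.

    Force-balance heuristic: the buoyancy of the medium cap immersed in
    denser FC40, ``(rho_FC40 - rho_medium) * g * V``, exceeds the maximum
    contact-line pinning force ``gamma * pi * ID`` when::

        V* = gamma * pi * ID / (drho * g)

    Callers compare a running cap volume against ``V*``.
    """
    if min(inner_diameter, gamma, density_difference, gravity) <= 0:
        raise ValueError("all arguments must be positive")
    return gamma * math.pi * inner_diameter / (density_difference * gravity)


def gap_stability(gap_height: float, inner_diameter: float,
                  env: Environment = DEFAULT_ENVIRONMENT) -> GapStability:
    """Classify an exposed medium column spanning a gap between stacked washers.

    Compares buoyancy on the exposed column,
    ``drho * g * pi * (ID/2)^2 * gap``, against contact-line pinning
    ``gamma * pi * ID``; the dimensionless ratio ``drho*g*ID*gap/(4*gamma)``
    is cut at :data:`GAP_STABLE_MAX` and :data:`GAP_UNSTABLE_MIN` -
    calibrated so that at platform defaults 1 mm gaps are stable (carried
    around a lab), 2 mm marginal (carried carefully) and 4 mm unstable.
    """
    if gap_height < 0:
        raise InvalidGeometryError(f"gap height must be >= 0, got {gap_height}")
    if gap_height == 0.0:
        return GapStability.STABLE
    if inner_diameter <= 0:
        raise InvalidGeometryError("inner diameter must be positive")
    ratio = (env.density_difference * env.gravity * inner_diameter * gap_height
             / (4.0 * env.gamma))
    if ratio < GAP_STABLE_MAX:
        return GapStability.STABLE
    if ratio <= GAP_UNSTABLE_MIN:
        return GapStability.MARGINAL
    return GapStability.UNSTABLE
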
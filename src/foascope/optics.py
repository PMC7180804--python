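"""Closed-form design calculations for a tapered fiber-optic array (FOA).

A tapered FOA is a fused bundle of optical fibers used as a magnifying
relay between a specimen (small end) and an image sensor (large end).
This module collects the standard design quantities for such a device:

* the normalized frequency (V number) of a tapered fiber and the
  single-mode criterion ``V < 2.405``,
* the per-reflection incidence angle and mode feature angle of a ray
  propagating from the small end up the taper,
* the evanescent-wave penetration depth at the core/cladding interface,
* hexagonal-lattice packing (effective light-transmission area fraction)
  and the resolution advantage of hexagonal over square core packing,
* field-of-view area comparison between two imaging systems.

All angles are radians, all lengths are micrometres, and all refractive
indices are absolute (dimensionless). Degree conversion is offered only
at the command line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import EvanescentRegimeError, ParameterError

__all__ = [
    "TaperedFiberSpec",
    "FieldOfView",
    "SINGLE_MODE_CUTOFF",
    "v_number",
    "is_single_mode",
    "incident_angle",
    "mode_feature_angle",
    "penetration_depth",
    "transmission_area_fraction",
    "resolution_period",
    "hex_over_square_gain",
    "fov_area_ratio",
]

#: Cutoff of the fundamental-mode-only regime for a step-index fiber
#: (first zero of the Bessel function J0).
SINGLE_MODE_CUTOFF = 2.405


@dataclass(frozen=True)
class TaperedFiberSpec:
    """All optical parameters of the taper in one place.

    The V-number formula and the evanescent-depth formula each involve a
    pair of refractive indices whose conventional names collide; they are
    stored as distinct fields so each formula reads its own pair:

    ``ncl``/``next``
        core and surrounding indices entering the V number.
    ``n0``/``n1``
        core and cladding indices entering the reflection-angle and
        mode-feature-angle recursions.
    ``nco``/``ncl6``
        core and cladding indices entering the penetration depth; the
        radicand ``nco**2 sin**2(theta) - ncl6**2`` is positive only when
        ``nco`` is the core index under total internal reflection.

    Parameters
    ----------
    r : float
        Core radius at the small end, µm.
    lambda_ : float
        Vacuum wavelength of the illumination, µm.
    theta_s : float
        Entry angle at the small end, rad.
    delta : float
        Taper cone angle entering the incidence-angle recursion, rad.
    alpha : float
        Taper cone angle entering the mode-feature-angle recursion, rad.
    theta : float
        Incidence angle at the core/cladding interface for the
        penetration-depth formula, rad.
    d, D : float
        Core radius and whole-fiber radius used by the lattice/packing
        formulas, µm.
    """

    r: float = 0.6
    lambda_: float = 0.55
    ncl: float = 1.52
    next: float = 1.50
    n0: float = 1.52
    n1: float = 1.50
    nco: float = 1.52
    ncl6: float = 1.50
    theta_s: float = 0.3
    delta: float = 0.02
    alpha: float = 0.02
    theta: float = 1.2
    d: float = 0.61
    D: float = 0.72

    def __post_init__(self) -> None:
        for name in ("ncl", "next", "n0", "n1", "nco", "ncl6"):
            if getattr(self, name) <= 1.0:
                raise ParameterError(f"refractive index {name} must exceed 1")
        for name in ("r", "lambda_", "d", "D"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.d > self.D:
            raise ParameterError("core radius d cannot exceed fiber radius D")


@dataclass(frozen=True)
class FieldOfView:
    """Imaged specimen area as width x height, µm."""

    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ParameterError("field-of-view dimensions must be positive")

    @property
    def area(self) -> float:
        return self.width * self.height


def v_number(spec: TaperedFiberSpec) -> float:
    """Normalized frequency V = 2*pi*r/lambda * sqrt(ncl^2 - next^2).

    ``V < 2.405`` means only the fundamental HE11 mode propagates; a
    weakly guiding taper is designed into this regime to suppress
    intermodal dispersion and hence image distortion.
    """
    if spec.ncl < spec.next:
        raise ParameterError(
            "guiding index ncl must be at least the surrounding index next"
        )
    na = math.sqrt(spec.ncl**2 - spec.next**2)
    return 2.0 * math.pi * spec.r / spec.lambda_ * na


def is_single_mode(spec: TaperedFiberSpec) -> bool:
    """True when the taper supports only the fundamental mode."""
    return v_number(spec) < SINGLE_MODE_CUTOFF


def _refracted_entry_angle(spec: TaperedFiberSpec) -> float:
    if abs(spec.theta_s) > 1.0:
        raise ParameterError(
            "entry angle theta_s outside the arcsin domain [-1, 1]"
        )
    return (spec.n0 / spec.n1) * math.asin(spec.theta_s)


def incident_angle(n: int, spec: TaperedFiberSpec) -> float:
    """Incidence angle at the n-th core/cladding reflection in the taper.

    ``phi_n = pi/2 - (n0/n1) * arcsin(theta_s) + (2n - 1) * delta / 2``

    Strictly increasing in ``n`` whenever the cone angle ``delta`` is
    positive: each successive reflection up the taper is more grazing, so
    total internal reflection is never broken on the way from the small
    end to the large end.
    """
    if n < 1 or int(n) != n:
        raise ParameterError("reflection count n must be a positive integer")
    return math.pi / 2 - _refracted_entry_angle(spec) + (2 * n - 1) * spec.delta / 2


def mode_feature_angle(n: int, spec: TaperedFiberSpec) -> float:
    """Feature angle of the propagating mode after n reflections.

    ``theta_n = (n0/n1) * arcsin(theta_s) - (n - 1) * alpha``

    Strictly decreasing in ``n`` for a positive cone angle ``alpha``: the
    mode order drops with each reflection, concentrating energy in the
    core; a larger cone angle makes the drop faster.
    """
    if n < 1 or int(n) != n:
        raise ParameterError("reflection count n must be a positive integer")
    return _refracted_entry_angle(spec) - (n - 1) * spec.alpha


def penetration_depth(spec: TaperedFiberSpec) -> float:
    """Evanescent-wave penetration depth at the core/cladding interface.

    ``dp = lambda / (2*pi*sqrt(nco^2 sin^2(theta) - ncl6^2))``, µm.

    Defined only in the total-internal-reflection regime
    ``nco*sin(theta) > ncl6``; strictly decreasing in ``theta`` there, so
    the steepening reflections up the taper leak less near-field light.
    """
    radicand = (spec.nco * math.sin(spec.theta)) ** 2 - spec.ncl6**2
    if radicand <= 0:
        raise EvanescentRegimeError(
            "nco*sin(theta) must exceed ncl6: no total internal reflection, "
            "penetration depth undefined"
        )
    return spec.lambda_ / (2.0 * math.pi * math.sqrt(radicand))


def transmission_area_fraction(d: float, D: float) -> float:
    """Effective light-transmission area fraction of hexagonally packed cores.

    ``(pi / 3.464) * (d / D)**2`` with core radius ``d`` and fiber radius
    ``D`` (3.464 = 2*sqrt(3), the hexagonal packing constant). Bounded
    above by pi/(2*sqrt(3)) ~= 0.9069, attained when the cores touch.
    """
    if d <= 0 or D <= 0:
        raise ParameterError("radii must be positive")
    if d > D:
        raise ParameterError("core radius d cannot exceed fiber radius D")
    return (math.pi / 3.464) * (d / D) ** 2


def resolution_period(d: float, arrangement: str = "hexagonal") -> float:
    """Smallest resolvable spatial period of a core lattice, µm.

    The sampling frequency of a hexagonal lattice of core radius ``d``
    (touching fibers) is 1/(sqrt(3)*d) and of a square lattice 1/(2*d);
    the resolvable periods are the reciprocals ``sqrt(3)*d`` and ``2*d``.
    """
    if d <= 0:
        raise ParameterError("core radius must be positive")
    if arrangement == "hexagonal":
        return math.sqrt(3.0) * d
    if arrangement == "square":
        return 2.0 * d
    raise ParameterError(f"unknown arrangement {arrangement!r}")


def hex_over_square_gain() -> float:
    """Resolution gain of hexagonal over square core packing, 2/sqrt(3) ~= 1.15."""
    return 2.0 / math.sqrt(3.0)


def fov_area_ratio(a: FieldOfView | tuple, b: FieldOfView | tuple) -> float:
    """Area ratio of two fields of view (a over b)."""
    if not isinstance(a, FieldOfView):
        a = FieldOfView(*a)
    if not isinstance(b, FieldOfView):
        b = FieldOfView(*b)
    return a.area / b.area
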
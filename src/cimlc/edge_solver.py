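"""Solve for the diverging ray whose leaf chord equals a survival path.

The radiation field edge of a rectangular-ended leaf is set by attenuation
along slant chords through the leaf end.  A ray at angle ``t`` from the axis
(with ``theta < t < theta_dprime``) enters the vertical end face at axial
depth ``z_enter = x_leaf / tan(t)`` and exits through the leaf bottom, so its
material chord is::

    chord(t) = (z_bottom - x_leaf / tan t) / cos t

which rises monotonically from 0 at ``theta`` to the full slant thickness at
``theta_dprime``.  The p-fraction dose point on the isocenter axis is the
projection ``sad * tan(t*)`` of the unique ``t*`` with
``chord(t*) = -lambda * ln(p)``.

The equivalent fixed point ``z_enter = z_bottom - d_p * cos(atan(x_leaf /
z_enter))`` is a contraction at the sub-2-degree angles of this beamline and
converges to machine precision in a handful of iterations; no randomness or
bracketing tolerance is involved.
"""

from __future__ import annotations

import math

from .errors import CimlcError, InsufficientThicknessError, ValidationError
from .geometry import (
    BeamlineGeometry,
    EdgeSolution,
    LeafSetting,
    divergence_angles,
    leaf_lateral_position,
    x_mlc,
    x_tang,
)
from .materials import Material, path_for_survival

__all__ = [
    "chord_length",
    "solve_x_p",
    "offset",
    "light_radiation_agreement",
    "model_penumbra",
    "solve_edge",
]

_FIXED_POINT_TOL_CM = 1e-12
_RESIDUAL_TOL_CM = 1e-8
_MAX_ITER = 200


def chord_length(t: float, x_leaf: float, z_bottom: float, thickness: float) -> float:
    """Material chord (cm) of a ray at angle ``t`` through the leaf slab.

    ``x_leaf`` and ``t`` are magnitudes (mirror symmetry handles signs).
    Rays below ``theta`` miss the leaf; rays above ``theta_dprime`` cross the
    full slant thickness.
    """
    if t <= 0.0:
        return 0.0
    z_enter = x_leaf / math.tan(t)
    z_top = z_bottom - thickness
    if z_enter >= z_bottom:
        return 0.0
    return (z_bottom - max(z_enter, z_top)) / math.cos(t)


def solve_x_p(
    setting: LeafSetting,
    material: Material,
    geom: BeamlineGeometry,
    p: float = 0.5,
) -> float:
    """Axis position (cm) of the p-fraction dose point behind the leaf edge.

    ``p`` is the survival (relative dose) fraction in (0, 1).  The zero-field
    setting is the exact degenerate limit and returns 0.
    """
    if not (0.0 < p < 1.0):
        raise ValidationError(f"survival fraction must lie in (0, 1), got {p}")
    xl_signed = leaf_lateral_position(setting, geom)
    if xl_signed == 0.0:
        return 0.0
    sign = math.copysign(1.0, xl_signed)
    x_leaf = abs(xl_signed)
    z_bottom, _, z_top = geom.leaf_planes(material)
    d_p = path_for_survival(p, material)

    theta_dprime = math.atan2(x_leaf, z_top)
    max_chord = material.thickness_cm / math.cos(theta_dprime)
    if d_p >= max_chord:
        raise InsufficientThicknessError(
            f"survival path {d_p:.4g} cm for p={p} exceeds the maximum leaf-end "
            f"chord {max_chord:.4g} cm of material {material.name!r}"
        )

    # fixed point on the entry depth of the ray through the end face
    z_enter = z_bottom - d_p
    for _ in range(_MAX_ITER):
        t = math.atan2(x_leaf, z_enter)
        z_next = z_bottom - d_p * math.cos(t)
        if abs(z_next - z_enter) < _FIXED_POINT_TOL_CM:
            z_enter = z_next
            break
        z_enter = z_next
    t = math.atan2(x_leaf, z_enter)
    residual = chord_length(t, x_leaf, z_bottom, material.thickness_cm) - d_p
    if abs(residual) > _RESIDUAL_TOL_CM:  # pragma: no cover - contraction always converges
        raise CimlcError(f"chord solve did not converge (residual {residual:.3g} cm)")
    return sign * geom.sad_cm * math.tan(t)


def offset(setting: LeafSetting, material: Material, geom: BeamlineGeometry) -> float:
    """Planning offset (mm): 50%-dose position minus the planned leaf position."""
    if setting.half_field_cm == 0.0:
        return 0.0
    return (solve_x_p(setting, material, geom, 0.5) - x_mlc(setting, material, geom)) * 10.0


def light_radiation_agreement(
    setting: LeafSetting, material: Material, geom: BeamlineGeometry
) -> float:
    """Light/radiation mismatch (mm): light-field edge minus the 50%-dose position."""
    if setting.half_field_cm == 0.0:
        return 0.0
    return (x_tang(setting, geom) - solve_x_p(setting, material, geom, 0.5)) * 10.0


def model_penumbra(setting: LeafSetting, material: Material, geom: BeamlineGeometry) -> float:
    """Attenuation-model 20-80% penumbra (mm).

    Width between the 20% and 80% dose points of the pure chord-attenuation
    edge.  This is narrower than a measured penumbra, which also carries the
    effective source size and in-leaf scatter; it is reported as a model
    quantity only.
    """
    if setting.half_field_cm == 0.0:
        return 0.0
    x20 = solve_x_p(setting, material, geom, 0.2)
    x80 = solve_x_p(setting, material, geom, 0.8)
    return abs(x20 - x80) * 10.0


def solve_edge(
    setting: LeafSetting, material: Material, geom: BeamlineGeometry
) -> EdgeSolution:
    """Aggregate every edge quantity for one (setting, material) case."""
    theta, theta_prime, theta_dprime = divergence_angles(setting, material, geom)
    xt = x_tang(setting, geom)
    xm = x_mlc(setting, material, geom)
    if setting.half_field_cm == 0.0:
        x50 = 0.0
        alpha = 0.0
        pen = 0.0
    else:
        x50 = solve_x_p(setting, material, geom, 0.5)
        alpha = math.atan2(x50, geom.sad_cm)
        pen = model_penumbra(setting, material, geom)
    return EdgeSolution(
        material=material.name,
        half_field_cm=setting.half_field_cm,
        theta=theta,
        theta_prime=theta_prime,
        theta_dprime=theta_dprime,
        alpha=alpha,
        x_tang_cm=xt,
        x_mlc_cm=xm,
        x50_cm=x50,
        offset_mm=(x50 - xm) * 10.0,
        light_rad_agreement_mm=(xt - x50) * 10.0,
        model_penumbra_mm=pen,
    )
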
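"""Beamline divergence geometry: source, MLC leaf, isocenter axis.

Coordinates: the effective source sits at the origin of the beam axis and
distances increase toward the isocenter, which lies at ``sad_cm``
(source-to-axis distance).  The leaf is a rectangular slab occupying the
axial interval ``[z_bottom - thickness, z_bottom]`` with a vertical
(beam-parallel) end face at the lateral position of the leaf edge; it blocks
the region beyond that face on the signed side the leaf sits on.

Three diverging rays through the leaf-end corners and midpoint define the
projection quantities:

* ``theta``        — ray through the leaf-bottom inner corner; its axis
  intersection is the light-field edge ``x_tang`` (equal to the nominal
  half-field by construction).
* ``theta_prime``  — ray through the leaf-end midpoint; its intersection is
  the planning-system leaf position ``x_mlc``.
* ``theta_dprime`` — ray through the leaf-top inner corner.

The 50%-dose ray ``alpha`` always lies between ``theta`` and
``theta_dprime`` and is solved in :mod:`cimlc.edge_solver`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .errors import GeometryError
from .materials import Material

__all__ = [
    "BeamlineGeometry",
    "LeafSetting",
    "EdgeSolution",
    "leaf_lateral_position",
    "x_tang",
    "x_mlc",
    "divergence_angles",
]

#: Half-field magnitude (cm) above which a setting is rejected outright.
HARD_CAP_HALF_FIELD_CM = 10.0


@dataclass(frozen=True)
class BeamlineGeometry:
    """Projection geometry constants.

    Defaults reproduce a passive-scattering carbon-ion beamline with a
    263.3 cm SAD whose effective (virtual) source, measured by field-size
    magnification, sits 257.8 cm from the isocenter with 191.3 cm to the MLC
    bottom; projecting from the nominal SAD plane therefore puts the leaf
    bottom 196.8 cm = 263.3 - (257.8 - 191.3) from the source.
    """

    sad_cm: float = 263.3
    source_to_leaf_bottom_cm: float = 196.8
    max_half_field_cm: float = 6.0

    def __post_init__(self) -> None:
        if not (0.0 < self.source_to_leaf_bottom_cm < self.sad_cm):
            raise GeometryError(
                f"need 0 < source_to_leaf_bottom ({self.source_to_leaf_bottom_cm}) "
                f"< sad ({self.sad_cm})"
            )
        if self.max_half_field_cm <= 0:
            raise GeometryError("max_half_field_cm must be positive")

    def leaf_planes(self, material: Material) -> tuple[float, float, float]:
        """Axial distances (cm) of leaf bottom, midpoint and top from the source."""
        z_bottom = self.source_to_leaf_bottom_cm
        z_top = z_bottom - material.thickness_cm
        if z_top <= 0:
            raise GeometryError(
                f"leaf of thickness {material.thickness_cm} cm extends behind the "
                f"source (leaf bottom at {z_bottom} cm)"
            )
        return z_bottom, z_bottom - material.thickness_cm / 2.0, z_top


@dataclass(frozen=True)
class LeafSetting:
    """A nominal half-field setting.

    ``half_field_cm`` is the nominal light-field half-width at the isocenter;
    ``direction_sign`` is +1 when the leaf travels away from the central axis
    (opening) and -1 when it travels toward or across it.
    """

    half_field_cm: float
    direction_sign: int = 1

    def __post_init__(self) -> None:
        if self.direction_sign not in (1, -1):
            raise GeometryError("direction_sign must be +1 or -1")
        if abs(self.half_field_cm) > HARD_CAP_HALF_FIELD_CM:
            raise GeometryError(
                f"half_field {self.half_field_cm} cm exceeds the hard cap "
                f"{HARD_CAP_HALF_FIELD_CM} cm"
            )

    def check_against(self, geom: BeamlineGeometry) -> None:
        if abs(self.half_field_cm) > geom.max_half_field_cm:
            warnings.warn(
                f"half_field {self.half_field_cm} cm exceeds the maximum physical "
                f"half-field {geom.max_half_field_cm} cm; extrapolating the geometry",
                stacklevel=3,
            )

    @property
    def signed_half_field_cm(self) -> float:
        return self.direction_sign * self.half_field_cm


@dataclass(frozen=True)
class EdgeSolution:
    """All per-(material, half-field) edge quantities.

    Angles in radians, projections in cm on the isocenter axis, offsets in mm.
    ``offset_mm = (x50 - x_mlc) * 10`` is the planning correction;
    ``light_rad_agreement_mm = (x_tang - x50) * 10`` is the light/radiation
    field mismatch.
    """

    material: str
    half_field_cm: float
    theta: float
    theta_prime: float
    theta_dprime: float
    alpha: float
    x_tang_cm: float
    x_mlc_cm: float
    x50_cm: float
    offset_mm: float
    light_rad_agreement_mm: float
    model_penumbra_mm: float

    @property
    def theta_deg(self) -> float:
        return math.degrees(self.theta)


def leaf_lateral_position(setting: LeafSetting, geom: BeamlineGeometry) -> float:
    """Signed lateral position (cm) of the leaf-end face at the leaf plane.

    The leaf-bottom inner corner sits on the ray that projects exactly to the
    nominal half-field on the isocenter axis, hence
    ``x_leaf = half_field * z_bottom / sad``.
    """
    setting.check_against(geom)
    return setting.signed_half_field_cm * geom.source_to_leaf_bottom_cm / geom.sad_cm


def x_tang(setting: LeafSetting, geom: BeamlineGeometry) -> float:
    """Light-field edge projection (cm); equals the signed half-field exactly."""
    setting.check_against(geom)
    return setting.signed_half_field_cm


def x_mlc(setting: LeafSetting, material: Material, geom: BeamlineGeometry) -> float:
    """Planning-system leaf position (cm): leaf-end midpoint projected to the axis."""
    z_bottom, z_mid, _ = geom.leaf_planes(material)
    if z_mid <= 0:
        raise GeometryError("leaf-end midpoint at or behind the source")
    return leaf_lateral_position(setting, geom) * geom.sad_cm / z_mid


def divergence_angles(
    setting: LeafSetting, material: Material, geom: BeamlineGeometry
) -> tuple[float, float, float]:
    """Signed divergence angles (rad) to the leaf-bottom corner, end midpoint
    and top corner: ``atan(x_leaf / z)`` at the three leaf planes.

    ``theta`` equivalently equals ``atan(half_field / sad)``.
    """
    z_bottom, z_mid, z_top = geom.leaf_planes(material)
    xl = leaf_lateral_position(setting, geom)
    return (
        math.atan2(xl, z_bottom),
        math.atan2(xl, z_mid),
        math.atan2(xl, z_top),
    )
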
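"""Virtual-source localisation by field-size magnification.

A scattered particle beam appears to diverge from a point (the virtual
source) that generally differs from the nominal SAD origin.  Measuring the
field size at the isocenter plane and at a plane displaced by a signed gap
``g`` (+ downstream of the isocenter, - upstream) gives the source distance

    f = g / (FS_gap / FS_iso - 1)

exact for a point source at any gap.  The derived effective geometry keeps
the physical leaf-bottom-to-isocenter distance fixed while re-expressing the
projection from the nominal SAD plane.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean
from typing import NamedTuple, Sequence

from .errors import GeometryError, ValidationError
from .geometry import BeamlineGeometry

__all__ = [
    "VirtualSourceMeasurement",
    "CombinedEstimate",
    "estimate_virtual_source",
    "combine_gap_estimates",
    "derive_projection_geometry",
]


@dataclass(frozen=True)
class VirtualSourceMeasurement:
    """One magnification measurement: field sizes at the isocenter and at a
    plane displaced by ``gap_cm`` (signed, + away from the source)."""

    fs_at_iso_cm: float
    fs_at_gap_cm: float
    gap_cm: float
    nominal_sad_cm: float = 263.3

    def __post_init__(self) -> None:
        if self.fs_at_iso_cm <= 0 or self.fs_at_gap_cm <= 0:
            raise ValidationError("field sizes must be positive")
        if self.gap_cm == 0:
            raise ValidationError("gap must be non-zero")
        if self.gap_cm > 0 and self.fs_at_gap_cm <= self.fs_at_iso_cm:
            raise ValidationError(
                "downstream gap must magnify the field of a diverging beam "
                f"(fs_at_gap {self.fs_at_gap_cm} <= fs_at_iso {self.fs_at_iso_cm})"
            )


class CombinedEstimate(NamedTuple):
    mean_cm: float
    spread_cm: float


def estimate_virtual_source(m: VirtualSourceMeasurement) -> float:
    """Virtual source-to-isocenter distance ``f`` (cm) from one measurement."""
    ratio = m.fs_at_gap_cm / m.fs_at_iso_cm
    if ratio == 1.0:
        raise ValidationError("no divergence detected: field sizes are equal")
    return m.gap_cm / (ratio - 1.0)


def combine_gap_estimates(estimates: Sequence[float]) -> CombinedEstimate:
    """Unweighted mean of per-gap estimates, with the max-min spread."""
    values = list(estimates)
    if not values:
        raise ValidationError("no virtual-source estimates to combine")
    return CombinedEstimate(fmean(values), max(values) - min(values))


def derive_projection_geometry(
    f_cm: float, f_to_leaf_bottom_cm: float, nominal_sad_cm: float = 263.3
) -> BeamlineGeometry:
    """Effective projection geometry from the measured virtual source.

    The physical leaf-bottom-to-isocenter distance ``f - f_to_leaf_bottom``
    is preserved; re-anchoring the projection at the nominal SAD puts the
    leaf bottom at ``nominal_sad - (f - f_to_leaf_bottom)`` from the source.
    """
    if not (0.0 < f_to_leaf_bottom_cm < f_cm <= nominal_sad_cm):
        raise GeometryError(
            f"need 0 < f_to_leaf_bottom ({f_to_leaf_bottom_cm}) < f ({f_cm}) "
            f"<= nominal_sad ({nominal_sad_cm})"
        )
    return BeamlineGeometry(
        sad_cm=nominal_sad_cm,
        source_to_leaf_bottom_cm=nominal_sad_cm - (f_cm - f_to_leaf_bottom_cm),
    )
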
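"""MLC leaf materials and the exponential survival (attenuation) model.

A heavy charged-particle beam traversing a path ``x`` of leaf material keeps a
fraction ``exp(-x / lambda)`` of its nuclei, where ``lambda`` is the
interaction mean free path (in this context often called the straggling
range).  The half-value path ``d50 = lambda * ln 2`` is the material path that
reduces the beam to 50% and is what places the radiation field edge.

The shipped table covers nine candidate leaf materials (tungsten, three W/Cu
alloys and brass, iron, nickel, copper, stainless steel, aluminium).  For pure
tungsten the attenuation length is 2.7 cm; for the other materials no
published value exists and the straggling range stands in for it.  Both can be
overridden by a user-supplied table with an explicit ``lambda_cm`` column.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .errors import ValidationError

__all__ = [
    "Material",
    "survival_fraction",
    "path_for_survival",
    "load_material_table",
    "get_material",
    "TUNGSTEN_LAMBDA_CM",
]

#: Attenuation length of 400 MeV/n carbon ions in pure tungsten, cm.
TUNGSTEN_LAMBDA_CM = 2.7

_COMPOSITION_SUM_TOL = 0.5


def _parse_composition(text: str) -> tuple[tuple[str, float], ...]:
    """Parse a compact composition string like ``"W:90 Cu:10"``."""
    pairs: list[tuple[str, float]] = []
    for token in text.replace(",", " ").split():
        if ":" not in token:
            raise ValidationError(f"malformed composition token {token!r}")
        elem, _, pct = token.partition(":")
        try:
            pairs.append((elem, float(pct)))
        except ValueError as exc:
            raise ValidationError(f"malformed composition token {token!r}") from exc
    return tuple(pairs)


@dataclass(frozen=True)
class Material:
    """One MLC leaf material.

    Parameters
    ----------
    name : str
        Short identifier, e.g. ``"W100"`` or ``"W90Cu10"``.
    composition : tuple of (element, weight-percent)
        Weight percentages; must sum to 100 within 0.5.
    density_g_cm3 : float
        Bulk density in g/cm^3.
    thickness_cm : float
        Leaf thickness along the beam direction, cm.
    lambda_cm : float
        Attenuation length (interaction mean free path), cm.
    straggling_range_cm : float
        Tabulated straggling range, cm (kept verbatim; equals ``lambda_cm``
        for every shipped material except tungsten).
    secondary_dose_1e4_sv : float, optional
        Reference metadata: Monte-Carlo secondary-radiation equivalent dose
        in units of 1e-4 Sv.  Never computed by this package.
    """

    name: str
    composition: tuple[tuple[str, float], ...]
    density_g_cm3: float
    thickness_cm: float
    lambda_cm: float
    straggling_range_cm: float
    secondary_dose_1e4_sv: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for fname in ("density_g_cm3", "thickness_cm", "lambda_cm", "straggling_range_cm"):
            value = getattr(self, fname)
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise ValidationError(f"material {self.name!r}: {fname} must be positive, got {value!r}")
        if self.composition:
            total = sum(pct for _, pct in self.composition)
            if abs(total - 100.0) > _COMPOSITION_SUM_TOL:
                raise ValidationError(
                    f"material {self.name!r}: composition weight-percents sum to {total}, expected 100"
                )
        # d50 < thickness/2 keeps the 50% ray inside the leaf-end face for
        # every divergent field; all shipped materials satisfy it.
        if self.thickness_cm <= 2.0 * math.log(2.0) * self.lambda_cm:
            warnings.warn(
                f"material {self.name!r}: thickness {self.thickness_cm} cm does not exceed "
                f"2*ln2*lambda = {2 * math.log(2.0) * self.lambda_cm:.4g} cm; the half-value "
                "path reaches past the leaf-end midpoint",
                stacklevel=2,
            )

    @property
    def d50_cm(self) -> float:
        """Half-value path ``lambda * ln 2`` in cm."""
        return self.lambda_cm * math.log(2.0)


def survival_fraction(path_length_cm, material: Material):
    """Surviving beam fraction after a material path, ``exp(-x/lambda)``.

    Accepts scalar or array path lengths (cm); returns the same shape.
    Raises on negative path lengths.
    """
    x = np.asarray(path_length_cm, dtype=float)
    if np.any(x < 0):
        raise ValidationError("path_length must be non-negative")
    out = np.exp(-x / material.lambda_cm)
    return float(out) if np.isscalar(path_length_cm) or x.ndim == 0 else out


def path_for_survival(p: float, material: Material) -> float:
    """Material path (cm) reducing survival to fraction ``p``: ``-lambda*ln p``."""
    if not (0.0 < p < 1.0):
        raise ValidationError(f"survival fraction must lie in (0, 1), got {p}")
    return -material.lambda_cm * math.log(p)


_REQUIRED = ("name", "composition", "density_g_cm3", "thickness_cm", "straggling_range_cm")


def _material_from_record(rec: Mapping[str, object]) -> Material:
    name = rec.get("name")
    for key in _REQUIRED:
        if key not in rec or rec[key] in (None, ""):
            raise ValidationError(f"material {name!r}: missing field {key!r}")
    lam = rec.get("lambda_cm")
    if lam in (None, ""):
        lam = float(rec["straggling_range_cm"])  # type: ignore[arg-type]
    sec = rec.get("secondary_dose_1e4_sv")
    return Material(
        name=str(name),
        composition=_parse_composition(str(rec["composition"])),
        density_g_cm3=float(rec["density_g_cm3"]),  # type: ignore[arg-type]
        thickness_cm=float(rec["thickness_cm"]),  # type: ignore[arg-type]
        lambda_cm=float(lam),  # type: ignore[arg-type]
        straggling_range_cm=float(rec["straggling_range_cm"]),  # type: ignore[arg-type]
        secondary_dose_1e4_sv=None if sec in (None, "") else float(sec),  # type: ignore[arg-type]
    )


def load_material_table(source: str | Path | Iterable[Mapping[str, object]] | None = None) -> list[Material]:
    """Load a material table.

    ``source`` may be ``None`` (the packaged nine-material default), a path to
    a YAML or CSV file with columns ``name, composition, density_g_cm3,
    thickness_cm, straggling_range_cm, lambda_cm`` (the last optional), or an
    iterable of already-parsed records.
    """
    if source is None:
        text = resources.files("cimlc").joinpath("data/materials.yaml").read_text()
        records = yaml.safe_load(text)["materials"]
    elif isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            raise ValidationError(f"material table not found: {path}")
        if path.suffix.lower() in (".yaml", ".yml"):
            doc = yaml.safe_load(path.read_text())
            records = doc.get("materials", doc) if isinstance(doc, dict) else doc
        else:
            with open(path, newline="") as fh:
                records = list(csv.DictReader(fh))
    else:
        records = list(source)
    if not records:
        raise ValidationError("material table is empty")
    return [_material_from_record(rec) for rec in records]


def get_material(name: str, table: Sequence[Material] | None = None) -> Material:
    """Look up a material by name (case-insensitive) in a table."""
    materials = list(table) if table is not None else load_material_table()
    for m in materials:
        if m.name.lower() == name.lower():
            return m
    known = ", ".join(m.name for m in materials)
    raise ValidationError(f"unknown material {name!r}; known materials: {known}")
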
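"""Dose-profile synthesis and edge-metric extraction.

Ray tracing a leaf edge gives the brute-force counterpart of the analytic
chord solve: each axis position corresponds to one diverging ray whose leaf
chord sets the transmitted dose ``exp(-chord/lambda)``.  Traced profiles
serve both as an independent numerical oracle for the edge solver and as
seeded CSV fixtures for testing edge extraction under noise.

Also here: the minimal film dose-calibration fit (graded doses against net
optical density, the H-D curve), as a strictly monotone piecewise-linear
response-to-dose map.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .edge_solver import chord_length, model_penumbra, solve_x_p
from .errors import CalibrationRangeError, EdgeNotFoundError, ValidationError
from .geometry import BeamlineGeometry, LeafSetting, leaf_lateral_position
from .materials import Material, load_material_table

__all__ = [
    "DoseProfile",
    "CalibrationCurve",
    "EdgeMetrics",
    "trace_profile",
    "extract_edge_metrics",
    "fit_calibration",
    "apply_calibration",
    "generate_fixture_profiles",
    "read_profile_csv",
    "write_profile_csv",
]

_MIN_SAMPLES = 8


@dataclass(frozen=True)
class DoseProfile:
    """A sampled 1-D on-axis dose profile.

    ``central_axis_dose`` is the reference the 50/20/80% levels refer to; if
    not supplied it is interpolated at position 0 (which must then lie inside
    the sampled range).
    """

    positions_cm: np.ndarray
    doses: np.ndarray
    central_axis_dose: float | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_cm, dtype=float)
        dose = np.asarray(self.doses, dtype=float)
        object.__setattr__(self, "positions_cm", pos)
        object.__setattr__(self, "doses", dose)
        if pos.ndim != 1 or pos.size < _MIN_SAMPLES:
            raise ValidationError(f"profile needs >= {_MIN_SAMPLES} samples, got {pos.size}")
        if dose.shape != pos.shape:
            raise ValidationError("positions and doses must have equal length")
        if not np.all(np.diff(pos) > 0):
            raise ValidationError("positions must be strictly increasing")
        if np.any(dose < 0):
            raise ValidationError("doses must be non-negative")
        if self.central_axis_dose is None:
            if not (pos[0] <= 0.0 <= pos[-1]):
                raise ValidationError(
                    "central_axis_dose not given and position 0 outside the profile"
                )
            object.__setattr__(
                self, "central_axis_dose", float(np.interp(0.0, pos, dose))
            )
        if self.central_axis_dose <= 0:
            raise ValidationError("central_axis_dose must be positive")


class EdgeMetrics(NamedTuple):
    x50_cm: float
    x20_cm: float
    x80_cm: float
    penumbra_mm: float


def trace_profile(
    setting: LeafSetting,
    material: Material,
    geom: BeamlineGeometry,
    positions_cm: Sequence[float] | np.ndarray,
) -> DoseProfile:
    """Ray-trace the relative dose at each axis position past one leaf edge.

    Each position ``x`` defines the ray from the effective source through
    ``(x, sad)``; the dose is ``exp(-chord/lambda)`` for that ray's material
    chord (1 in the open field, the full slant-thickness transmission deep
    under the leaf).  The open field is normalised to 1.
    """
    pos = np.asarray(positions_cm, dtype=float)
    xl_signed = leaf_lateral_position(setting, geom)
    sign = math.copysign(1.0, xl_signed) if xl_signed != 0.0 else 1.0
    x_leaf = abs(xl_signed)
    z_bottom = geom.source_to_leaf_bottom_cm
    doses = np.empty_like(pos)
    for i, x in enumerate(pos):
        # mirror so the leaf always sits on the positive side
        t = math.atan2(sign * x, geom.sad_cm)
        chord = chord_length(t, x_leaf, z_bottom, material.thickness_cm) if t > 0 else 0.0
        doses[i] = math.exp(-chord / material.lambda_cm)
    return DoseProfile(pos, doses, central_axis_dose=1.0)


def _crossings(pos: np.ndarray, rel: np.ndarray, level: float) -> list[float]:
    """Linearly interpolated positions where ``rel`` crosses ``level``."""
    out: list[float] = []
    d = rel - level
    for i in range(d.size - 1):
        a, b = d[i], d[i + 1]
        if a == 0.0:
            out.append(float(pos[i]))
        elif (a > 0 > b) or (a < 0 < b):
            out.append(float(pos[i] + (pos[i + 1] - pos[i]) * a / (a - b)))
    if d[-1] == 0.0:
        out.append(float(pos[-1]))
    return out


def extract_edge_metrics(profile: DoseProfile) -> EdgeMetrics:
    """Locate the 50/20/80% crossings of a profile edge by linear interpolation.

    Levels are fractions of the central-axis dose.  With multiple crossings
    of a level (noise, or a second edge) the outermost one is used and a
    warning is emitted.
    """
    rel = profile.doses / profile.central_axis_dose
    found: dict[float, float] = {}
    for level in (0.5, 0.2, 0.8):
        xs = _crossings(profile.positions_cm, rel, level)
        if not xs:
            raise EdgeNotFoundError(f"profile never crosses {level:.0%} of the central-axis dose")
        if len(xs) > 1:
            warnings.warn(
                f"{len(xs)} crossings of the {level:.0%} level; using the outermost",
                stacklevel=2,
            )
        found[level] = max(xs, key=abs)
    return EdgeMetrics(
        x50_cm=found[0.5],
        x20_cm=found[0.2],
        x80_cm=found[0.8],
        penumbra_mm=abs(found[0.2] - found[0.8]) * 10.0,
    )


@dataclass(frozen=True)
class CalibrationCurve:
    """Strictly monotone film calibration: net optical density -> dose (cGy).

    Shape-preserving monotone cubic (PCHIP) between knots, exact at the
    knots, refuses to extrapolate.  On locally linear data the interpolant is
    exactly linear, so a knot collinear with its neighbours is redundant.
    """

    doses_cGy: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.doses_cGy, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "doses_cGy", d)
        object.__setattr__(self, "responses", r)
        if d.size < 3 or d.shape != r.shape:
            raise ValidationError("calibration needs >= 3 (dose, response) pairs")
        if not (np.all(np.diff(d) > 0) and np.all(np.diff(r) > 0)):
            raise ValidationError("calibration doses and responses must be strictly increasing")
        object.__setattr__(self, "_interp", PchipInterpolator(r, d, extrapolate=False))

    def dose_at(self, response):
        resp = np.asarray(response, dtype=float)
        if np.any(resp < self.responses[0]) or np.any(resp > self.responses[-1]):
            raise CalibrationRangeError(
                f"response outside calibrated range "
                f"[{self.responses[0]}, {self.responses[-1]}]"
            )
        out = self._interp(resp)
        return float(out) if resp.ndim == 0 else out


def fit_calibration(doses_cGy: Sequence[float], responses: Sequence[float]) -> CalibrationCurve:
    """Fit the monotone dose-response (H-D) calibration curve."""
    return CalibrationCurve(np.asarray(doses_cGy), np.asarray(responses))


def apply_calibration(curve: CalibrationCurve, response):
    """Convert a net-OD response (scalar or array) to dose in cGy."""
    return curve.dose_at(response)


# --- fixture generation -----------------------------------------------------

_FIXTURE_GRID_CM = 0.001
_FIXTURE_MARGIN_CM = 0.3


def _fixture_window(setting: LeafSetting, material: Material, geom: BeamlineGeometry):
    """Sampling window covering the open field through the full-shadow plateau."""
    h = abs(setting.half_field_cm)
    x_leaf = h * geom.source_to_leaf_bottom_cm / geom.sad_cm
    z_top = geom.source_to_leaf_bottom_cm - material.thickness_cm
    x_dprime = geom.sad_cm * x_leaf / z_top
    return h - _FIXTURE_MARGIN_CM, x_dprime + _FIXTURE_MARGIN_CM


def generate_fixture_profiles(
    seed: int,
    n_cases: int,
    out_dir: str | Path,
    noise_sigma: float = 0.0,
    materials: Sequence[Material] | None = None,
    geom: BeamlineGeometry | None = None,
) -> dict:
    """Write ``n_cases`` seeded leaf-edge profile CSVs plus a truth manifest.

    Cases sample the material table crossed with half-fields uniform in
    [1, 6] cm; optional additive Gaussian noise of ``noise_sigma`` on the
    relative dose.  Deterministic per seed (byte-identical re-runs).
    Returns the manifest dict (also written as ``manifest.json``).
    """
    geom = geom or BeamlineGeometry()
    materials = list(materials) if materials is not None else load_material_table()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_cases):
        material = materials[int(rng.integers(len(materials)))]
        half_field = float(np.round(rng.uniform(1.0, 6.0), 3))
        setting = LeafSetting(half_field)
        lo, hi = _fixture_window(setting, material, geom)
        positions = np.arange(lo, hi, _FIXTURE_GRID_CM)
        profile = trace_profile(setting, material, geom, positions)
        doses = profile.doses
        if noise_sigma > 0.0:
            doses = np.clip(doses + rng.normal(0.0, noise_sigma, doses.size), 0.0, None)
        fname = f"case_{i:03d}.csv"
        write_profile_csv(out / fname, DoseProfile(positions, doses, central_axis_dose=1.0))
        cases.append(
            {
                "file": fname,
                "material": material.name,
                "half_field_cm": half_field,
                "true_x50_cm": solve_x_p(setting, material, geom, 0.5),
                "true_x20_cm": solve_x_p(setting, material, geom, 0.2),
                "true_x80_cm": solve_x_p(setting, material, geom, 0.8),
                "true_penumbra_mm": model_penumbra(setting, material, geom),
            }
        )
    manifest = {
        "seed": seed,
        "n_cases": n_cases,
        "noise_sigma": noise_sigma,
        "grid_cm": _FIXTURE_GRID_CM,
        "geometry": {
            "sad_cm": geom.sad_cm,
            "source_to_leaf_bottom_cm": geom.source_to_leaf_bottom_cm,
        },
        "cases": cases,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest


def write_profile_csv(path: str | Path, profile: DoseProfile) -> None:
    """Write a two-column ``position_cm,dose_rel`` CSV."""
    lines = ["position_cm,dose_rel"]
    for x, d in zip(profile.positions_cm, profile.doses):
        lines.append(f"{x:.6f},{d:.9g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_profile_csv(path: str | Path, central_axis_dose: float | None = 1.0) -> DoseProfile:
    """Read a ``position_cm,dose_rel`` CSV written by :func:`write_profile_csv`."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"profile file not found: {path}")
    raw = np.genfromtxt(path, delimiter=",", names=True)
    if raw.dtype.names is None or set(raw.dtype.names) != {"position_cm", "dose_rel"}:
        raise ValidationError(f"{path}: expected header 'position_cm,dose_rel'")
    return DoseProfile(raw["position_cm"], raw["dose_rel"], central_axis_dose=central_axis_dose)
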
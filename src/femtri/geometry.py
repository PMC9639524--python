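"""Triangle-based feature derivation from the three femoral inter-landmark distances.

The proximal femur carries three landmarks — the most lateral point on the
articular rim of the head (A), the most medially projecting point on the
greater trochanter (B), and the highest medially projecting point on the
lesser trochanter (C).  The three inter-landmark distances AB, BC and AC
(mm) define a triangle whose size and shape differ between the sexes and
between geographic populations.  From the three raw distances this module
derives twelve variables:

* the three interior angles (Law of Cosines; A opposite BC, B opposite AC,
  C opposite AB), in degrees by default;
* three angle-to-length ratios x100 (angle A / AB, angle B / BC,
  angle C / AC — the pairing is by vertex label, not by opposite side);
* the three medians from each vertex to the midpoint of the opposite side
  (Apollonius' theorem);
* three dimensionless Darroch–Mosimann shape variables, each raw distance
  divided by the per-case geometric mean of the three.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TriangleError",
    "TriangleMeasurements",
    "DerivedFeatures",
    "FEATURE_SETS",
    "compute_angles",
    "compute_ratios",
    "compute_medians",
    "compute_shape_variables",
    "derive_features",
    "derive_feature_table",
]

#: absolute slack allowed on the arccos argument before it is treated as an error
_ACOS_SLACK = 1e-12

# Ordered feature-set schemas.  "pooled" is the 12-variable set: the three raw
# distances plus angles, ratios and medians; the shape variables are size-free
# and are kept as their own set rather than pooled.
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "linear": ("ab_mm", "bc_mm", "ac_mm"),
    "angles": ("angle_a_deg", "angle_b_deg", "angle_c_deg"),
    "ratios": ("ratio_a", "ratio_b", "ratio_c"),
    "medians": ("median_a_mm", "median_b_mm", "median_c_mm"),
    "shape": ("shape_ab", "shape_bc", "shape_ac"),
    "pooled": (
        "ab_mm", "bc_mm", "ac_mm",
        "angle_a_deg", "angle_b_deg", "angle_c_deg",
        "ratio_a", "ratio_b", "ratio_c",
        "median_a_mm", "median_b_mm", "median_c_mm",
    ),
}


class TriangleError(ValueError):
    """Raised when three lengths cannot form a valid (non-degenerate) triangle."""


@dataclass(frozen=True)
class TriangleMeasurements:
    """One individual's three raw inter-landmark distances, in millimetres.

    ``ab_mm``: head articular rim to greater trochanter;
    ``bc_mm``: greater to lesser trochanter (inter-trochanteric);
    ``ac_mm``: head to lesser trochanter.

    Validation is eager: non-positive lengths and strict triangle-inequality
    violations raise :class:`TriangleError` naming the offending side.
    Violating rows are measurement blunders and are rejected, never repaired.
    """

    ab_mm: float
    bc_mm: float
    ac_mm: float

    def __post_init__(self) -> None:
        sides = {"ab_mm": self.ab_mm, "bc_mm": self.bc_mm, "ac_mm": self.ac_mm}
        for name, value in sides.items():
            if not (value > 0) or not math.isfinite(value):
                raise TriangleError(f"side {name} must be a positive finite length, got {value!r}")
        for name, value in sides.items():
            others = sum(v for k, v in sides.items() if k != name)
            if not (value < others):
                raise TriangleError(
                    f"triangle inequality violated: side {name}={value} is not "
                    f"strictly less than the sum of the other two ({others})"
                )

    @property
    def sides(self) -> tuple[float, float, float]:
        return (self.ab_mm, self.bc_mm, self.ac_mm)


@dataclass(frozen=True)
class DerivedFeatures:
    """The twelve derived variables plus the per-case geometric mean."""

    angle_a_deg: float
    angle_b_deg: float
    angle_c_deg: float
    ratio_a: float
    ratio_b: float
    ratio_c: float
    median_a_mm: float
    median_b_mm: float
    median_c_mm: float
    shape_ab: float
    shape_bc: float
    shape_ac: float
    gm_mm: float


def _safe_arccos(arg: float, context: str) -> float:
    if abs(arg) > 1.0 + _ACOS_SLACK:
        raise TriangleError(f"arccos argument {arg} out of range while computing {context}")
    return math.acos(min(1.0, max(-1.0, arg)))


def compute_angles(tri: TriangleMeasurements, degrees: bool = True) -> tuple[float, float, float]:
    """Interior angles at vertices A, B, C via the Law of Cosines.

    Angle A is opposite side BC, angle B opposite AC, angle C opposite AB.
    Returned in degrees unless ``degrees=False`` (radians).
    """
    ab, bc, ac = tri.sides
    ang_a = _safe_arccos((ab**2 + ac**2 - bc**2) / (2 * ab * ac), "angle A")
    ang_b = _safe_arccos((ab**2 + bc**2 - ac**2) / (2 * ab * bc), "angle B")
    ang_c = _safe_arccos((ac**2 + bc**2 - ab**2) / (2 * ac * bc), "angle C")
    if degrees:
        return (math.degrees(ang_a), math.degrees(ang_b), math.degrees(ang_c))
    return (ang_a, ang_b, ang_c)


def compute_ratios(
    tri: TriangleMeasurements, angles: tuple[float, float, float]
) -> tuple[float, float, float]:
    """Angle-to-length ratios x100: angle A/AB, angle B/BC, angle C/AC.

    The pairing is by vertex label (angle A with the side AB that meets at A),
    deliberately not the opposite-side pairing.  A larger femur can have the
    same angles as a smaller one, so angles relative to the lengths carry
    size-adjusted signal.
    """
    ang_a, ang_b, ang_c = angles
    return (
        100.0 * ang_a / tri.ab_mm,
        100.0 * ang_b / tri.bc_mm,
        100.0 * ang_c / tri.ac_mm,
    )


def compute_medians(tri: TriangleMeasurements) -> tuple[float, float, float]:
    """Medians from each vertex to the opposite side's midpoint (Apollonius).

    m_a = 1/2 * sqrt(2 AB^2 + 2 AC^2 - BC^2), and cyclically for B and C.
    The radicand is strictly positive for every valid triangle; a negative
    value indicates an internal error, not bad input.
    """
    ab, bc, ac = tri.sides
    radicands = {
        "median from A": 2 * ab**2 + 2 * ac**2 - bc**2,
        "median from B": 2 * ab**2 + 2 * bc**2 - ac**2,
        "median from C": 2 * ac**2 + 2 * bc**2 - ab**2,
    }
    for name, r in radicands.items():
        if r <= 0:
            raise RuntimeError(f"internal error: non-positive radicand for {name} on valid triangle")
    vals = [0.5 * math.sqrt(r) for r in radicands.values()]
    return (vals[0], vals[1], vals[2])


def compute_shape_variables(
    tri: TriangleMeasurements,
) -> tuple[float, float, float, float]:
    """Darroch–Mosimann shape variables and the geometric mean.

    gm = (AB*BC*AC)^(1/3); each side divided by gm.  The three shapes are
    scale-free and multiply to 1, so pooling sexes for ancestry work is safe.
    Returns (shape_ab, shape_bc, shape_ac, gm_mm).
    """
    ab, bc, ac = tri.sides
    gm = (ab * bc * ac) ** (1.0 / 3.0)
    return (ab / gm, bc / gm, ac / gm, gm)


def derive_features(tri: TriangleMeasurements, degrees: bool = True) -> DerivedFeatures:
    """All twelve derived variables for one individual."""
    angles = compute_angles(tri, degrees=degrees)
    ratios = compute_ratios(tri, angles)
    medians = compute_medians(tri)
    sh_ab, sh_bc, sh_ac, gm = compute_shape_variables(tri)
    return DerivedFeatures(
        angle_a_deg=angles[0], angle_b_deg=angles[1], angle_c_deg=angles[2],
        ratio_a=ratios[0], ratio_b=ratios[1], ratio_c=ratios[2],
        median_a_mm=medians[0], median_b_mm=medians[1], median_c_mm=medians[2],
        shape_ab=sh_ab, shape_bc=sh_bc, shape_ac=sh_ac, gm_mm=gm,
    )


def derive_feature_table(
    rows: "list[TriangleMeasurements] | pd.DataFrame",
    set_name: str = "pooled",
    degrees: bool = True,
) -> pd.DataFrame:
    """Feature matrix for a feature set, one output row per input row.

    ``rows`` may be a list of :class:`TriangleMeasurements` or any DataFrame
    carrying ``ab_mm, bc_mm, ac_mm`` columns.  Column order follows
    :data:`FEATURE_SETS` and is part of the contract.  An invalid row aborts
    the derivation with the offending row index; rows are never silently
    dropped.
    """
    if set_name not in FEATURE_SETS:
        raise KeyError(f"unknown feature set {set_name!r}; expected one of {sorted(FEATURE_SETS)}")
    if isinstance(rows, pd.DataFrame):
        triples = list(zip(rows["ab_mm"], rows["bc_mm"], rows["ac_mm"]))
        index = rows.index
    else:
        triples = [(t.ab_mm, t.bc_mm, t.ac_mm) for t in rows]
        index = pd.RangeIndex(len(triples))

    columns = FEATURE_SETS[set_name]
    records = []
    for i, (ab, bc, ac) in zip(index, triples):
        try:
            tri = TriangleMeasurements(ab, bc, ac)
            feats = derive_features(tri, degrees=degrees)
        except TriangleError as exc:
            raise TriangleError(f"row {i}: {exc}") from exc
        full = {"ab_mm": ab, "bc_mm": bc, "ac_mm": ac, **feats.__dict__}
        records.append([full[c] for c in columns])
    return pd.DataFrame(records, columns=list(columns), index=index, dtype=float)
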
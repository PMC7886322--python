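"""Parametric three-sub-tendon Achilles geometry.

The free Achilles tendon is modelled as a stack of elliptical cross-sections
partitioned into the three sub-tendons by two straight chords:

* a transverse chord at y = y0 separates the anterior soleus (SOL) region
  from the posterior gastrocnemii,
* a sagittal chord at x = x0 splits the posterior region into the medial
  (MG, x < x0) and lateral (LG, x > x0) gastrocnemius regions.

Chord positions are solved so the partition areas match prescribed area
fractions.  The canonical arrangement (SOL anterior, MG posterior-medial,
LG posterior-lateral) is defined at the proximal end; passing distally the
sections rotate laterally by a total twist angle.  Coordinates: x lateral,
y posterior, z longitudinal (+z proximal, distal face at z = 0).

Three archetypes emulate the three dissected tendons: Model 1 is the longest
(70 mm) and most twisted, Models 2 and 3 are 40 mm, with total cross-sections
of 89.1, 90.4 and 42.3 mm^2 respectively.  Only the section spacing, total
cross-sectional areas, lengths, arrangement and qualitative twist of the real
tendons are reproduced; the section outlines themselves are procedural.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import SUBTENDON_ORDER, SubTendonID

__all__ = [
    "CrossSection",
    "TendonGeometry",
    "ARCHETYPES",
    "make_archetype",
    "section_areas",
    "polygon_area",
]

#: Default sub-tendon area fractions, LG : MG : SOL (from the in vitro mean
#: cross-sectional areas 9.3 / 13.4 / 32.8 mm^2).
DEFAULT_FRACTIONS: dict[SubTendonID, float] = {
    SubTendonID.LG: 9.3 / 55.5,
    SubTendonID.MG: 13.4 / 55.5,
    SubTendonID.SOL: 32.8 / 55.5,
}

#: Archetype defaults.  Twist angles are stated modelling assumptions (the
#: source tendons are described only qualitatively): Model 1's LG reaches the
#: anterior surface distally, implying roughly a quarter turn.
ARCHETYPES: dict[int, dict] = {
    1: {"length": 70.0, "total_csa": 89.1, "twist_deg": 90.0},
    2: {"length": 40.0, "total_csa": 90.4, "twist_deg": 40.0},
    3: {"length": 40.0, "total_csa": 42.3, "twist_deg": 40.0},
}

DEFAULT_ASPECT = 2.0  # mediolateral : anteroposterior semi-axis ratio
DEFAULT_SECTION_SPACING = 10.0  # mm


def polygon_area(points: np.ndarray) -> float:
    """Unsigned polygon area via the shoelace formula.

    ``points`` is an (n, 2) array of vertices of a simple closed polygon
    (first vertex not repeated).  Orientation-independent.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2 or len(p) < 3:
        raise ValueError("polygon needs an (n>=3, 2) vertex array")
    x, y = p[:, 0], p[:, 1]
    s = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    area = abs(float(s))
    if area <= 0:
        raise ValueError("degenerate polygon (area <= 0)")
    return area


@dataclass(frozen=True)
class PartitionParams:
    """Analytic description of one partitioned elliptical section."""

    a: float  # lateral semi-axis (mm)
    b: float  # posterior semi-axis (mm)
    y0: float  # transverse chord ordinate (SOL below)
    x0: float  # sagittal chord abscissa (LG lateral of it)

    @property
    def x_chord(self) -> float:
        """Half-width of the transverse chord at y = y0."""
        return self.a * math.sqrt(max(1.0 - (self.y0 / self.b) ** 2, 0.0))

    @property
    def y_top(self) -> float:
        """Ellipse ordinate above the sagittal chord at x = x0."""
        return self.b * math.sqrt(max(1.0 - (self.x0 / self.a) ** 2, 0.0))


def _solve_partition(total_csa: float, fractions: dict[SubTendonID, float],
                     aspect: float) -> PartitionParams:
    if total_csa <= 0:
        raise ValueError("total CSA must be positive")
    fr = {k: float(v) for k, v in fractions.items()}
    if any(v <= 0 for v in fr.values()):
        raise ValueError("area fractions must be positive")
    norm = sum(fr.values())
    fr = {k: v / norm for k, v in fr.items()}
    f_sol, f_lg = fr[SubTendonID.SOL], fr[SubTendonID.LG]

    a = math.sqrt(total_csa * aspect / math.pi)
    b = a / aspect

    # transverse chord: ellipse area below y0 equals f_sol * total
    def seg(u):  # normalised area below y0 = u*b, in units of a*b
        return math.pi / 2 + math.asin(u) + u * math.sqrt(1 - u * u)

    u0 = brentq(lambda u: seg(u) - math.pi * f_sol, -0.999999, 0.999999,
                xtol=1e-14)
    y0 = u0 * b

    # sagittal chord: area of {y >= y0, x >= x0} equals f_lg * total
    xa = a * math.sqrt(1 - u0 * u0)

    def above(x):  # integral of (y_ell(x') - y0) dx' from x to xa
        def F(t):
            s = t / a
            return 0.5 * a * b * (math.asin(s) + s * math.sqrt(1 - s * s)) - y0 * t
        return F(xa) - F(x)

    x0 = brentq(lambda x: above(x) - f_lg * total_csa, -xa + 1e-12, xa - 1e-12,
                xtol=1e-14)
    return PartitionParams(a=a, b=b, y0=y0, x0=x0)


def _arc(params: PartitionParams, th0: float, th1: float, n: int) -> np.ndarray:
    th = np.linspace(th0, th1, n + 1)
    return np.column_stack([params.a * np.cos(th), params.b * np.sin(th)])


def base_partition_polygons(params: PartitionParams, n_arc: int = 48
                            ) -> dict[SubTendonID, np.ndarray]:
    """Partition polygons in the canonical (untwisted) frame.

    Adjacent partitions share their chord vertices exactly, so the three
    polygons tile the (polygonised) ellipse to floating-point precision.
    """
    a, b, y0, x0 = params.a, params.b, params.y0, params.x0
    xa, yt = params.x_chord, params.y_top
    th_r = math.atan2(y0 / b, xa / a)
    th_l = math.pi - th_r
    th_t = math.atan2(yt / b, x0 / a)

    def chord(p, q, n):
        t = np.linspace(0.0, 1.0, n + 1)[:, None]
        return np.asarray(p) * (1 - t) + np.asarray(q) * t

    P_L, P_R = np.array([-xa, y0]), np.array([xa, y0])
    J, T = np.array([x0, y0]), np.array([x0, yt])

    def ring(chains):
        pts = np.vstack([c[:-1] for c in chains])
        x, y = pts[:, 0], pts[:, 1]
        signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        if signed < 0:
            pts = pts[::-1]
        return pts

    sol = ring([
        chord(P_R, P_L, n_arc // 2),
        _arc(params, th_l - 2 * math.pi, th_r, n_arc),  # bottom arc P_L -> P_R
    ])
    lg = ring([
        chord(J, P_R, max(n_arc // 4, 2)),
        _arc(params, th_r, th_t, n_arc // 2),  # arc P_R -> T
        chord(T, J, max(n_arc // 4, 2)),
    ])
    mg = ring([
        chord(J, T, max(n_arc // 4, 2)),
        _arc(params, th_t, th_l, n_arc // 2),  # arc T -> P_L
        chord(P_L, J, max(n_arc // 4, 2)),
    ])
    return {SubTendonID.SOL: sol, SubTendonID.LG: lg, SubTendonID.MG: mg}


def rotation_2d(angle_deg: float) -> np.ndarray:
    t = math.radians(angle_deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s], [s, c]])


@dataclass
class CrossSection:
    """One transverse section: outer boundary plus sub-tendon partitions.

    ``twist_angle`` is the rotation of this section about the longitudinal
    axis relative to the distal (z = 0) section, degrees.
    """

    z: float
    outer_boundary: np.ndarray
    partitions: dict[SubTendonID, np.ndarray]
    twist_angle: float

    def validate(self, closure_tol: float = 1.0) -> None:
        outer = polygon_area(self.outer_boundary)
        areas = {s: polygon_area(p) for s, p in self.partitions.items()}
        if any(v <= 0 for v in areas.values()):
            raise ValueError("partition with non-positive area")
        if abs(sum(areas.values()) - outer) >= closure_tol:
            raise ValueError(
                f"partition areas {sum(areas.values()):.3f} do not close the "
                f"outer area {outer:.3f} within {closure_tol} mm^2"
            )


@dataclass
class TendonGeometry:
    """Stack of partitioned cross-sections defining one tendon model."""

    sections: list[CrossSection]
    length: float
    model_id: int | str
    section_spacing: float = DEFAULT_SECTION_SPACING
    total_csa: float = 0.0
    fractions: dict[SubTendonID, float] = field(default_factory=dict)
    aspect: float = DEFAULT_ASPECT
    twist_deg: float = 0.0
    partition_params: PartitionParams | None = None

    def __post_init__(self) -> None:
        if len(self.sections) < 2:
            raise ValueError("need at least two sections")
        zs = [s.z for s in self.sections]
        if not all(b > a for a, b in zip(zs, zs[1:])):
            raise ValueError("section z must be strictly increasing")
        if abs(zs[0]) > 1e-9 or abs(zs[-1] - self.length) > 1e-9:
            raise ValueError("sections must span z = 0 .. length")
        tw = [s.twist_angle for s in self.sections]
        if not all(b >= a for a, b in zip(tw, tw[1:])) and \
           not all(b <= a for a, b in zip(tw, tw[1:])):
            raise ValueError("twist must be monotone along z")

    def twist_at(self, z: float) -> float:
        """Twist angle (deg, relative to the distal section) at height z."""
        return self.twist_deg * z / self.length

    def frame_rotation_at(self, z: float) -> float:
        """Rotation (deg) applied to the canonical proximal layout at z.

        Zero at the proximal end; negative (lateral) rotation distally.
        """
        return -(self.twist_deg - self.twist_at(z))


_OVERRIDE_KEYS = {"total_csa", "length", "twist_deg", "fractions", "aspect",
                  "section_spacing"}


def make_archetype(model_id: int, overrides: dict | None = None) -> TendonGeometry:
    """Build one of the three archetype tendon geometries.

    Parameters
    ----------
    model_id : {1, 2, 3}
        Archetype: Model 1 is 70 mm long, 89.1 mm^2, most twisted (90 deg
        default); Model 2 is 40 mm, 90.4 mm^2; Model 3 is the thinnest
        (40 mm, 42.3 mm^2).  Twists default to 40 deg for Models 2-3.
    overrides : dict, optional
        Restricted to: total_csa, length, twist_deg, fractions, aspect,
        section_spacing.
    """
    if model_id not in ARCHETYPES:
        raise ValueError(f"unknown model_id {model_id!r}; expected 1, 2 or 3")
    cfg = dict(ARCHETYPES[model_id])
    cfg["fractions"] = dict(DEFAULT_FRACTIONS)
    cfg["aspect"] = DEFAULT_ASPECT
    cfg["section_spacing"] = DEFAULT_SECTION_SPACING
    if overrides:
        unknown = set(overrides) - _OVERRIDE_KEYS
        if unknown:
            raise ValueError(f"unknown override keys: {sorted(unknown)}")
        cfg.update(overrides)

    params = _solve_partition(cfg["total_csa"], cfg["fractions"], cfg["aspect"])
    base = base_partition_polygons(params)
    outer0 = _arc(params, 0.0, 2 * math.pi, 96)[:-1]

    length = float(cfg["length"])
    spacing = float(cfg["section_spacing"])
    n_sec = int(round(length / spacing))
    zs = np.linspace(0.0, length, n_sec + 1)

    sections = []
    for z in zs:
        twist = cfg["twist_deg"] * z / length
        rot = rotation_2d(-(cfg["twist_deg"] - twist))
        sec = CrossSection(
            z=float(z),
            outer_boundary=outer0 @ rot.T,
            partitions={s: p @ rot.T for s, p in base.items()},
            twist_angle=float(twist),
        )
        sec.validate()
        sections.append(sec)

    return TendonGeometry(
        sections=sections,
        length=length,
        model_id=model_id,
        section_spacing=spacing,
        total_csa=float(cfg["total_csa"]),
        fractions={k: float(v) for k, v in cfg["fractions"].items()},
        aspect=float(cfg["aspect"]),
        twist_deg=float(cfg["twist_deg"]),
        partition_params=params,
    )


def section_areas(geometry: TendonGeometry) -> pd.DataFrame:
    """Tidy table of (z, sub_tendon, area_mm2) for every section."""
    rows = []
    for sec in geometry.sections:
        outer = polygon_area(sec.outer_boundary)
        total = 0.0
        for s in SUBTENDON_ORDER:
            area = polygon_area(sec.partitions[s])
            total += area
            rows.append({"z_mm": sec.z, "sub_tendon": str(s), "area_mm2": area})
        if abs(total - outer) >= 1.0:
            raise ValueError(f"partition closure violated at z = {sec.z}")
    return pd.DataFrame(rows)
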
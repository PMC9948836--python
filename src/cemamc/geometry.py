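"""Region model for the simulated setups.

A :class:`GeometryModel` is a cubic water phantom containing a short ordered
list of finite, z-axis-aligned cylinders (detector parts and an optional
photon cross-section enhancement shell).  Overlaps are resolved by list
order: later bodies take precedence (innermost last).  Everything outside
the phantom is vacuum ("world", region 0), the phantom body itself is
region 1 and the cylinders occupy regions 2, 3, ...

Coordinates are right-handed with the beam travelling along +z; lengths in
cm.  Boundaries are resolved by pushing a trajectory ``BOUNDARY_EPS`` past
the crossing point before relocating, the usual Monte Carlo trick to avoid
boundary re-hits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .materials import MATERIALS, Material

__all__ = [
    "BOUNDARY_EPS",
    "Region",
    "Cylinder",
    "GeometryModel",
    "build_setup",
    "PRESETS",
]

BOUNDARY_EPS = 1e-9  # cm

WORLD_REGION = 0
PHANTOM_REGION = 1


@dataclass(frozen=True)
class Region:
    """Attributes attached to one geometric region."""

    id: int
    material: Material
    xcse_factor: float = 1.0
    ecut_kinetic: float = 0.010  # MeV
    is_scoring_cavity: bool = False
    is_phantom: bool = False

    def __post_init__(self) -> None:
        if self.xcse_factor < 1.0:
            raise ValueError("xcse_factor must be >= 1")


@dataclass(frozen=True)
class Cylinder:
    """Finite cylinder with axis parallel to z."""

    center: tuple[float, float, float]
    radius: float
    half_height: float
    region: Region

    def contains(self, x: float, y: float, z: float) -> bool:
        cx, cy, cz = self.center
        if abs(z - cz) > self.half_height:
            return False
        return (x - cx) ** 2 + (y - cy) ** 2 <= self.radius**2


@dataclass(frozen=True)
class GeometryModel:
    """Phantom box plus ordered cylinder bodies (later bodies win overlaps)."""

    phantom_half_size: tuple[float, float, float]
    phantom_region: Region
    bodies: tuple[Cylinder, ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        hx, hy, hz = self.phantom_half_size
        for b in self.bodies:
            cx, cy, cz = b.center
            if (
                abs(cx) + b.radius > hx
                or abs(cy) + b.radius > hy
                or abs(cz) + b.half_height > hz
            ):
                raise ValueError(
                    f"body region {b.region.id} extends outside the phantom"
                )

    @property
    def n_regions(self) -> int:
        return 2 + len(self.bodies)

    def region(self, region_id: int) -> Region:
        if region_id == PHANTOM_REGION:
            return self.phantom_region
        return self.bodies[region_id - 2].region

    @property
    def regions(self) -> list[Region]:
        return [self.phantom_region] + [b.region for b in self.bodies]

    def locate(self, point) -> int:
        """Region id claiming ``point``; later bodies take precedence."""
        x, y, z = point
        for i in range(len(self.bodies) - 1, -1, -1):
            if self.bodies[i].contains(x, y, z):
                return 2 + i
        hx, hy, hz = self.phantom_half_size
        if abs(x) <= hx and abs(y) <= hy and abs(z) <= hz:
            return PHANTOM_REGION
        return WORLD_REGION

    def distance_to_boundary(self, pos, direction, current_region: int):
        """Distance to the nearest surface crossing and the region beyond it.

        Returns ``(t, next_region)``; ``t`` is ``inf`` when a world-region ray
        never reaches the phantom.  The direction must be unit length.
        """
        d = np.asarray(direction, dtype=float)
        if abs(float(d @ d) - 1.0) > 1e-10:
            raise ValueError("direction must be a unit vector")
        t = self._nearest_surface(np.asarray(pos, dtype=float), d, current_region)
        if not math.isfinite(t):
            return math.inf, WORLD_REGION
        probe = np.asarray(pos, dtype=float) + (t + BOUNDARY_EPS) * d
        return t, self.locate(probe)

    # -- internal ------------------------------------------------------------

    def _nearest_surface(self, pos: np.ndarray, d: np.ndarray, region: int) -> float:
        ts: list[float] = []
        hx, hy, hz = self.phantom_half_size
        inside_box = (
            abs(pos[0]) <= hx + BOUNDARY_EPS
            and abs(pos[1]) <= hy + BOUNDARY_EPS
            and abs(pos[2]) <= hz + BOUNDARY_EPS
        )
        # phantom box faces
        for axis, h in enumerate((hx, hy, hz)):
            if d[axis] != 0.0:
                for plane in (-h, h):
                    t = (plane - pos[axis]) / d[axis]
                    if t > BOUNDARY_EPS:
                        p = pos + t * d
                        oth = [0, 1, 2]
                        oth.remove(axis)
                        hh = (hx, hy, hz)
                        if all(abs(p[o]) <= hh[o] + 1e-7 for o in oth):
                            ts.append(t)
        for b in self.bodies:
            ts.extend(_cylinder_crossings(pos, d, b))
        if region == WORLD_REGION and not inside_box and not ts:
            return math.inf
        return min(ts) if ts else math.inf

    def with_xcse(self, factor: float) -> "GeometryModel":
        """Copy of the model with the given enhancement factor applied to all
        non-phantom regions currently flagged for enhancement (factor > 1
        presets) or to all detector bodies when none is flagged."""
        bodies = []
        flagged = any(b.region.xcse_factor > 1.0 for b in self.bodies)
        for b in self.bodies:
            if (not flagged) or b.region.xcse_factor > 1.0:
                bodies.append(
                    replace(b, region=replace(b.region, xcse_factor=max(1.0, factor)))
                )
            else:
                bodies.append(b)
        return replace(self, bodies=tuple(bodies))


def _cylinder_crossings(pos: np.ndarray, d: np.ndarray, b: Cylinder) -> list[float]:
    out: list[float] = []
    cx, cy, cz = b.center
    px, py, pz = pos[0] - cx, pos[1] - cy, pos[2] - cz
    a = d[0] * d[0] + d[1] * d[1]
    if a > 0.0:
        bq = px * d[0] + py * d[1]
        c = px * px + py * py - b.radius**2
        disc = bq * bq - a * c
        if disc > 0.0:
            sq = math.sqrt(disc)
            for t in ((-bq - sq) / a, (-bq + sq) / a):
                if t > BOUNDARY_EPS and abs(pz + t * d[2]) <= b.half_height:
                    out.append(t)
    if d[2] != 0.0:
        for plane in (-b.half_height, b.half_height):
            t = (plane - pz) / d[2]
            if t > BOUNDARY_EPS:
                x, y = px + t * d[0], py + t * d[1]
                if x * x + y * y <= b.radius**2:
                    out.append(t)
    return out


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

#: water disc detector: radius = height = 0.1 cm
DISC_RADIUS = 0.1
DISC_HALF_HEIGHT = 0.05

# simplified thimble chamber (generic; stands in for a real small-volume
# chamber): air cavity r=0.1 cm, length 0.5 cm (~0.015 cm^3), PMMA wall
# 0.06 cm, graphite central electrode r=0.015 cm, PMMA stem extending 1 cm.
CAV_RADIUS = 0.1
CAV_HALF = 0.25
WALL_THICK = 0.06
ELECTRODE_RADIUS = 0.015
STEM_LENGTH = 1.0
CHAMBER_SHELL_HALF = 0.75  # XCSE shell height fixed to 1.5 cm

PRESETS = ("external_disc", "external_chamber", "immersed_chamber", "immersed_voxel")


def build_setup(
    preset: str,
    *,
    r: float = 0.0,
    xcse_factor: float = 1.0,
    depth: float = 5.0,
    phantom_side: float = 30.0,
    field_size: float = 4.0,
    ssd: float = 95.0,
    delta: float = 0.010,
) -> GeometryModel:
    """Build one of the four preset geometries.

    ``r`` is the XCSE shell thickness [cm]; ``r = 0`` enhances the detector
    bodies only (no shell body is created).  External presets place the
    detector reference point at ``depth`` below the entrance face; the
    immersed presets put the source at the phantom centre and the detector
    reference point 1 cm away on the z axis.  The phantom is centred on the
    origin; the entrance face is at z = -side/2.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    if r < 0:
        raise ValueError("shell thickness r must be >= 0")
    half = phantom_side / 2.0
    water = MATERIALS["water"]
    airm = MATERIALS["air"]
    pmma = MATERIALS["pmma"]
    graphite = MATERIALS["graphite"]
    phantom = Region(PHANTOM_REGION, water, 1.0, delta, is_phantom=True)
    if preset.startswith("external"):
        z_det = -half + depth
    else:
        z_det = 1.0
    b = max(1.0, xcse_factor)
    bodies: list[Cylinder] = []
    next_id = 2

    def add(center, radius, half_height, material, *, xcse, cavity=False):
        nonlocal next_id
        reg = Region(next_id, material, xcse, delta, is_scoring_cavity=cavity)
        bodies.append(Cylinder(center, radius, half_height, reg))
        next_id += 1

    if preset in ("external_disc", "immersed_voxel"):
        if r > 0.0:
            add((0.0, 0.0, z_det), DISC_RADIUS + r, DISC_HALF_HEIGHT + r, water, xcse=b)
        add((0.0, 0.0, z_det), DISC_RADIUS, DISC_HALF_HEIGHT, water, xcse=b, cavity=True)
    else:
        wall_r = CAV_RADIUS + WALL_THICK
        wall_half = CAV_HALF + WALL_THICK
        if r > 0.0:
            add((0.0, 0.0, z_det), wall_r + r, CHAMBER_SHELL_HALF, water, xcse=b)
        stem_center = z_det + wall_half + STEM_LENGTH / 2.0
        add((0.0, 0.0, stem_center), wall_r, STEM_LENGTH / 2.0, pmma, xcse=b)
        add((0.0, 0.0, z_det), wall_r, wall_half, pmma, xcse=b)
        add((0.0, 0.0, z_det), CAV_RADIUS, CAV_HALF, airm, xcse=b, cavity=True)
        add((0.0, 0.0, z_det), ELECTRODE_RADIUS, CAV_HALF - WALL_THICK, graphite, xcse=b)
    model = GeometryModel(
        (half, half, half), phantom, tuple(bodies), name=preset
    )
    return model
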
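"""Rosette architecture: organ initiation, phyllotaxis, hyponasty, senescence, geometry.

An *Arabidopsis* rosette is represented as an ordered collection of leaves,
each split into a petiole (thin inclined segment from the rosette centre) and
a lamina (planar ellipse attached at the petiole tip), plus a single root that
acts purely as a carbon sink.  Leaves emerge on a fixed plastochron in a
spiral phyllotactic pattern, raise their elevation angle (hyponasty) when
crowded or when the lamina perceives a low red:far-red ratio, and senesce
after a fixed age.  The geometry produced here is what the canopy light
module intersects rays with.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PlasticityStrategy",
    "Leaf",
    "Plant",
    "OrganSchedule",
    "AngleParams",
    "SurfacePatches",
    "initiate_organs",
    "phyllotaxis_azimuth",
    "update_leaf_angle",
    "senesce",
    "leaf_geometry",
    "plant_patches",
    "stand_patches",
]

#: leaf age (days) beyond which a leaf is senesced ("after 40 days of age")
SENESCENCE_AGE = 40.0


@dataclass(frozen=True)
class PlasticityStrategy:
    """Heritable shade-avoidance strategy.

    ``alpha`` is the curvature of the response curve mapping perceived R:FR to
    the relative organ growth factor F; ``n_exponent`` scales how strongly the
    lamina carbon demand is down-regulated relative to petiole elongation;
    ``rfr_control`` is the reference (unshaded) R:FR of the light source.
    """

    alpha: float
    n_exponent: float = 2.0
    rfr_control: float = 2.3

    def __post_init__(self) -> None:
        if not math.isfinite(self.alpha):
            raise ValueError("alpha must be finite")
        if self.n_exponent < 0:
            raise ValueError("n_exponent must be >= 0")
        if not self.rfr_control > 0:
            raise ValueError("rfr_control must be > 0")


@dataclass
class Leaf:
    """State of one leaf (petiole + lamina)."""

    rank: int
    emergence_day: float
    azimuth: float                      # degrees
    petiole_length: float = 0.0         # m
    petiole_biomass: float = 0.0        # mg
    lamina_area: float = 0.0            # m^2
    lamina_biomass: float = 0.0         # mg
    elevation_angle: float = 10.0       # degrees from horizontal
    petiole_growing: bool = True
    lamina_growing: bool = True
    senesced: bool = False
    # carbon owed for past photomorphogenic elongation, paid next step (mg)
    pending_elongation_demand: float = 0.0
    # last perceived light environment (set daily by the simulation loop)
    petiole_rfr: float = float("nan")
    lamina_rfr: float = float("nan")
    lamina_par: float = 0.0             # absorbed PAR flux density, umol m-2 s-1

    def age(self, day: float) -> float:
        return day - self.emergence_day

    @property
    def biomass(self) -> float:
        return self.petiole_biomass + self.lamina_biomass


@dataclass
class Plant:
    position: tuple[float, float]
    strategy: PlasticityStrategy
    leaves: list[Leaf] = field(default_factory=list)
    root_biomass: float = 0.0           # mg
    seed_carbon_used: float = 0.0       # mg endowed from the seed so far
    base_azimuth: float = 0.0           # degrees, randomized per replicate
    is_focal: bool = False

    @property
    def total_biomass(self) -> float:
        """Petioles + laminas + root, mg.  Senesced biomass is retained."""
        return self.root_biomass + sum(l.biomass for l in self.leaves)

    def active_leaves(self) -> list[Leaf]:
        return [l for l in self.leaves if not l.senesced]


@dataclass(frozen=True)
class OrganSchedule:
    """Leaf initiation schedule and seed-scale organ endowments."""

    germination_day: float = 3.0
    plastochron: float = 1.5            # d between successive leaf emergences
    divergence_angle: float = 137.5     # degrees
    initial_lamina_biomass: float = 0.05   # mg
    initial_petiole_biomass: float = 0.02  # mg
    initial_elevation: float = 10.0     # degrees

    def leaves_emerged(self, day: float) -> int:
        if day < self.germination_day:
            return 0
        return int(math.floor((day - self.germination_day) / self.plastochron))

    def emergence_day_of(self, rank: int) -> float:
        return self.germination_day + rank * self.plastochron


@dataclass(frozen=True)
class AngleParams:
    """Hyponastic leaf-angle response settings."""

    step: float = 16.0                  # degrees per time-step when triggered
    max_angle: float = 80.0             # degrees
    touch_distance: float = 0.002       # m, "touching" trigger
    rfr_threshold: float = 0.5          # lamina R:FR trigger
    #: if True only leaves of *other* plants count as touching neighbours
    restrict_to_neighbours: bool = False


def phyllotaxis_azimuth(rank: int, base: float = 0.0, divergence: float = 137.5) -> float:
    """Azimuth (degrees) of a leaf in a spiral phyllotactic pattern."""
    if rank < 1:
        raise ValueError(f"rank must be >= 1, got {rank}")
    return (base + (rank - 1) * divergence) % 360.0


def initiate_organs(plant: Plant, day: float, schedule: OrganSchedule,
                    sla: float, petiole_linear_density: float) -> float:
    """Append leaves that have emerged by ``day``; returns seed carbon endowed (mg).

    Idempotent within a day: calling twice adds nothing the second time.
    Each new leaf starts at the seed-scale biomass of the schedule, with its
    dimensions given by the mass-to-dimension conversions (``sla`` in m^2/mg,
    petiole linear density in mg/m).
    """
    n_target = schedule.leaves_emerged(day)
    endowed = 0.0
    while len(plant.leaves) < n_target:
        rank = len(plant.leaves) + 1
        leaf = Leaf(
            rank=rank,
            emergence_day=schedule.emergence_day_of(rank),
            azimuth=phyllotaxis_azimuth(rank, plant.base_azimuth,
                                        schedule.divergence_angle),
            petiole_biomass=schedule.initial_petiole_biomass,
            lamina_biomass=schedule.initial_lamina_biomass,
            petiole_length=schedule.initial_petiole_biomass / petiole_linear_density,
            lamina_area=schedule.initial_lamina_biomass * sla,
            elevation_angle=schedule.initial_elevation,
        )
        plant.leaves.append(leaf)
        endowed += leaf.biomass
    plant.seed_carbon_used += endowed
    return endowed


def update_leaf_angle(leaf: Leaf, min_neighbour_distance: float,
                      lamina_rfr: float, params: AngleParams) -> Leaf:
    """Hyponasty: raise elevation by one step if touching or under low R:FR."""
    if leaf.senesced:
        raise ValueError("cannot update angle of a senesced leaf")
    if min_neighbour_distance < 0:
        raise ValueError("neighbour distance must be >= 0")
    triggered = (min_neighbour_distance < params.touch_distance
                 or lamina_rfr < params.rfr_threshold)
    if triggered:
        leaf.elevation_angle = min(params.max_angle,
                                   leaf.elevation_angle + params.step)
    return leaf


def senesce(plant: Plant, day: float) -> Plant:
    """Flag leaves strictly older than the senescence age.

    Senesced leaves drop out of light capture and sink bookkeeping from the
    next step on; their biomass stays in the plant total.
    """
    for leaf in plant.leaves:
        if leaf.age(day) > SENESCENCE_AGE:
            leaf.senesced = True
            leaf.petiole_growing = False
            leaf.lamina_growing = False
    return plant


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

KIND_LAMINA = 0
KIND_PETIOLE = 1

#: petiole interception width, m (thin segment of negligible area)
PETIOLE_WIDTH = 0.0015
#: lamina ellipse aspect ratio, major:minor
LAMINA_ASPECT = 2.0


@dataclass
class SurfacePatches:
    """Struct-of-arrays scene description consumed by the light module.

    Every patch is a planar ellipse: centre ``c``, unit normal ``n`` and
    scaled in-plane axes ``ua = u/a``, ``vb = v/b`` so that a plane point p is
    inside iff ((p-c)@ua)^2 + ((p-c)@vb)^2 <= 1.
    """

    centers: np.ndarray       # (P, 3)
    normals: np.ndarray       # (P, 3)
    ua: np.ndarray            # (P, 3)
    vb: np.ndarray            # (P, 3)
    areas: np.ndarray         # (P,)
    kinds: np.ndarray         # (P,) int8: 0 lamina, 1 petiole
    plant_idx: np.ndarray     # (P,) int32
    leaf_idx: np.ndarray      # (P,) int32 index into plant.leaves
    sensors: np.ndarray       # (P, 3) perception point per patch

    def __len__(self) -> int:
        return len(self.areas)

    @classmethod
    def empty(cls) -> "SurfacePatches":
        z3 = np.zeros((0, 3))
        z = np.zeros(0)
        zi = np.zeros(0, dtype=np.int32)
        return cls(z3, z3.copy(), z3.copy(), z3.copy(), z,
                   np.zeros(0, dtype=np.int8), zi, zi.copy(), z3.copy())

    @classmethod
    def concat(cls, parts: list["SurfacePatches"]) -> "SurfacePatches":
        parts = [p for p in parts if len(p)]
        if not parts:
            return cls.empty()
        return cls(*[np.concatenate([getattr(p, f) for p in parts])
                     for f in ("centers", "normals", "ua", "vb", "areas",
                               "kinds", "plant_idx", "leaf_idx", "sensors")])

    def lamina_tips(self) -> np.ndarray:
        """Lamina distal tip points, used for the touching trigger."""
        lam = self.kinds == KIND_LAMINA
        # ua = u_hat / a  =>  u_hat * a = ua / |ua|^2
        ua = self.ua[lam]
        norm2 = np.maximum((ua ** 2).sum(axis=1), 1e-300)
        return self.centers[lam] + ua / norm2[:, None]


def _leaf_frame(elevation_deg: float, azimuth_deg: float):
    """Unit direction along the leaf plus an upward-facing normal."""
    e = math.radians(elevation_deg)
    a = math.radians(azimuth_deg)
    d = np.array([math.cos(e) * math.cos(a),
                  math.cos(e) * math.sin(a),
                  math.sin(e)])
    # normal: component of vertical perpendicular to d (upward-facing)
    n = np.array([0.0, 0.0, 1.0]) - d[2] * d
    ln = np.linalg.norm(n)
    if ln < 1e-12:   # vertical leaf: any horizontal normal
        n = np.array([math.cos(a + math.pi / 2), math.sin(a + math.pi / 2), 0.0])
    else:
        n = n / ln
    s = np.cross(d, n)  # in-plane lateral axis, horizontal
    return d, n, s


def leaf_geometry(leaf: Leaf, plant_position: tuple[float, float],
                  plant_index: int = 0, leaf_index: int = 0) -> SurfacePatches:
    """Petiole segment + lamina ellipse for one leaf, as ellipse patches.

    The petiole runs from the rosette centre to its tip at length x
    (cos e cos a, cos e sin a, sin e); the lamina (flat ellipse, 2:1 aspect,
    area-parameterized) is attached at the tip and continues along the same
    inclined direction.  Band-specific optics are attached by the light module
    from the patch ``kinds``.
    """
    if leaf.petiole_length < 0 or leaf.lamina_area < 0:
        raise ValueError("leaf sizes must be >= 0")
    base = np.array([plant_position[0], plant_position[1], 0.0])
    d, n, s = _leaf_frame(leaf.elevation_angle, leaf.azimuth)
    tip = base + leaf.petiole_length * d
    parts: list[SurfacePatches] = []

    if leaf.petiole_length > 0:
        a = leaf.petiole_length / 2.0
        b = PETIOLE_WIDTH / 2.0
        c = base + a * d
        parts.append(SurfacePatches(
            centers=c[None, :], normals=n[None, :],
            ua=(d / a)[None, :], vb=(s / b)[None, :],
            areas=np.array([math.pi * a * b]),
            kinds=np.array([KIND_PETIOLE], dtype=np.int8),
            plant_idx=np.array([plant_index], dtype=np.int32),
            leaf_idx=np.array([leaf_index], dtype=np.int32),
            sensors=c[None, :],   # petiole perceives at its midpoint
        ))
    if leaf.lamina_area > 0:
        b = math.sqrt(leaf.lamina_area / (math.pi * LAMINA_ASPECT))
        a = LAMINA_ASPECT * b
        c = tip + a * d
        parts.append(SurfacePatches(
            centers=c[None, :], normals=n[None, :],
            ua=(d / a)[None, :], vb=(s / b)[None, :],
            areas=np.array([leaf.lamina_area]),
            kinds=np.array([KIND_LAMINA], dtype=np.int8),
            plant_idx=np.array([plant_index], dtype=np.int32),
            leaf_idx=np.array([leaf_index], dtype=np.int32),
            sensors=c[None, :],   # lamina perceives at the blade centre
        ))
    return SurfacePatches.concat(parts)


def plant_patches(plant: Plant, plant_index: int = 0) -> SurfacePatches:
    """All non-senesced leaf patches of one plant."""
    parts = [leaf_geometry(l, plant.position, plant_index, i)
             for i, l in enumerate(plant.leaves) if not l.senesced]
    return SurfacePatches.concat(parts)


def stand_patches(plants: list[Plant]) -> SurfacePatches:
    """Scene for a whole stand, patch plant_idx pointing back into ``plants``."""
    return SurfacePatches.concat([plant_patches(p, i) for i, p in enumerate(plants)])
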
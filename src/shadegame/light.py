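"""Canopy light: absorbed PAR and locally perceived R:FR per organ.

The stand is a regular square grid treated as an infinite toroidal tiling.  A
diffuse (cosine-weighted) overcast sky of fixed R:FR and PAR intensity is
sampled with stratified Monte Carlo rays that are absorbed, reflected and
transmitted by lamina and petiole patches per band (red, far-red, PAR); this
gives each organ's absorbed PAR and a whole-scene energy ledger.  Organ-level
R:FR *perception* is computed by sensor rays from each organ's perception
point: upward rays carry sky flux attenuated by the transmittance of every
crossed patch, downward rays gather first-order scattered light (mostly
far-red, which leaves reflect much more strongly than red) from the Monte
Carlo pass's incident estimates.  Because every optical interaction depletes
red at least as strongly as far-red, no organ ever perceives an R:FR above
the source ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _trace
from .architecture import KIND_LAMINA, KIND_PETIOLE, Plant, SurfacePatches

__all__ = [
    "LAMINA_OPTICS",
    "StandLayout",
    "LightSourceSpec",
    "LightSample",
    "grid_positions",
    "compute_light",
    "daily_par_dose",
    "mean_plant_rfr",
    "compute_lai",
]

#: lamina absorptance per band (red, far-red, PAR); the remainder is split
#: equally between reflection and transmission, so leaves selectively absorb
#: red and reflect/transmit far-red.  Petioles absorb whatever they intercept.
LAMINA_OPTICS = {"absorptance": np.array([0.85, 0.15, 0.85])}

_BANDS = ("red", "farred", "par")


@dataclass(frozen=True)
class StandLayout:
    """Regular square planting grid; spacing follows from density."""

    density: float              # plants m^-2
    rows: int = 7
    cols: int = 7
    tile_extent: int = 20       # reportable replication count per axis

    def __post_init__(self) -> None:
        if not self.density > 0:
            raise ValueError("density must be > 0")
        if self.rows * self.cols < 9:
            raise ValueError("stand needs rows*cols >= 9 for a full "
                             "neighbour ring around the focal plant")

    @property
    def spacing(self) -> float:
        return self.density ** -0.5

    @property
    def period(self) -> tuple[float, float]:
        return self.cols * self.spacing, self.rows * self.spacing


@dataclass(frozen=True)
class LightSourceSpec:
    """Diffuse growth-chamber sky."""

    par_intensity: float = 220.0    # umol m^-2 s^-1 on the horizontal
    rfr_ratio: float = 2.3
    photoperiod: float = 9.0        # h per day
    ray_count: int = 20000
    max_bounces: int = 2
    sensor_up_rays: int = 8
    sensor_down_rays: int = 4
    angular_distribution: str = "cosine"

    def __post_init__(self) -> None:
        if min(self.par_intensity, self.rfr_ratio, self.photoperiod) < 0:
            raise ValueError("light source parameters must be >= 0")
        if self.ray_count < 1:
            raise ValueError("ray_count must be >= 1")


@dataclass
class LightSample:
    """Per-organ light environment plus the scene energy ledger."""

    patches: SurfacePatches
    incident: np.ndarray        # (P, 3) band flux on each patch (flux * m^2)
    absorbed: np.ndarray        # (P, 3)
    perceived: np.ndarray       # (P, 3) band flux density at the sensor point
    emitted: np.ndarray         # (3,) total emitted per band
    soil: np.ndarray            # (3,)
    escaped: np.ndarray         # (3,)
    truncated: np.ndarray       # (3,)

    @property
    def absorbed_par_flux(self) -> np.ndarray:
        """Absorbed PAR flux density per organ, umol m^-2 s^-1.

        Estimated from the sensor-ray irradiance at the organ's perception
        point times the PAR absorptance: the Monte Carlo tallies are unbiased
        but far too noisy for seedling-scale organs (a 1 cm^2 leaf in a
        0.25 m^2 unit cell sees well under one ray per day), while the sensor
        estimate is organ-size independent.
        """
        absorptance, _, _, _ = _optics(self.patches)
        return self.perceived[:, 2] * absorptance[:, 2]

    @property
    def mc_absorbed_par_flux(self) -> np.ndarray:
        """Monte-Carlo absorbed PAR per unit patch area (noisy for small organs)."""
        area = np.maximum(self.patches.areas, 1e-300)
        return self.absorbed[:, 2] / area

    @property
    def perceived_rfr(self) -> np.ndarray:
        """Perceived R:FR per patch; NaN where no far-red arrives."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.perceived[:, 1] > 0,
                            self.perceived[:, 0] / self.perceived[:, 1],
                            np.nan)

    def energy_closure(self) -> np.ndarray:
        """(absorbed + soil + escaped + truncated) / emitted per band."""
        budget = (self.absorbed.sum(axis=0) + self.soil + self.escaped
                  + self.truncated)
        return budget / np.where(self.emitted > 0, self.emitted, 1.0)


def grid_positions(layout: StandLayout) -> np.ndarray:
    """(rows*cols, 2) positions of a centred regular grid; the exact centre
    (the focal/mutant slot) is at index ``rows*cols // 2`` for odd grids."""
    s = layout.spacing
    xs = (np.arange(layout.cols) - (layout.cols - 1) / 2) * s
    ys = (np.arange(layout.rows) - (layout.rows - 1) / 2) * s
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    return np.column_stack([gx.ravel(), gy.ravel()])


def focal_index(layout: StandLayout) -> int:
    return (layout.rows // 2) * layout.cols + layout.cols // 2


def _optics(patches: SurfacePatches):
    """Per-patch per-band absorptance, scattered remainder, transmittance
    and reflectance arrays."""
    P = len(patches)
    absorptance = np.empty((P, 3))
    lam = patches.kinds == KIND_LAMINA
    absorptance[lam] = LAMINA_OPTICS["absorptance"]
    absorptance[~lam] = 1.0      # petiole: absorbing interceptor
    remainder = 1.0 - absorptance
    tau = remainder / 2.0        # transmission = reflection = remainder / 2
    rho = remainder / 2.0
    return absorptance, remainder, tau, rho


def compute_light(patches: SurfacePatches, layout: StandLayout,
                  source: LightSourceSpec, rng: np.random.Generator,
                  sensor_mask: np.ndarray | None = None) -> LightSample:
    """Trace one day of diffuse sky light through the stand.

    ``sensor_mask`` selects the patches whose perception point gets sensor
    rays (default: all); unsensed patches report zero perceived flux.
    Degenerate scenes (no patches) return all-zero absorption.
    """
    Lx, Ly = layout.period
    sky = np.array([source.rfr_ratio, 1.0, source.par_intensity])
    P = len(patches)
    if P == 0:
        z = np.zeros((0, 3))
        return LightSample(patches, z, z.copy(), z.copy(),
                           np.zeros(3), np.zeros(3), np.zeros(3), np.zeros(3))
    absorptance, remainder, tau, rho = _optics(patches)

    n_side = max(1, int(round(math.sqrt(source.ray_count))))
    n_rays = n_side * n_side
    w0 = sky * Lx * Ly / n_rays
    bound = 1.0 / np.maximum(np.linalg.norm(patches.ua, axis=1), 1e-300)
    z_top = float((patches.centers[:, 2] + bound).max()) + 1e-4

    C = np.ascontiguousarray(patches.centers)
    N = np.ascontiguousarray(patches.normals)
    UA = np.ascontiguousarray(patches.ua)
    VB = np.ascontiguousarray(patches.vb)
    seed_mc, seed_sense = [int(s) for s in
                           rng.integers(0, 2 ** 31 - 1, size=2)]
    incident, absorbed, soil, escaped, truncated = _trace.trace_mc(
        seed_mc, n_side, n_side, Lx, Ly, z_top, w0,
        C, N, UA, VB, absorptance, remainder, int(source.max_bounces))

    exitance = rho * incident / np.maximum(patches.areas, 1e-300)[:, None]
    if sensor_mask is None:
        sensor_mask = np.ones(P, dtype=bool)
    perceived = np.zeros((P, 3))
    idx = np.flatnonzero(sensor_mask)
    if idx.size:
        sensed = _trace.sense(
            seed_sense, np.ascontiguousarray(patches.sensors[idx]),
            idx.astype(np.int64), C, N, UA, VB, tau, exitance,
            Lx, Ly, z_top, sky,
            int(source.sensor_up_rays), int(source.sensor_down_rays))
        perceived[idx] = sensed
    emitted = sky * Lx * Ly
    return LightSample(patches, incident, absorbed, perceived,
                       emitted, soil, escaped, truncated)


def daily_par_dose(absorbed_par: float, photoperiod: float) -> float:
    """mol m^-2 d^-1 from a flux in umol m^-2 s^-1 over ``photoperiod`` hours."""
    if absorbed_par < 0 or photoperiod < 0:
        raise ValueError("inputs must be >= 0")
    return absorbed_par * 3600.0 * photoperiod * 1e-6


def mean_plant_rfr(sample: LightSample, plant_index: int) -> float:
    """Whole-plant R:FR: total perceived red over total perceived far-red.

    Totals are the Monte Carlo band fluxes intercepted by the plant's
    non-senesced organs (summation before the ratio), so canopy strata count
    by the light they actually receive.  NaN when no far-red was intercepted
    (possible for seedling-scale plants on sparse-ray days).
    """
    mask = sample.patches.plant_idx == plant_index
    if not mask.any():
        raise ValueError(f"plant {plant_index} has no organs in the sample")
    red = sample.incident[mask, 0].sum()
    farred = sample.incident[mask, 1].sum()
    return red / farred if farred > 0 else float("nan")


def compute_lai(plant: Plant, density: float) -> float:
    """Leaf area index contributed by one plant: non-senesced lamina area x density."""
    return density * sum(l.lamina_area for l in plant.leaves if not l.senesced)
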
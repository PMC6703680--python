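"""Daily-step stand simulations: monomorphic and mutant-in-resident canopies.

One simulated day runs, in order: organ initiation, canopy light transport,
photosynthesis into each plant's carbon pool, R:FR response factors per organ,
sink-demand assembly and relative-sink-strength allocation, dimension update,
petiole elongation (with its next-step carbon debt), hyponastic leaf-angle
update, and senescence.  The focal (centre) plant carries the mutant strategy;
all others the resident strategy.  Performance is the focal plant's total
accumulated biomass (root + laminas + petioles, senesced leaves included)
after the final day.  Runs are bit-reproducible from their seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .architecture import (AngleParams, KIND_LAMINA, KIND_PETIOLE,
                           OrganSchedule, Plant, PlasticityStrategy,
                           initiate_organs, senesce, stand_patches,
                           update_leaf_angle)
from .light import (LightSourceSpec, StandLayout, compute_lai, compute_light,
                    focal_index, grid_positions, mean_plant_rfr)
from .physiology import (PhysiologyParams, SinkDemand, allocate,
                         apply_petiole_plasticity, beta_growth_rate,
                         dimension_update, lamina_demand, percent_biomass_in,
                         photosynthesis, response_factor)

__all__ = [
    "StandConfiguration",
    "StandResult",
    "PerformanceMatrix",
    "simulate_stand",
    "run_experiment",
    "derive_seed",
    "cue_reliability_query",
]


@dataclass(frozen=True)
class StandConfiguration:
    """One mutant-in-resident canopy run."""

    density: float
    resident_alpha: float
    mutant_alpha: float | None = None     # None => monomorphic
    scenario_n: float = 2.0               # Average scenario
    days: int = 46
    rows: int = 7
    cols: int = 7
    seed: int = 0
    source: LightSourceSpec = field(default_factory=LightSourceSpec)
    physiology: PhysiologyParams = field(default_factory=PhysiologyParams)
    schedule: OrganSchedule = field(default_factory=OrganSchedule)
    angles: AngleParams = field(default_factory=AngleParams)
    record_organ_light: bool = False

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ValueError("days must be >= 1")

    @property
    def effective_mutant_alpha(self) -> float:
        return self.resident_alpha if self.mutant_alpha is None else self.mutant_alpha

    @property
    def is_monomorphic(self) -> bool:
        return self.effective_mutant_alpha == self.resident_alpha

    def layout(self) -> StandLayout:
        return StandLayout(self.density, self.rows, self.cols)


@dataclass
class StandResult:
    """Focal-plant performance plus per-day trajectories."""

    focal_performance: float          # mg
    trajectories: pd.DataFrame        # one row per day
    rank_sizes: pd.DataFrame          # final per-rank organ sizes, focal plant
    seed: int
    config: StandConfiguration
    assimilate: np.ndarray            # (days, n_plants) mg fixed per day
    endowment: np.ndarray             # (days, n_plants) mg of seed carbon added
    biomass: np.ndarray               # (days, n_plants) end-of-day totals
    organ_light: pd.DataFrame | None = None
    energy_closure: np.ndarray | None = None   # per-band, last day


def _pairwise_min_tip_distance(tips: np.ndarray, plant_ids: np.ndarray,
                               Lx: float, Ly: float,
                               restrict_to_neighbours: bool) -> np.ndarray:
    """Min toroidal distance from each lamina tip to any other leaf's tip."""
    T = len(tips)
    out = np.full(T, np.inf)
    if T < 2:
        return out
    d = tips[:, None, :] - tips[None, :, :]
    d[..., 0] -= Lx * np.round(d[..., 0] / Lx)
    d[..., 1] -= Ly * np.round(d[..., 1] / Ly)
    dist = np.sqrt((d ** 2).sum(axis=-1))
    np.fill_diagonal(dist, np.inf)
    if restrict_to_neighbours:
        same = plant_ids[:, None] == plant_ids[None, :]
        dist[same] = np.inf
    return dist.min(axis=1)


def simulate_stand(config: StandConfiguration) -> StandResult:
    """Run one canopy for ``config.days`` days and return the focal result."""
    rng = np.random.default_rng(config.seed)
    layout = config.layout()
    positions = grid_positions(layout)
    foc = focal_index(layout)
    Lx, Ly = layout.period
    phys = config.physiology
    resident = PlasticityStrategy(config.resident_alpha, config.scenario_n)
    mutant = PlasticityStrategy(config.effective_mutant_alpha, config.scenario_n)

    plants = [
        Plant(position=(float(x), float(y)),
              strategy=mutant if i == foc else resident,
              base_azimuth=float(rng.uniform(0.0, 360.0)),
              is_focal=(i == foc))
        for i, (x, y) in enumerate(positions)
    ]
    n_plants = len(plants)
    t_e_lam = phys.lamina_growth.t_e
    t_e_pet = phys.petiole_growth.t_e

    days = config.days
    assim = np.zeros((days, n_plants))
    endow = np.zeros((days, n_plants))
    biomass = np.zeros((days, n_plants))
    traj_rows = []
    light_rows: list[dict] = []
    closure = None

    for di in range(days):
        day = float(di + 1)
        # (1) organ initiation
        for pi, plant in enumerate(plants):
            endow[di, pi] = initiate_organs(plant, day, config.schedule,
                                            phys.sla,
                                            phys.petiole_linear_density)
        # growth-phase flags from age
        for plant in plants:
            for leaf in plant.leaves:
                if leaf.senesced:
                    continue
                age = leaf.age(day)
                leaf.lamina_growing = age < t_e_lam
                leaf.petiole_growing = age < t_e_pet

        # (2) light
        patches = stand_patches(plants)
        if len(patches) == 0:
            for pi in range(n_plants):
                biomass[di, pi] = plants[pi].total_biomass
            traj_rows.append(_empty_traj_row(day, plants[foc], config))
            continue
        sensor_mask = _sensor_mask(patches, plants, config)
        sample = compute_light(patches, layout, config.source, rng,
                               sensor_mask=sensor_mask)
        closure = sample.energy_closure()

        # push per-organ light onto leaves
        par_flux = sample.absorbed_par_flux
        rfr = sample.perceived_rfr
        for k in range(len(patches)):
            leaf = plants[patches.plant_idx[k]].leaves[patches.leaf_idx[k]]
            if patches.kinds[k] == KIND_LAMINA:
                leaf.lamina_par = float(par_flux[k])
                leaf.lamina_rfr = float(rfr[k])
            else:
                leaf.petiole_rfr = float(rfr[k])

        for pi, plant in enumerate(plants):
            # (3) photosynthesis into the plant's central pool
            pool = sum(
                photosynthesis(l.lamina_par, l.lamina_area, phys,
                               config.source.photoperiod)
                for l in plant.active_leaves())
            assim[di, pi] = pool

            # (4)+(5) response factors, demands, allocation
            demands: list[SinkDemand] = []
            leaf_potential = 0.0
            for li, leaf in enumerate(plant.leaves):
                if leaf.senesced:
                    continue
                age = leaf.age(day)
                if leaf.lamina_growing:
                    d_p = beta_growth_rate(age, phys.lamina_growth)
                    leaf_potential += d_p
                    f_lam = (response_factor(leaf.lamina_rfr, plant.strategy)
                             if math.isfinite(leaf.lamina_rfr) else 1.0)
                    d = lamina_demand(d_p, f_lam, plant.strategy.n_exponent)
                    demands.append(SinkDemand("lamina", li, d_p, d))
                if leaf.petiole_growing:
                    d_p = beta_growth_rate(age, phys.petiole_growth)
                    leaf_potential += d_p
                    demands.append(SinkDemand("petiole", li, d_p, d_p))
                if leaf.pending_elongation_demand > 0:
                    debt = leaf.pending_elongation_demand
                    demands.append(SinkDemand("petiole_debt", li, debt, debt))
            root_d = phys.root_demand_fraction * leaf_potential
            demands.append(SinkDemand("root", -1, root_d, root_d))
            demands = allocate(pool, demands, phys.surplus_lamina_fraction)

            # (6) dimension update
            alloc = {("lamina", li): 0.0 for li in range(len(plant.leaves))}
            got = {}
            for d in demands:
                if d.organ == "root":
                    plant.root_biomass += d.allocated
                else:
                    key = (d.organ, d.leaf_index)
                    got[key] = got.get(key, 0.0) + d.allocated
            for li, leaf in enumerate(plant.leaves):
                if leaf.senesced:
                    continue
                dimension_update(leaf,
                                 got.get(("lamina", li), 0.0),
                                 got.get(("petiole", li), 0.0),
                                 got.get(("petiole_debt", li), 0.0),
                                 phys)

            # (7) petiole elongation after growth, debt queued for next step
            for leaf in plant.active_leaves():
                if leaf.petiole_growing and math.isfinite(leaf.petiole_rfr):
                    f_pet = response_factor(leaf.petiole_rfr, plant.strategy)
                    apply_petiole_plasticity(leaf, f_pet,
                                             phys.petiole_linear_density)

        # (8) leaf-angle update on post-growth geometry
        new_patches = stand_patches(plants)
        lam_sel = new_patches.kinds == KIND_LAMINA
        tips = new_patches.lamina_tips()
        min_dist = _pairwise_min_tip_distance(
            tips, new_patches.plant_idx[lam_sel], Lx, Ly,
            config.angles.restrict_to_neighbours)
        for k, (pi, li) in enumerate(zip(new_patches.plant_idx[lam_sel],
                                         new_patches.leaf_idx[lam_sel])):
            leaf = plants[pi].leaves[li]
            lam_rfr = leaf.lamina_rfr if math.isfinite(leaf.lamina_rfr) else np.inf
            update_leaf_angle(leaf, float(min_dist[k]), lam_rfr, config.angles)

        # (9) senescence
        for plant in plants:
            senesce(plant, day)

        for pi, plant in enumerate(plants):
            total = plant.total_biomass
            if not math.isfinite(total):
                raise RuntimeError(
                    f"non-finite biomass on day {day:.0f}, plant {pi}")
            biomass[di, pi] = total

        focal = plants[foc]
        traj_rows.append({
            "day": day,
            "mean_rfr": mean_plant_rfr(sample, foc),
            "total_biomass_mg": focal.total_biomass,
            "pct_petiole": percent_biomass_in("petiole", focal),
            "pct_lamina": percent_biomass_in("lamina", focal),
            "lai": compute_lai(focal, config.density),
            "mean_leaf_angle": (np.mean([l.elevation_angle
                                         for l in focal.active_leaves()])
                                if focal.active_leaves() else np.nan),
            "n_leaves": len(focal.leaves),
        })
        if config.record_organ_light:
            for leaf in focal.leaves:
                if leaf.senesced:
                    continue
                light_rows.append({
                    "day": day, "plant_id": foc, "rank": leaf.rank,
                    "absorbed_par": leaf.lamina_par,
                    "lamina_rfr": leaf.lamina_rfr,
                    "petiole_rfr": leaf.petiole_rfr,
                })

    focal = plants[foc]
    rank_rows = [{
        "rank": l.rank,
        "petiole_length_m": l.petiole_length,
        "petiole_biomass_mg": l.petiole_biomass,
        "lamina_area_m2": l.lamina_area,
        "lamina_biomass_mg": l.lamina_biomass,
        "elevation_angle": l.elevation_angle,
        "senesced": l.senesced,
    } for l in focal.leaves]
    return StandResult(
        focal_performance=focal.total_biomass,
        trajectories=pd.DataFrame(traj_rows),
        rank_sizes=pd.DataFrame(rank_rows),
        seed=config.seed,
        config=config,
        assimilate=assim,
        endowment=endow,
        biomass=biomass,
        organ_light=pd.DataFrame(light_rows) if config.record_organ_light else None,
        energy_closure=closure,
    )


def _sensor_mask(patches, plants, config) -> np.ndarray:
    """Sense laminas (angle rule + lamina response) and growing or recorded
    petioles; skipping finished petioles keeps the sensor pass small."""
    mask = np.zeros(len(patches), dtype=bool)
    for k in range(len(patches)):
        leaf = plants[patches.plant_idx[k]].leaves[patches.leaf_idx[k]]
        if patches.kinds[k] == KIND_LAMINA:
            mask[k] = True
        else:
            mask[k] = leaf.petiole_growing or config.record_organ_light
    return mask


def _empty_traj_row(day, focal, config):
    return {"day": day, "mean_rfr": np.nan,
            "total_biomass_mg": focal.total_biomass,
            "pct_petiole": np.nan, "pct_lamina": np.nan,
            "lai": 0.0, "mean_leaf_angle": np.nan, "n_leaves": 0}


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------


@dataclass
class PerformanceMatrix:
    """Replicate focal performances over the (mutant, resident) strategy grid."""

    density: float
    scenario_n: float
    strategies: np.ndarray            # (S,)
    replicates: np.ndarray            # (S mutant, S resident, K)
    failures: list = field(default_factory=list)

    @property
    def mean(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.replicates, axis=2)

    @property
    def sd(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanstd(self.replicates, axis=2, ddof=1)

    @property
    def n_replicates(self) -> int:
        return self.replicates.shape[2]

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for mi, m in enumerate(self.strategies):
            for ri, r in enumerate(self.strategies):
                for k in range(self.n_replicates):
                    rows.append({
                        "density": self.density,
                        "scenario_n": self.scenario_n,
                        "mutant_alpha": m,
                        "resident_alpha": r,
                        "replicate": k,
                        "focal_biomass_mg": self.replicates[mi, ri, k],
                    })
        return pd.DataFrame(rows)

    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame) -> "PerformanceMatrix":
        density = float(frame["density"].iloc[0])
        scenario_n = float(frame["scenario_n"].iloc[0])
        strategies = np.array(sorted(frame["resident_alpha"].unique()))
        n_rep = int(frame["replicate"].max()) + 1
        reps = np.full((len(strategies), len(strategies), n_rep), np.nan)
        pos = {a: i for i, a in enumerate(strategies)}
        for _, row in frame.iterrows():
            reps[pos[row["mutant_alpha"]], pos[row["resident_alpha"]],
                 int(row["replicate"])] = row["focal_biomass_mg"]
        return cls(density, scenario_n, strategies, reps)


def derive_seed(seed_base: int, density: float, scenario_n: float,
                mutant_index: int, resident_index: int, replicate: int) -> int:
    """Stable per-run seed from the design coordinates (SeedSequence hash)."""
    entropy = (int(seed_base), int(round(density)),
               int(round(scenario_n * 1000)),
               int(mutant_index), int(resident_index), int(replicate))
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] & 0x7FFFFFFF)


def run_experiment(strategies, densities, scenarios, replicates: int,
                   seed_base: int, progress=None,
                   **stand_kwargs) -> dict[tuple[float, float], PerformanceMatrix]:
    """Full (mutant x resident x replicate) design per density and scenario.

    Seeds derive deterministically from ``seed_base`` and the design
    coordinates, so partial reruns reproduce individual cells.  A failed run
    leaves a NaN cell and is recorded in the matrix's failure list.
    """
    strategies = np.asarray(list(strategies), dtype=float)
    if strategies.size == 0:
        raise ValueError("strategy grid must be non-empty")
    out: dict[tuple[float, float], PerformanceMatrix] = {}
    for density in densities:
        for n in scenarios:
            reps = np.full((len(strategies), len(strategies), replicates), np.nan)
            failures = []
            for mi, m in enumerate(strategies):
                for ri, r in enumerate(strategies):
                    for k in range(replicates):
                        seed = derive_seed(seed_base, density, n, mi, ri, k)
                        cfg = StandConfiguration(
                            density=density, resident_alpha=float(r),
                            mutant_alpha=float(m), scenario_n=float(n),
                            seed=seed, **stand_kwargs)
                        try:
                            reps[mi, ri, k] = simulate_stand(cfg).focal_performance
                        except Exception as exc:   # partial failure: keep going
                            failures.append((m, r, k, repr(exc)))
                            warnings.warn(f"run (m={m}, r={r}, rep={k}) "
                                          f"failed: {exc}")
                        if progress is not None:
                            progress()
            out[(float(density), float(n))] = PerformanceMatrix(
                float(density), float(n), strategies, reps, failures)
    return out


def cue_reliability_query(results: list[StandResult],
                          rfr_window: tuple[float, float] = (0.95, 1.05),
                          min_day: float | None = None) -> pd.DataFrame:
    """Absorbed lamina PAR where the leaf's petiole perceived R:FR inside
    ``rfr_window``, summarized per density (mean/median/quartiles/count).

    ``min_day`` restricts the pooled organ samples to late canopy
    development (the published query reads like a late single-day snapshot);
    default pools every recorded day.
    """
    lo, hi = rfr_window
    frames = []
    for res in results:
        if res.organ_light is None:
            raise ValueError("cue_reliability_query needs record_organ_light=True")
        df = res.organ_light.copy()
        df["density"] = res.config.density
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)
    if min_day is not None:
        data = data[data["day"] >= min_day]
    sel = data[(data["petiole_rfr"] >= lo) & (data["petiole_rfr"] <= hi)]
    if sel.empty:
        warnings.warn("cue-reliability window selected no leaves")
        return pd.DataFrame(columns=["density", "n", "mean_par", "median_par",
                                     "q1_par", "q3_par"])
    rows = []
    for density, grp in sel.groupby("density"):
        rows.append({
            "density": density,
            "n": len(grp),
            "mean_par": grp["absorbed_par"].mean(),
            "median_par": grp["absorbed_par"].median(),
            "q1_par": grp["absorbed_par"].quantile(0.25),
            "q3_par": grp["absorbed_par"].quantile(0.75),
        })
    return pd.DataFrame(rows).sort_values("density").reset_index(drop=True)
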
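"""Carbon physiology: photosynthesis, sink demands, allocation, R:FR responses.

The plant's daily carbon budget follows the relative sink strength principle:
every lamina converts its absorbed photosynthetically active radiation (PAR)
into assimilates via a negative-exponential light response; assimilates are
pooled per plant and partitioned over all growing organs in proportion to
their demand.  An organ's potential demand is the derivative of a determinate
beta growth curve at its age.  Shade-avoidance plasticity enters twice:

* the response factor ``F = min(2, (R:FR / RFR_control)^-alpha)`` multiplies
  the petiole length each day (the carbon cost is queued as extra petiole
  demand for the next step), and
* the lamina demand is down-regulated as ``D = D_p / F^n``.

Both responses act only while the organ is in its growth phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .architecture import Leaf, Plant, PlasticityStrategy

__all__ = [
    "GrowthCurveParams",
    "PhysiologyParams",
    "SinkDemand",
    "response_factor",
    "lamina_demand",
    "beta_growth_mass",
    "beta_growth_rate",
    "photosynthesis",
    "allocate",
    "apply_petiole_plasticity",
    "dimension_update",
    "percent_biomass_in",
]

#: hard cap on the relative organ growth factor (at most doubling per day)
F_MAX = 2.0


def response_factor(rfr: float, strategy: PlasticityStrategy) -> float:
    """Relative organ growth factor F from locally perceived R:FR.

    F = min(2, (rfr / rfr_control)^(-alpha)); F == 1 for alpha == 0 or at the
    control ratio, rising towards the cap of 2 as R:FR drops below control.
    """
    if not rfr > 0:
        raise ValueError(f"R:FR must be > 0, got {rfr}")
    return min(F_MAX, (rfr / strategy.rfr_control) ** (-strategy.alpha))


def lamina_demand(d_p: float, f: float, n: float) -> float:
    """Actual lamina carbon demand, mg/d: D = D_p / F^n."""
    if d_p < 0:
        raise ValueError("potential demand must be >= 0")
    if not f > 0:
        raise ValueError("F must be > 0")
    if n < 0:
        raise ValueError("n must be >= 0")
    return d_p / f ** n


@dataclass(frozen=True)
class GrowthCurveParams:
    """Determinate (beta) growth curve: final mass, duration, inflection."""

    w_max: float    # mg
    t_e: float      # d, end of growth
    t_m: float      # d, inflection (time of maximal rate)

    def __post_init__(self) -> None:
        if not (0 < self.t_m < self.t_e):
            raise ValueError("need 0 < t_m < t_e")
        if not self.w_max > 0:
            raise ValueError("w_max must be > 0")


def beta_growth_mass(t: float, p: GrowthCurveParams) -> float:
    """Beta growth curve W(t) = W_max (1 + (t_e - t)/(t_e - t_m)) (t/t_e)^(t_e/(t_e-t_m))."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if t >= p.t_e:
        return p.w_max
    if t == 0:
        return 0.0
    ex = p.t_e / (p.t_e - p.t_m)
    return p.w_max * (1.0 + (p.t_e - t) / (p.t_e - p.t_m)) * (t / p.t_e) ** ex


def beta_growth_rate(t: float, p: GrowthCurveParams) -> float:
    """Closed-form derivative dW/dt of the beta growth curve; 0 outside (0, t_e).

    dW/dt = W_max * ex * (2t_e - t_m - t)(t_e - t) / (t_e - t_m)^2 / t_e
            * (t/t_e)^(ex - 1) / t_e   with ex = t_e/(t_e - t_m)
    (verified in the tests against a numerical-differentiation oracle).
    """
    if t <= 0 or t >= p.t_e:
        return 0.0
    span = p.t_e - p.t_m
    ex = p.t_e / span
    u = t / p.t_e
    # d/dt [ (1 + (t_e-t)/span) u^ex ]
    #   = -1/span * u^ex + (1 + (t_e-t)/span) * ex * u^(ex-1) / t_e
    return p.w_max * (-u ** ex / span
                      + (1.0 + (p.t_e - t) / span) * ex * u ** (ex - 1.0) / p.t_e)


@dataclass(frozen=True)
class PhysiologyParams:
    """Rate constants and conversions for the carbon budget.

    Units: masses mg (CH2O-equivalent dry biomass), areas m^2, lengths m,
    light umol m^-2 s^-1, time d.  Defaults are chosen for realistic
    Arabidopsis rosette scale: light-saturated assimilation ~0.3 mg biomass
    m^-2 s^-1 (~10 umol CO2 m^-2 s^-1), quantum-yield-like initial slope,
    SLA ~ 400 cm^2 g^-1, petioles ~200 mg per metre.
    """

    p_max: float = 0.3                 # mg biomass m^-2 s^-1, light-saturated
    phi: float = 1.5e-3                # mg biomass per umol photons
    conversion: float = 1.0            # assimilate conversion efficiency
    sla: float = 4.0e-5                # m^2 lamina per mg
    petiole_linear_density: float = 200.0   # mg per m of petiole
    lamina_growth: GrowthCurveParams = GrowthCurveParams(12.0, 20.0, 9.0)
    petiole_growth: GrowthCurveParams = GrowthCurveParams(4.0, 20.0, 9.0)
    root_demand_fraction: float = 0.10      # of total leaf potential demand
    surplus_lamina_fraction: float = 0.5    # surplus split: laminas vs root


def photosynthesis(absorbed_par: float, lamina_area: float,
                   p: PhysiologyParams, photoperiod: float) -> float:
    """Daily assimilate (mg/d) of one lamina under a negative-exponential
    light response: p_max (1 - exp(-phi I / p_max)) * area * photoperiod."""
    if absorbed_par < 0 or lamina_area < 0 or photoperiod < 0:
        raise ValueError("photosynthesis inputs must be >= 0")
    rate = p.p_max * (1.0 - math.exp(-p.phi * absorbed_par / p.p_max))
    return rate * lamina_area * photoperiod * 3600.0 * p.conversion


@dataclass
class SinkDemand:
    """One growing sink's claim on the day's carbon pool."""

    organ: str                  # "lamina" | "petiole" | "root"
    leaf_index: int             # -1 for root
    potential: float            # D_p, mg/d
    demand: float               # D after plastic down-regulation, mg/d
    allocated: float = 0.0      # mg, filled by allocate()


def allocate(pool: float, demands: list[SinkDemand],
             surplus_lamina_fraction: float = 0.5) -> list[SinkDemand]:
    """Partition the carbon pool over sinks by relative sink strength.

    If the pool is short, organ i receives pool * D_i / sum(D).  If the pool
    covers all demands, each organ receives its demand and the surplus is
    split between laminas (pro-rata by lamina demand) and the root.  The
    allocations sum to the pool exactly (up to float rounding).
    """
    if pool < 0:
        raise ValueError("pool must be >= 0")
    if any(d.demand < 0 for d in demands):
        raise ValueError("demands must be >= 0")
    total = sum(d.demand for d in demands)
    for d in demands:
        d.allocated = 0.0
    if pool == 0 or not demands:
        return demands
    if total == 0:
        # nothing asks for carbon: the whole surplus is stored in the root
        for d in demands:
            if d.organ == "root":
                d.allocated = pool
                return demands
        demands.append(SinkDemand("root", -1, 0.0, 0.0, pool))
        return demands
    if pool < total:
        for d in demands:
            d.allocated = pool * d.demand / total
        return demands
    surplus = pool - total
    laminas = [d for d in demands if d.organ == "lamina" and d.demand > 0]
    lam_total = sum(d.demand for d in laminas)
    to_lam = surplus * surplus_lamina_fraction if lam_total > 0 else 0.0
    to_root = surplus - to_lam
    for d in demands:
        d.allocated = d.demand
        if d.organ == "lamina" and lam_total > 0:
            d.allocated += to_lam * d.demand / lam_total
        elif d.organ == "root":
            d.allocated += to_root
    if not any(d.organ == "root" for d in demands) and to_root > 0:
        demands.append(SinkDemand("root", -1, 0.0, 0.0, to_root))
    return demands


def apply_petiole_plasticity(leaf: Leaf, f: float,
                             petiole_linear_density: float) -> float:
    """Multiply petiole length by F; return the extra demand queued (mg).

    Only acts while the petiole is in its growth phase.  The length change is
    immediate; the carbon to back it, (F - 1) * old_length * linear density,
    is added to the petiole's next-step sink demand and is never rolled back
    if unpaid.
    """
    if not leaf.petiole_growing or leaf.senesced:
        return 0.0
    old = leaf.petiole_length
    leaf.petiole_length = old * f
    extra = (f - 1.0) * old * petiole_linear_density
    leaf.pending_elongation_demand += extra
    return extra


def dimension_update(leaf: Leaf, allocated_lamina: float,
                     allocated_petiole_growth: float,
                     allocated_petiole_debt: float,
                     p: PhysiologyParams) -> Leaf:
    """Convert allocated mass into organ dimensions.

    Lamina mass extends area through an SLA-like conversion while the lamina
    is growing (post-growth-phase surplus is stored without area gain);
    petiole *growth* mass extends length through the linear density, while
    mass paying off an earlier elongation debt adds biomass only (the length
    was already realized when F was applied).
    """
    if min(allocated_lamina, allocated_petiole_growth, allocated_petiole_debt) < 0:
        raise ValueError("allocations must be >= 0")
    leaf.lamina_biomass += allocated_lamina
    if leaf.lamina_growing:
        leaf.lamina_area += allocated_lamina * p.sla
    leaf.petiole_biomass += allocated_petiole_growth + allocated_petiole_debt
    leaf.petiole_length += allocated_petiole_growth / p.petiole_linear_density
    leaf.pending_elongation_demand = max(
        0.0, leaf.pending_elongation_demand - allocated_petiole_debt)
    return leaf


def percent_biomass_in(compartment: str, plant: Plant) -> float:
    """Percent of whole-plant biomass (petioles + laminas + root) in one compartment."""
    total = plant.total_biomass
    if total <= 0:
        return float("nan")
    if compartment == "petiole":
        mass = sum(l.petiole_biomass for l in plant.leaves)
    elif compartment == "lamina":
        mass = sum(l.lamina_biomass for l in plant.leaves)
    elif compartment == "root":
        mass = plant.root_biomass
    else:
        raise ValueError(f"unknown compartment {compartment!r}")
    return 100.0 * mass / total
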